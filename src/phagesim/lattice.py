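"""The environment and discrete-time scheduler.

A toroidal W x H lattice holds at most one bacterium and any number of free
virions per site.  The environment is well-mixed: all positions are
re-randomized at the start of every iteration, so space matters only through
single-site occupancy (free space is the bacterial resource) and the Moore
neighbourhood (reproduction competition and the local free-phage count that
drives the lysogeny decision).

One iteration executes, in fixed order:

1. randomize positions;
2. antibiotic action (death of unprotected cells, stress update);
3. prophage induction (stress-dependent sigmoidal probability, lysis);
4. adsorption of co-located virions (superinfection exclusion, transducing
   injection, lytic/lysogenic decision; at most one productive functional
   infection per cell per iteration);
5. free-virion decay;
6. intrinsic bacterial death;
7. reproduction into free sites by fitness-proportional roulette among the
   Moore neighbours;
8. record the time series.

Virions released by lysis become visible (positions, adsorption, decay,
local counts) from the next iteration on.  State is kept in flat numpy
arrays; genomes are interned integer ids (see :mod:`phagesim.registry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import InvalidParameterError, PhageGenotype, induction_probability
from .registry import GenomeRegistry

__all__ = [
    "SimulationParams",
    "Lattice",
    "OutcomeSummary",
    "TimeseriesRecord",
    "run_replicates",
    "replicate_seed",
    "survival_fractions",
    "series_median_ci",
]


@dataclass(frozen=True)
class SimulationParams:
    """Environment-level rates (all per iteration).

    p_ads                adsorption probability per co-located virion
    p_decay              free-virion decay probability
    p_death              intrinsic bacterial death probability
    max_age              optional hard age limit for bacteria
    cost                 fitness cost per active resistance gene
    p_kill               kill probability per exposed, unprotected cell
    stress_on_exposure   stress level set by antibiotic exposure
    p_recomb             probability injected cargo recombines into the genome
    prophage_span        genome slots occupied by an integrated prophage
    """

    p_ads: float = 0.4
    p_decay: float = 0.15
    p_death: float = 0.01
    max_age: Optional[int] = None
    cost: float = 0.05
    p_kill: float = 1.0
    stress_on_exposure: float = 10.0
    p_recomb: float = 1.0
    prophage_span: int = 5

    def __post_init__(self) -> None:
        for name in ("p_ads", "p_decay", "p_death", "p_kill", "p_recomb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.cost < 1.0:
            raise InvalidParameterError("cost must be in [0, 1)")


@dataclass(frozen=True)
class OutcomeSummary:
    """End-of-run summary: bacteria survive if any cell is alive; phage
    survive if any free functional virion exists or any living cell carries a
    prophage."""

    bacteria_survived: bool
    phage_survived: bool
    final_iteration: int
    seed: int

    @property
    def joint_survival(self) -> bool:
        return self.bacteria_survived and self.phage_survived


@dataclass
class TimeseriesRecord:
    """Per-iteration counts.

    ``bacteria`` is long format (iteration x strain x resistance profile x
    lysogen status); ``totals`` holds one row per iteration with population
    totals, free functional/transducing virions and cumulative event counts.
    """

    bacteria: pd.DataFrame
    totals: pd.DataFrame


_NEIGHBOR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def moore_neighbors(width: int, height: int) -> np.ndarray:
    """(n_sites, 8) toroidal Moore-neighbour site indices."""
    key = (width, height)
    hit = _NEIGHBOR_CACHE.get(key)
    if hit is not None:
        return hit
    ys, xs = np.divmod(np.arange(width * height), width)
    cols = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            cols.append(((ys + dy) % height) * width + (xs + dx) % width)
    table = np.stack(cols, axis=1).astype(np.int64)
    _NEIGHBOR_CACHE[key] = table
    return table


class Lattice:
    """Mutable simulation state plus the scheduler."""

    def __init__(
        self,
        width: int,
        height: int,
        registry: GenomeRegistry,
        params: SimulationParams,
        rng: np.random.Generator,
        antibiotic_schedule: Optional[Mapping[int, frozenset[str]]] = None,
    ) -> None:
        self.width = width
        self.height = height
        self.n_sites = width * height
        self.reg = registry
        self.params = params
        self.rng = rng
        self.schedule: dict[int, frozenset[str]] = dict(antibiotic_schedule or {})
        self.iteration = 0
        self._nbr = moore_neighbors(width, height)

        self.strains: list[str] = []
        self._strain_index: dict[str, int] = {}

        self.bact_gid = np.zeros(0, dtype=np.int64)
        self.bact_site = np.zeros(0, dtype=np.int64)
        self.bact_strain = np.zeros(0, dtype=np.int64)
        self.bact_stress = np.zeros(0, dtype=float)
        self.bact_age = np.zeros(0, dtype=np.int64)
        self.site2b = np.full(self.n_sites, -1, dtype=np.int64)

        self.vir_gt = np.zeros(0, dtype=np.int64)
        self.vir_cargo = np.full(0, -1, dtype=np.int64)  # -1 = phage DNA
        self.vir_site = np.zeros(0, dtype=np.int64)
        self.vir_age = np.zeros(0, dtype=np.int64)

        self.cum_transductions = 0
        self.cum_inductions = 0
        self._births_gid: list[np.ndarray] = []
        self._births_strain: list[np.ndarray] = []
        self._births_site: list[np.ndarray] = []
        self.audit: list[dict] = []
        self._bact_rows: list[tuple[int, int, int, int, int]] = []
        self._total_rows: list[dict] = []

    # -- population management -------------------------------------------------

    def strain_id(self, name: str) -> int:
        if name not in self._strain_index:
            self._strain_index[name] = len(self.strains)
            self.strains.append(name)
        return self._strain_index[name]

    @property
    def n_bacteria(self) -> int:
        return len(self.bact_gid)

    @property
    def n_virions(self) -> int:
        return len(self.vir_gt)

    def place_bacteria(self, gid: int, strain: str, n_cells: int) -> None:
        """Place ``n_cells`` bacteria with genome ``gid`` on random free sites."""
        free = np.flatnonzero(self.site2b < 0)
        if n_cells > len(free):
            raise InvalidParameterError(
                f"cannot place {n_cells} bacteria on {len(free)} free sites"
            )
        sites = self.rng.choice(free, size=n_cells, replace=False)
        sid = self.strain_id(strain)
        start = self.n_bacteria
        self.bact_gid = np.concatenate([self.bact_gid, np.full(n_cells, gid, dtype=np.int64)])
        self.bact_site = np.concatenate([self.bact_site, sites.astype(np.int64)])
        self.bact_strain = np.concatenate([self.bact_strain, np.full(n_cells, sid, dtype=np.int64)])
        self.bact_stress = np.concatenate([self.bact_stress, np.zeros(n_cells)])
        self.bact_age = np.concatenate([self.bact_age, np.zeros(n_cells, dtype=np.int64)])
        self.site2b[sites] = np.arange(start, start + n_cells)

    def seed_virions(self, gt_ids: np.ndarray, cargo_ids: np.ndarray) -> None:
        """Introduce free virions at uniformly random sites."""
        n = len(gt_ids)
        sites = self.rng.integers(self.n_sites, size=n)
        self.vir_gt = np.concatenate([self.vir_gt, np.asarray(gt_ids, dtype=np.int64)])
        self.vir_cargo = np.concatenate([self.vir_cargo, np.asarray(cargo_ids, dtype=np.int64)])
        self.vir_site = np.concatenate([self.vir_site, sites])
        self.vir_age = np.concatenate([self.vir_age, np.zeros(n, dtype=np.int64)])

    def seed_functional(self, genotype_name: str, count: int) -> None:
        gt = self.reg.gt_index[genotype_name]
        self.seed_virions(
            np.full(count, gt, dtype=np.int64), np.full(count, -1, dtype=np.int64)
        )

    # -- phases ------------------------------------------------------------------

    def randomize_positions(self) -> None:
        """Well-mixed shuffle: bacteria permuted over sites (single occupancy
        preserved), each free virion independently reassigned to a uniform
        random site.  All counts are conserved."""
        n = self.n_bacteria
        if n:
            sites = self.rng.choice(self.n_sites, size=n, replace=False)
            self.bact_site = sites.astype(np.int64)
            self.site2b.fill(-1)
            self.site2b[sites] = np.arange(n)
        if self.n_virions:
            self.vir_site = self.rng.integers(self.n_sites, size=self.n_virions)

    def _kill(self, idx: np.ndarray) -> None:
        self.site2b[self.bact_site[idx]] = -1
        self._alive[idx] = False

    def _antibiotic_phase(self, drugs: frozenset[str]) -> int:
        if not drugs:
            self.bact_stress.fill(0.0)
            return 0
        self.bact_stress.fill(self.params.stress_on_exposure)
        alive = np.flatnonzero(self._alive)
        if not len(alive):
            return 0
        bits = self.reg.drug_bits(drugs)
        unprotected = (self.reg.res_mask[self.bact_gid[alive]] & bits) != bits
        at_risk = alive[unprotected]
        killed = at_risk[self.rng.random(len(at_risk)) < self.params.p_kill]
        self._kill(killed)
        return len(killed)

    def _induction_phase(self) -> int:
        alive = np.flatnonzero(self._alive)
        if not len(alive):
            return 0
        gids = self.bact_gid[alive]
        g1 = self.reg.pro_gt[gids]
        g2 = self.reg.pro_gt2[gids]
        lys = g1 >= 0
        if not lys.any():
            return 0
        p = np.zeros(len(alive))
        stress = self.bact_stress[alive]
        for gt in np.unique(g1[lys]):
            m = g1 == gt
            p[m] = induction_probability(
                stress[m], float(self.reg.gt_alpha[gt]), float(self.reg.gt_kappa[gt])
            )
        if (g2 >= 0).any():
            p2 = np.zeros(len(alive))
            for gt in np.unique(g2[g2 >= 0]):
                m = g2 == gt
                p2[m] = induction_probability(
                    stress[m], float(self.reg.gt_alpha[gt]), float(self.reg.gt_kappa[gt])
                )
            p = 1.0 - (1.0 - p) * (1.0 - p2)
        induced = lys & (self.rng.random(len(alive)) < p)
        idx = alive[induced]
        if len(idx):
            # the induced prophage's genotype packages the burst (first one if
            # a rare double lysogen fires)
            self._lyse(idx, self.reg.pro_gt[self.bact_gid[idx]].astype(np.int64))
        self.cum_inductions += len(idx)
        return len(idx)

    def _lyse(self, cells: np.ndarray, gt_ids: np.ndarray) -> None:
        """Lyse ``cells``; package bursts (appended at end of the iteration)."""
        gids = self.bact_gid[cells]
        sites = self.bact_site[cells]
        self._kill(cells)
        burst = self.reg.gt_burst[gt_ids]
        p_gt = self.reg.gt_p_gt[gt_ids]
        n_trans = self.rng.binomial(burst, p_gt)
        n_func = burst - n_trans
        # functional progeny
        self._new_vir_gt.append(np.repeat(gt_ids, n_func))
        self._new_vir_cargo.append(np.full(int(n_func.sum()), -1, dtype=np.int64))
        self._new_vir_site.append(np.repeat(sites, n_func))
        # transducing progeny: headful windows at uniform starts of each host
        total_t = int(n_trans.sum())
        if total_t:
            rep_gid = np.repeat(gids, n_trans)
            rep_npack = np.repeat(self.reg.n_pack[gids], n_trans)
            starts = (self.rng.random(total_t) * rep_npack).astype(np.int64)
            intern = self.reg.intern_cargo
            cids = np.fromiter(
                (intern(int(g), int(s)) for g, s in zip(rep_gid, starts)),
                dtype=np.int64,
                count=total_t,
            )
            self._new_vir_gt.append(np.repeat(gt_ids, n_trans))
            self._new_vir_cargo.append(cids)
            self._new_vir_site.append(np.repeat(sites, n_trans))

    def _adsorption_phase(self) -> dict:
        counts = {
            "adsorbed": 0,
            "blocked": 0,
            "surplus_lost": 0,
            "transduced": 0,
            "lysogenized": 0,
            "lysed": 0,
        }
        m = self.n_virions
        if m == 0 or not self._alive.any():
            return counts
        host = self.site2b[self.vir_site]
        ads = (host >= 0) & (self.rng.random(m) < self.params.p_ads)
        if not ads.any():
            return counts
        site_counts = np.bincount(self.vir_site, minlength=self.n_sites)
        counts["adsorbed"] = int(ads.sum())

        # transducing injections first (they bypass superinfection immunity
        # and cannot kill, so ordering against each other is immaterial)
        t_idx = np.flatnonzero(ads & (self.vir_cargo >= 0))
        if len(t_idx):
            recomb = (
                np.ones(len(t_idx), dtype=bool)
                if self.params.p_recomb >= 1.0
                else self.rng.random(len(t_idx)) < self.params.p_recomb
            )
            for vi, ok in zip(t_idx, recomb):
                if not ok:
                    continue
                b = int(host[vi])
                self.bact_gid[b] = self.reg.transduce(
                    int(self.bact_gid[b]), int(self.vir_cargo[vi])
                )
                counts["transduced"] += 1
            self.cum_transductions += counts["transduced"]

        # functional infections: at most one productive infection per cell per
        # iteration; every adsorbed functional virion is consumed
        f_idx = np.flatnonzero(ads & (self.vir_cargo < 0))
        if len(f_idx):
            hosts_f = host[f_idx]
            order = np.lexsort((self.rng.random(len(f_idx)), hosts_f))
            _, first = np.unique(hosts_f[order], return_index=True)
            chosen = f_idx[order[first]]
            cells = host[chosen]
            gts = self.vir_gt[chosen]
            immune = (
                self.reg.imm_mask[self.bact_gid[cells]] & self.reg.gt_group[gts]
            ) != 0
            counts["surplus_lost"] = len(f_idx) - len(chosen)
            prod = ~immune
            counts["blocked"] += int(immune.sum())
            if prod.any():
                cells_p = cells[prod]
                gts_p = gts[prod]
                sites_p = self.bact_site[cells_p]
                n_local = site_counts[self._nbr[sites_p]].sum(axis=1)
                p_lys = self.reg.gt_p_lys[gts_p] * n_local / (
                    n_local + self.reg.gt_k_lys[gts_p]
                )
                lysogenize = self.rng.random(len(cells_p)) < p_lys
                for b, gt in zip(cells_p[lysogenize], gts_p[lysogenize]):
                    self.bact_gid[b] = self.reg.lysogenize(int(self.bact_gid[b]), int(gt))
                counts["lysogenized"] = int(lysogenize.sum())
                lysed = ~lysogenize
                if lysed.any():
                    self._lyse(cells_p[lysed], gts_p[lysed].astype(np.int64))
                    counts["lysed"] = int(lysed.sum())

        # all adsorbed virions are consumed
        self._vir_keep &= ~ads
        return counts

    def _decay_phase(self) -> int:
        m = self.n_virions
        if m == 0:
            return 0
        decayed = self._vir_keep & (self.rng.random(m) < self.params.p_decay)
        self._vir_keep &= ~decayed
        return int(decayed.sum())

    def _death_phase(self) -> int:
        alive = np.flatnonzero(self._alive)
        if not len(alive):
            return 0
        die = self.rng.random(len(alive)) < self.params.p_death
        if self.params.max_age is not None:
            die |= self.bact_age[alive] >= self.params.max_age
        self._kill(alive[die])
        return int(die.sum())

    def reproduction_step(self) -> int:
        """Fill free sites by fitness-proportional roulette among living Moore
        neighbours; a parent may win several sites; sites with no living
        neighbour stay empty.  Returns the number of births."""
        free = np.flatnonzero(self.site2b < 0)
        if not len(free) or not (self.site2b >= 0).any():
            return 0
        cand = self.site2b[self._nbr[free]]  # (F, 8); -1 where empty
        w = np.where(cand >= 0, self.reg.fitness_weights(self.params.cost)[self.bact_gid[np.where(cand >= 0, cand, 0)]], 0.0)
        tot = w.sum(axis=1)
        ok = tot > 0.0
        if not ok.any():
            return 0
        cum = np.cumsum(w[ok], axis=1)
        r = self.rng.random(int(ok.sum())) * tot[ok]
        pick = (cum >= r[:, None]).argmax(axis=1)
        parents = cand[ok, pick]
        sites = free[ok]
        self._births_gid.append(self.bact_gid[parents])
        self._births_strain.append(self.bact_strain[parents])
        self._births_site.append(sites)
        return int(ok.sum())

    # -- one iteration -------------------------------------------------------------

    def step(self, record: bool = True) -> None:
        self._alive = np.ones(self.n_bacteria, dtype=bool)
        self._vir_keep = np.ones(self.n_virions, dtype=bool)
        self._new_vir_gt: list[np.ndarray] = []
        self._new_vir_cargo: list[np.ndarray] = []
        self._new_vir_site: list[np.ndarray] = []
        self._births_gid: list[np.ndarray] = []
        self._births_strain: list[np.ndarray] = []
        self._births_site: list[np.ndarray] = []

        self.randomize_positions()
        drugs = self.schedule.get(self.iteration, frozenset())
        n_abx = self._antibiotic_phase(drugs)
        n_ind = self._induction_phase()
        ads_counts = self._adsorption_phase()
        n_decay = self._decay_phase()
        n_death = self._death_phase()
        self.bact_age += 1
        self.vir_age += 1
        n_births = self.reproduction_step()
        n_released = sum(len(a) for a in self._new_vir_gt)
        self._compact()

        self.audit.append(
            {
                "iteration": self.iteration,
                "deaths_antibiotic": n_abx,
                "inductions": n_ind,
                "decayed": n_decay,
                "deaths_intrinsic": n_death,
                "births": n_births,
                "virions_released": n_released,
                **ads_counts,
            }
        )
        self.iteration += 1
        if record:
            self.record()

    def _compact(self) -> None:
        keep = self._vir_keep
        self.vir_gt = self.vir_gt[keep]
        self.vir_cargo = self.vir_cargo[keep]
        self.vir_site = self.vir_site[keep]
        self.vir_age = self.vir_age[keep]
        if self._new_vir_gt:
            new_gt = np.concatenate(self._new_vir_gt)
            if len(new_gt):
                self.vir_gt = np.concatenate([self.vir_gt, new_gt])
                self.vir_cargo = np.concatenate(
                    [self.vir_cargo, np.concatenate(self._new_vir_cargo)]
                )
                self.vir_site = np.concatenate(
                    [self.vir_site, np.concatenate(self._new_vir_site)]
                )
                self.vir_age = np.concatenate(
                    [self.vir_age, np.zeros(len(new_gt), dtype=np.int64)]
                )

        alive = self._alive
        self.bact_gid = self.bact_gid[alive]
        self.bact_site = self.bact_site[alive]
        self.bact_strain = self.bact_strain[alive]
        self.bact_stress = self.bact_stress[alive]
        self.bact_age = self.bact_age[alive]
        if self._births_gid:
            bg = np.concatenate(self._births_gid)
            if len(bg):
                self.bact_gid = np.concatenate([self.bact_gid, bg])
                self.bact_site = np.concatenate(
                    [self.bact_site, np.concatenate(self._births_site)]
                )
                self.bact_strain = np.concatenate(
                    [self.bact_strain, np.concatenate(self._births_strain)]
                )
                self.bact_stress = np.concatenate(
                    [self.bact_stress, np.zeros(len(bg))]
                )
                self.bact_age = np.concatenate(
                    [self.bact_age, np.zeros(len(bg), dtype=np.int64)]
                )
        self.site2b.fill(-1)
        self.site2b[self.bact_site] = np.arange(self.n_bacteria)

    # -- recording -------------------------------------------------------------------

    def record(self) -> None:
        """Append current counts (pure function of the lattice state)."""
        it = self.iteration
        if self.n_bacteria:
            res = self.reg.res_mask[self.bact_gid].astype(np.int64)
            lys = (self.reg.pro_gt[self.bact_gid] >= 0).astype(np.int64)
            nres = 1 << len(self.reg.drugs)
            key = (self.bact_strain * 2 + lys) * nres + res
            cnt = np.bincount(key)
            for k in np.flatnonzero(cnt):
                strain, rem = divmod(int(k), 2 * nres)
                lyso, resmask = divmod(rem, nres)
                self._bact_rows.append((it, strain, resmask, lyso, int(cnt[k])))
        functional = int((self.vir_cargo < 0).sum())
        self._total_rows.append(
            {
                "iteration": it,
                "n_bacteria": self.n_bacteria,
                "n_lysogens": int((self.reg.pro_gt[self.bact_gid] >= 0).sum()),
                "free_functional": functional,
                "free_transducing": self.n_virions - functional,
                "cum_transductions": self.cum_transductions,
                "cum_inductions": self.cum_inductions,
            }
        )

    def timeseries(self) -> TimeseriesRecord:
        drugs = self.reg.drugs

        def profile(mask: int) -> str:
            names = [d for d in drugs if self.reg.drug_bit[d] & mask]
            return "+".join(names) if names else "none"

        bact = pd.DataFrame(
            self._bact_rows,
            columns=["iteration", "strain_id", "res_mask", "lysogen", "count"],
        )
        if len(bact):
            bact["strain"] = bact["strain_id"].map(lambda s: self.strains[s])
            bact["resistance"] = bact["res_mask"].map(profile)
            bact["lysogen"] = bact["lysogen"].astype(bool)
            bact = bact[["iteration", "strain", "resistance", "lysogen", "count"]]
        else:
            bact = pd.DataFrame(
                columns=["iteration", "strain", "resistance", "lysogen", "count"]
            )
        totals = pd.DataFrame(self._total_rows)
        return TimeseriesRecord(bacteria=bact, totals=totals)

    # -- outcome ------------------------------------------------------------------------

    def n_prophages_alive(self) -> int:
        if not self.n_bacteria:
            return 0
        return int((self.reg.pro_gt[self.bact_gid] >= 0).sum())

    def outcome(self, seed: int) -> OutcomeSummary:
        phage = (self.vir_cargo < 0).any() or self.n_prophages_alive() > 0
        return OutcomeSummary(
            bacteria_survived=self.n_bacteria > 0,
            phage_survived=bool(phage),
            final_iteration=self.iteration,
            seed=seed,
        )

    # -- driver -------------------------------------------------------------------------

    def run(
        self,
        n_iterations: int,
        record: bool = True,
        fast_outcome: bool = True,
    ) -> None:
        """Advance ``n_iterations``.

        With ``record=False`` and ``fast_outcome=True``, a run whose bacteria
        have gone extinct is completed by projecting the remaining free-virion
        decay to the horizon in one binomial draw (exact in distribution for
        the outcome: with no hosts, virions can only decay).
        """
        target = self.iteration + n_iterations
        if record and self.iteration == 0:
            self.record()
        while self.iteration < target:
            if (
                fast_outcome
                and not record
                and self.n_bacteria == 0
            ):
                remaining = target - self.iteration
                keep_p = (1.0 - self.params.p_decay) ** remaining
                m = self.n_virions
                survive = self.rng.random(m) < keep_p
                self.vir_gt = self.vir_gt[survive]
                self.vir_cargo = self.vir_cargo[survive]
                self.vir_site = self.vir_site[survive]
                self.vir_age = self.vir_age[survive] + remaining
                self.iteration = target
                break
            self.step(record=record)


# ---------------------------------------------------------------------------
# replicate running
# ---------------------------------------------------------------------------


def replicate_seed(master_seed: int, k: int) -> np.random.Generator:
    """Counter-based replicate stream: replicate k is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, k]))


def run_replicates(
    runner: Callable[[np.random.Generator, int], OutcomeSummary],
    n_reps: int,
    master_seed: int,
) -> list[OutcomeSummary]:
    """Run ``runner`` under ``n_reps`` independent replicate streams."""
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    return [runner(replicate_seed(master_seed, k), k) for k in range(n_reps)]


def survival_fractions(outcomes: Sequence[OutcomeSummary]) -> dict[str, float]:
    n = len(outcomes)
    return {
        "bacteria": sum(o.bacteria_survived for o in outcomes) / n,
        "phage": sum(o.phage_survived for o in outcomes) / n,
        "joint": sum(o.joint_survival for o in outcomes) / n,
    }


def series_median_ci(
    series: Sequence[pd.DataFrame], columns: Iterable[str]
) -> pd.DataFrame:
    """Per-iteration median and central 95% interval across replicate totals."""
    stacked = pd.concat(series, keys=range(len(series)), names=["replicate"])
    out = {}
    g = stacked.groupby("iteration")
    for c in columns:
        out[f"{c}_median"] = g[c].median()
        out[f"{c}_lo"] = g[c].quantile(0.025)
        out[f"{c}_hi"] = g[c].quantile(0.975)
    return pd.DataFrame(out).reset_index()


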