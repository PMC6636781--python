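"""Interned genome bookkeeping for the lattice engine.

The engine never mutates genomes: a bacterium's genome changes only through
lysogenization (prophage appended) or transduction (cargo appended), and
offspring share the parent's genome.  The population therefore contains few
*distinct* genomes, which are interned here under integer ids.  Per-genome
quantities the scheduler needs every iteration (active-resistance bitmask,
number of active resistance genes, immunity bitmask, prophage genotypes,
packageable-locus count) live in flat numpy arrays indexed by genome id, so
the hot loop is pure array arithmetic.

Headful packaging needs, per donor genome, the drug content of every
circular window of packageable (non-prophage) slots.  To keep this off the
object layer, the registry maintains per-genome slot metadata (active-drug
bit and filled flag per packageable slot) built incrementally: a transduced
genome's metadata is its parent's plus the donor window slice.  Full
:class:`~phagesim.core.Genome` objects are materialized lazily, from a recipe
tree rooted at the founders, only when snapshots (or tests) ask for them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Gene, Genome, InvalidParameterError, PhageGenotype

_GROW = 256


class GenomeRegistry:
    """Interning table for genomes, transducing cargo and derived arrays."""

    def __init__(
        self,
        drugs: Sequence[str],
        genotypes: Sequence[PhageGenotype],
        prophage_span: int = 5,
    ) -> None:
        self.drugs = list(drugs)
        if len(self.drugs) > 8:
            raise InvalidParameterError("at most 8 distinct drugs are supported")
        self.drug_bit = {d: 1 << i for i, d in enumerate(self.drugs)}
        self.genotypes = list(genotypes)
        self.gt_index = {g.name: i for i, g in enumerate(self.genotypes)}
        groups = sorted({g.immunity_group for g in self.genotypes})
        self.group_bit = {g: 1 << i for i, g in enumerate(groups)}
        self.prophage_span = prophage_span
        headfuls = {g.headful for g in self.genotypes}
        if len(headfuls) > 1:
            raise InvalidParameterError(
                "all phage genotypes in one simulation must share the headful size"
            )
        self.headful = headfuls.pop() if headfuls else 0

        # genotype parameter arrays (indexed by genotype id)
        self.gt_p_gt = np.array([g.p_gt for g in self.genotypes])
        self.gt_burst = np.array([g.burst_size for g in self.genotypes], dtype=np.int64)
        self.gt_p_lys = np.array(
            [g.p_lys if g.lifestyle == "temperate" else 0.0 for g in self.genotypes]
        )
        self.gt_k_lys = np.array([g.k_lys for g in self.genotypes])
        self.gt_alpha = np.array([g.alpha for g in self.genotypes])
        self.gt_kappa = np.array([g.kappa for g in self.genotypes])
        self.gt_group = np.array(
            [self.group_bit[g.immunity_group] for g in self.genotypes], dtype=np.uint8
        )

        # per-genome arrays (grown on demand)
        self._n = 0
        self._cap = _GROW
        self.res_mask = np.zeros(self._cap, dtype=np.uint8)
        self.k_active = np.zeros(self._cap, dtype=np.int32)
        self.imm_mask = np.zeros(self._cap, dtype=np.uint8)
        self.n_pack = np.zeros(self._cap, dtype=np.int64)
        self.pro_gt = np.full(self._cap, -1, dtype=np.int16)  # first prophage
        self.pro_gt2 = np.full(self._cap, -1, dtype=np.int16)  # second (rare)

        self._recipes: list[tuple] = []
        self._materialized: dict[int, Genome] = {}
        self._intern: dict[tuple, int] = {}
        # per-genome packageable-slot metadata: active-drug bit / filled flag
        self._pk_bit: dict[int, np.ndarray] = {}
        self._pk_filled: dict[int, np.ndarray] = {}
        self._windows: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

        # cargo table: only windows actually packaged are interned
        self._cargo_key: dict[tuple[int, int], int] = {}
        self.cargo_donor: list[int] = []
        self.cargo_start: list[int] = []
        self.cargo_mask: list[int] = []
        self.cargo_k: list[int] = []
        self.cargo_len: list[int] = []  # genes (filled slots) in the window

        self._fitness_cache: tuple[float, int, np.ndarray] | None = None

    # -- genome creation ----------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return self._n

    def _new_id(self) -> int:
        gid = self._n
        self._n += 1
        if self._n > self._cap:
            self._cap *= 2
            for name in ("res_mask", "k_active", "imm_mask", "n_pack", "pro_gt", "pro_gt2"):
                old = getattr(self, name)
                fill = -1 if name.startswith("pro_gt") else 0
                new = np.full(self._cap, fill, dtype=old.dtype)
                new[: self._n - 1] = old[: self._n - 1]
                setattr(self, name, new)
        return gid

    def add_founder(self, genome: Genome) -> int:
        gid = self._new_id()
        self._recipes.append(("founder",))
        self._materialized[gid] = genome
        mask = 0
        for d in genome.active_drugs():
            mask |= self.drug_bit[d]
        imm = 0
        for g in genome.immunity_groups():
            imm |= self.group_bit[g]
        gts = [self.gt_index[p.genotype.name] for p in genome.prophages]
        pk = genome.packageable_loci
        self.res_mask[gid] = mask
        self.k_active[gid] = genome.n_active_resistance()
        self.imm_mask[gid] = imm
        self.n_pack[gid] = len(pk)
        self.pro_gt[gid] = gts[0] if gts else -1
        self.pro_gt2[gid] = gts[1] if len(gts) > 1 else -1
        bit = np.zeros(len(pk), dtype=np.int64)
        filled = np.zeros(len(pk), dtype=bool)
        for i, locus in enumerate(pk):
            g = genome.loci[locus]
            if g is None:
                continue
            filled[i] = True
            if g.category == "resistance" and g.active:
                bit[i] = self.drug_bit[g.drug]
        self._pk_bit[gid] = bit
        self._pk_filled[gid] = filled
        self._fitness_cache = None
        return gid

    def lysogenize(self, gid: int, gt_id: int) -> int:
        """Genome id after integrating a prophage of genotype ``gt_id``."""
        key = ("lys", gid, gt_id)
        hit = self._intern.get(key)
        if hit is not None:
            return hit
        if self.imm_mask[gid] & self.gt_group[gt_id]:
            raise InvalidParameterError(
                "repeat lysogenization by the same immunity group is blocked"
            )
        new = self._new_id()
        self._recipes.append(("lys", gid, gt_id))
        self._intern[key] = new
        self.res_mask[new] = self.res_mask[gid]
        self.k_active[new] = self.k_active[gid]
        self.imm_mask[new] = self.imm_mask[gid] | self.gt_group[gt_id]
        self.n_pack[new] = self.n_pack[gid]  # prophage slots are not packageable
        if self.pro_gt[gid] < 0:
            self.pro_gt[new], self.pro_gt2[new] = gt_id, -1
        else:
            self.pro_gt[new], self.pro_gt2[new] = self.pro_gt[gid], gt_id
        self._pk_bit[new] = self._pk_bit[gid]
        self._pk_filled[new] = self._pk_filled[gid]
        self._fitness_cache = None
        return new

    def transduce(self, gid: int, cargo_id: int) -> int:
        """Genome id after recombining ``cargo_id`` into genome ``gid``."""
        key = ("tdx", gid, cargo_id)
        hit = self._intern.get(key)
        if hit is not None:
            return hit
        new = self._new_id()
        self._recipes.append(("tdx", gid, cargo_id))
        self._intern[key] = new
        self.res_mask[new] = self.res_mask[gid] | self.cargo_mask[cargo_id]
        self.k_active[new] = self.k_active[gid] + self.cargo_k[cargo_id]
        self.imm_mask[new] = self.imm_mask[gid]
        self.n_pack[new] = self.n_pack[gid] + self.cargo_len[cargo_id]
        self.pro_gt[new] = self.pro_gt[gid]
        self.pro_gt2[new] = self.pro_gt2[gid]
        donor = self.cargo_donor[cargo_id]
        start = self.cargo_start[cargo_id]
        dbit, dfill = self._pk_bit[donor], self._pk_filled[donor]
        h = min(self.headful, len(dbit))
        idx = (start + np.arange(h)) % len(dbit)
        # only the filled slots of the window are appended to the genome
        keep = dfill[idx]
        self._pk_bit[new] = np.concatenate([self._pk_bit[gid], dbit[idx][keep]])
        self._pk_filled[new] = np.concatenate(
            [self._pk_filled[gid], np.ones(int(keep.sum()), dtype=bool)]
        )
        self._fitness_cache = None
        return new

    # -- headful packaging support --------------------------------------------

    def windows(self, gid: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-start summaries of the headful windows of donor genome ``gid``.

        Returns ``(mask, k, length)`` arrays over the ``n_pack[gid]`` circular
        start positions: bitmask of drugs with an active resistance gene in
        the window, count of active resistance genes, and count of genes
        (filled slots).
        """
        hit = self._windows.get(gid)
        if hit is not None:
            return hit
        bit = self._pk_bit[gid]
        filled = self._pk_filled[gid]
        n = len(bit)
        h = min(self.headful, n)
        idx = np.arange(n)
        cf = np.concatenate([[0], np.cumsum(np.concatenate([filled, filled]))])
        length = (cf[idx + h] - cf[idx]).astype(np.int32)
        act = (bit != 0).astype(np.int64)
        ca = np.concatenate([[0], np.cumsum(np.concatenate([act, act]))])
        k = (ca[idx + h] - ca[idx]).astype(np.int32)
        mask = np.zeros(n, dtype=np.uint8)
        present = np.unique(bit[bit != 0])
        for b in present:
            ind = (bit == b).astype(np.int64)
            c = np.concatenate([[0], np.cumsum(np.concatenate([ind, ind]))])
            has = (c[idx + h] - c[idx]) > 0
            mask |= np.where(has, np.uint8(b), np.uint8(0)).astype(np.uint8)
        out = (mask, k, length)
        self._windows[gid] = out
        return out

    def intern_cargo(self, donor: int, start: int) -> int:
        """Cargo id of the headful window of ``donor`` starting at ``start``."""
        key = (donor, start)
        hit = self._cargo_key.get(key)
        if hit is not None:
            return hit
        mask, k, length = self.windows(donor)
        cid = len(self.cargo_donor)
        self._cargo_key[key] = cid
        self.cargo_donor.append(donor)
        self.cargo_start.append(start)
        self.cargo_mask.append(int(mask[start]))
        self.cargo_k.append(int(k[start]))
        self.cargo_len.append(int(length[start]))
        return cid

    def cargo_genes(self, cargo_id: int) -> tuple[Gene, ...]:
        """Materialize the gene content of an interned cargo window."""
        donor = self.cargo_donor[cargo_id]
        start = self.cargo_start[cargo_id]
        genome = self.genome(donor)
        h = min(self.headful, len(genome.packageable_loci))
        return genome.window(start, h)

    def cargo_is_transducing(self, cargo_ids: np.ndarray) -> np.ndarray:
        return np.asarray(cargo_ids) >= 0

    # -- materialization ----------------------------------------------------

    def genome(self, gid: int) -> Genome:
        """Materialize the full Genome object for ``gid`` (memoized)."""
        hit = self._materialized.get(gid)
        if hit is not None:
            return hit
        recipe = self._recipes[gid]
        if recipe[0] == "lys":
            _, parent, gt_id = recipe
            g = self.genome(parent).with_prophage(
                self.genotypes[gt_id], span=self.prophage_span
            )
        else:
            _, parent, cargo_id = recipe
            g = self.genome(parent).with_cargo(self.cargo_genes(cargo_id))
        self._materialized[gid] = g
        return g

    # -- fitness -------------------------------------------------------------

    def fitness_weights(self, cost: float) -> np.ndarray:
        """(1 - cost)^k_active for every interned genome."""
        cache = self._fitness_cache
        if cache is not None and cache[0] == cost and cache[1] == self._n:
            return cache[2]
        w = (1.0 - cost) ** self.k_active[: self._n].astype(float)
        self._fitness_cache = (cost, self._n, w)
        return w

    def drug_bits(self, drugs) -> int:
        bits = 0
        for d in drugs:
            bits |= self.drug_bit[d]
        return bits
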