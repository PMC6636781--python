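"""Declarative experiment definitions and initial-population generators.

The central in-silico experiment is a two-phase protocol: a phage is first
propagated on an antibiotic-resistant donor population (phase 1); a sample of
the resulting lysate — functional virions plus any generalized-transducing
particles — is then introduced to a fresh, antibiotic-sensitive population,
and an antibiotic pulse is applied partway through (phase 2).  Four scenarios
cross phage lifestyle (temperate/virulent) with transducing ability
(p_gt > 0 / p_gt = 0):

    S1_temperate_GT     temperate, transducing
    S2_temperate_nonGT  temperate, non-transducing
    S3_virulent_GT      virulent, transducing
    S4_virulent_nonGT   virulent, non-transducing

A second design (FIG6) mixes two lysogens of the same temperate transducing
phage, each carrying a different active resistance gene (plus a silent copy
of the other), and exposes the culture to both drugs: marker exchange via
transducing particles released by prophage induction is the only route to
double resistance.  Variants: S4A_no_prophage (no prophages, no transfer
channel), S4B/S4C (no antibiotics, spontaneous induction 1e-5 / 1e-3).

Also includes the lysate-capacity arithmetic: how much bacterial DNA a
millilitre of phage lysate can carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import Genome, InvalidParameterError, PhageGenotype, build_genome
from .lattice import (
    Lattice,
    OutcomeSummary,
    SimulationParams,
    TimeseriesRecord,
    replicate_seed,
    survival_fractions,
)
from .registry import GenomeRegistry

logger = logging.getLogger(__name__)

SCENARIO_IDS = (
    "S1_temperate_GT",
    "S2_temperate_nonGT",
    "S3_virulent_GT",
    "S4_virulent_nonGT",
    "FIG6_two_lysogens",
    "S4A_no_prophage",
    "S4B_no_drug_low_induction",
    "S4C_no_drug_high_induction",
)

#: default probability that a packaged virion is a transducing particle, for
#: the transducing scenarios (desk-scale calibration: with a 500-virion sample
#: and a headful/genome ratio of 0.1 this puts ~5 marker-carrying particles in
#: the phase-2 inoculum)
DEFAULT_P_GT = 0.1


@dataclass(frozen=True)
class StrainSpec:
    """Founder-population recipe: genome layout plus optional prophage."""

    name: str
    genome_size: int = 100
    markers: tuple[tuple[str, bool, int], ...] = ()  # (drug, active, locus)
    prophage_of: Optional[str] = None  # genotype name


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: str
    width: int = 50
    height: int = 50
    phase1_iterations: int = 10
    phase2_antibiotic_iteration: int = 7
    total_iterations: int = 100
    n_sample: int = 500
    occupancy: float = 0.1  # initial fraction of occupied sites
    initial_moi: float = 1.0
    drug: str = "CAM"
    antibiotic_duration: Optional[int] = None  # None = persistent to the end
    donor_genome_size: int = 100
    recipient_genome_size: int = 100
    p_gt: float = DEFAULT_P_GT
    burst_size: int = 50
    headful: int = 10
    p_lys: float = 0.8
    k_lys: float = 2.0
    alpha: float = 1e5
    kappa: float = 0.4
    params: SimulationParams = field(default_factory=SimulationParams)

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def n_initial_bacteria(self) -> int:
        return int(round(self.occupancy * self.n_sites))

    def genotype(self) -> PhageGenotype:
        lifestyle = "virulent" if self.scenario_id.startswith(("S3", "S4_")) else "temperate"
        p_gt = self.p_gt
        if self.scenario_id in ("S2_temperate_nonGT", "S4_virulent_nonGT"):
            p_gt = 0.0
        return PhageGenotype(
            name="phi",
            lifestyle=lifestyle,
            p_gt=p_gt,
            burst_size=self.burst_size,
            headful=self.headful,
            immunity_group="A",
            p_lys=self.p_lys,
            k_lys=self.k_lys,
            alpha=self.alpha,
            kappa=self.kappa,
        )


def scenario_config(scenario_id: str, **overrides) -> ScenarioConfig:
    """Default configuration for a named scenario, with keyword overrides."""
    if scenario_id not in SCENARIO_IDS:
        raise InvalidParameterError(
            f"unknown scenario {scenario_id!r}; choose from {SCENARIO_IDS}"
        )
    defaults: dict = {}
    if scenario_id in ("FIG6_two_lysogens", "S4A_no_prophage"):
        # spontaneous induction 1e-3: the level at which pre-exposure marker
        # exchange between co-cultured lysogens is appreciable
        defaults["alpha"] = 1e3
    if scenario_id == "S4B_no_drug_low_induction":
        defaults["alpha"] = 1e5
    if scenario_id == "S4C_no_drug_high_induction":
        defaults["alpha"] = 1e3
    defaults.update(overrides)
    return ScenarioConfig(scenario_id=scenario_id, **defaults)


# ---------------------------------------------------------------------------
# population initializers (the synthetic-data generators)
# ---------------------------------------------------------------------------


def init_population(
    spec: StrainSpec, n_cells: int, lattice: Lattice
) -> int:
    """Build the founder genome for ``spec``, intern it, and place ``n_cells``
    bacteria on random free sites of ``lattice``.  Returns the genome id."""
    reg = lattice.reg
    prophage = None
    if spec.prophage_of is not None:
        prophage = reg.genotypes[reg.gt_index[spec.prophage_of]]
    genome = build_genome(
        strain=spec.name,
        size=spec.genome_size,
        markers=spec.markers,
        prophage_of=prophage,
        prophage_span=lattice.params.prophage_span,
    )
    gid = reg.add_founder(genome)
    lattice.place_bacteria(gid, spec.name, n_cells)
    return gid


def donor_spec(config: ScenarioConfig) -> StrainSpec:
    """Antibiotic-resistant donor: one active resistance gene mid-genome."""
    return StrainSpec(
        name="donor",
        genome_size=config.donor_genome_size,
        markers=((config.drug, True, config.donor_genome_size // 2),),
    )


def recipient_spec(config: ScenarioConfig) -> StrainSpec:
    """Antibiotic-sensitive recipient: an inactive (silent) copy of the
    resistance gene — the phenotype can only be acquired by transduction."""
    return StrainSpec(
        name="recipient",
        genome_size=config.recipient_genome_size,
        markers=((config.drug, False, config.recipient_genome_size // 2),),
    )


def _schedule(
    drugs: frozenset[str], start: int, total: int, duration: Optional[int]
) -> dict[int, frozenset[str]]:
    stop = total if duration is None else min(total, start + duration)
    return {i: drugs for i in range(start, stop)}


# ---------------------------------------------------------------------------
# two-phase protocol (scenarios S1-S4)
# ---------------------------------------------------------------------------


@dataclass
class TwoPhaseResult:
    phase1: TimeseriesRecord
    phase2: TimeseriesRecord
    outcome: OutcomeSummary
    n_sampled_functional: int
    n_sampled_transducing: int
    final_population: int
    lattice: Optional[Lattice]  # final phase-2 state (dropped by the
    # replicate driver unless keep_state=True — registries are large)


def run_two_phase(
    config: ScenarioConfig,
    seed: int | np.random.Generator,
    record: bool = True,
) -> TwoPhaseResult:
    """Run one replicate of the two-phase protocol.

    Phase 1: resistant donors at 10% occupancy, free phage at ``initial_moi``;
    run ``phase1_iterations``; draw ``n_sample`` free virions uniformly
    without replacement (all of them if fewer exist).  Phase 2: fresh lattice
    of sensitive recipients; introduce the sample; apply the antibiotic from
    ``phase2_antibiotic_iteration`` (phase-2 clock); run to
    ``total_iterations``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = -1 if isinstance(seed, np.random.Generator) else int(seed)
    genotype = config.genotype()
    reg = GenomeRegistry(
        drugs=[config.drug], genotypes=[genotype],
        prophage_span=config.params.prophage_span,
    )

    # ---- phase 1: propagate phage on the resistant donor population
    lat1 = Lattice(config.width, config.height, reg, config.params, rng)
    init_population(donor_spec(config), config.n_initial_bacteria, lat1)
    n_phage = int(round(config.initial_moi * config.n_initial_bacteria))
    lat1.seed_functional("phi", n_phage)
    lat1.run(config.phase1_iterations, record=record)

    # ---- sample the lysate
    n_free = lat1.n_virions
    if n_free == 0:
        logger.warning(
            "phase-1 lysate of %s is empty; proceeding with an empty sample",
            config.scenario_id,
        )
        take = np.zeros(0, dtype=np.int64)
    elif n_free <= config.n_sample:
        take = np.arange(n_free)
    else:
        take = rng.choice(n_free, size=config.n_sample, replace=False)
    gt_ids = lat1.vir_gt[take]
    cargo_ids = lat1.vir_cargo[take]
    n_trans = int((cargo_ids >= 0).sum())

    # ---- phase 2: sensitive recipients + sampled virions + antibiotic pulse
    phase2_iters = config.total_iterations - config.phase1_iterations
    schedule = _schedule(
        frozenset([config.drug]),
        config.phase2_antibiotic_iteration,
        phase2_iters,
        config.antibiotic_duration,
    )
    lat2 = Lattice(config.width, config.height, reg, config.params, rng, schedule)
    init_population(recipient_spec(config), config.n_initial_bacteria, lat2)
    lat2.seed_virions(gt_ids, cargo_ids)
    lat2.run(phase2_iters, record=record)

    return TwoPhaseResult(
        phase1=lat1.timeseries(),
        phase2=lat2.timeseries(),
        outcome=lat2.outcome(seed_label),
        n_sampled_functional=len(take) - n_trans,
        n_sampled_transducing=n_trans,
        final_population=lat2.n_bacteria,
        lattice=lat2,
    )


# ---------------------------------------------------------------------------
# two-lysogen gene shuffling (FIG6 and its controls)
# ---------------------------------------------------------------------------


@dataclass
class GeneShufflingResult:
    series: TimeseriesRecord
    outcome: OutcomeSummary
    double_resistant: "np.ndarray"  # per recorded iteration
    final_double_resistant: int
    final_population: int
    lattice: Optional[Lattice]


def run_gene_shuffling(
    config: ScenarioConfig,
    seed: int | np.random.Generator,
    record: bool = True,
) -> GeneShufflingResult:
    """Run one replicate of the two-lysogen marker-exchange experiment.

    Two strains, each lysogenic for the same temperate transducing phage
    (same immunity group), carry complementary chromosomal markers placed
    maximally distant from the prophage integration region: strain A an
    active ERM resistance gene, strain B an active CAM resistance gene, each
    with a silent copy of the other.  FIG6 applies both drugs at iteration
    10; S4A removes the prophages; S4B/S4C apply no drugs and set the
    spontaneous induction rate to 1e-5 / 1e-3.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = -1 if isinstance(seed, np.random.Generator) else int(seed)
    genotype = config.genotype()
    reg = GenomeRegistry(
        drugs=["CAM", "ERM"], genotypes=[genotype],
        prophage_span=config.params.prophage_span,
    )
    lysogenic = config.scenario_id != "S4A_no_prophage"
    with_drugs = config.scenario_id in ("FIG6_two_lysogens", "S4A_no_prophage")
    schedule = (
        _schedule(frozenset(["CAM", "ERM"]), 10, config.total_iterations,
                  config.antibiotic_duration)
        if with_drugs
        else {}
    )
    lat = Lattice(config.width, config.height, reg, config.params, rng, schedule)
    L = config.donor_genome_size
    mid = L // 2
    prophage = "phi" if lysogenic else None
    spec_a = StrainSpec(
        name="lysogen_A",
        genome_size=L,
        markers=(("ERM", True, mid), ("CAM", False, mid - 1)),
        prophage_of=prophage,
    )
    spec_b = StrainSpec(
        name="lysogen_B",
        genome_size=L,
        markers=(("CAM", True, mid), ("ERM", False, mid - 1)),
        prophage_of=prophage,
    )
    half = config.n_initial_bacteria // 2
    init_population(spec_a, half, lat)
    init_population(spec_b, config.n_initial_bacteria - half, lat)
    lat.run(config.total_iterations, record=record)

    both = reg.drug_bits(["CAM", "ERM"])
    if record:
        totals = lat.timeseries()
        bact = totals.bacteria
        dbl = (
            bact[bact["resistance"] == "CAM+ERM"]
            .groupby("iteration")["count"]
            .sum()
            .reindex(range(config.total_iterations + 1), fill_value=0)
            .to_numpy()
        )
    else:
        totals = lat.timeseries()
        dbl = np.zeros(0, dtype=np.int64)
    final_dbl = (
        int(((reg.res_mask[lat.bact_gid] & both) == both).sum())
        if lat.n_bacteria
        else 0
    )
    return GeneShufflingResult(
        series=totals,
        outcome=lat.outcome(seed_label),
        double_resistant=dbl,
        final_double_resistant=final_dbl,
        final_population=lat.n_bacteria,
        lattice=lat,
    )


# ---------------------------------------------------------------------------
# replicate drivers
# ---------------------------------------------------------------------------


def run_scenario(
    config: ScenarioConfig, seed: int | np.random.Generator, record: bool = True
):
    if config.scenario_id in (
        "FIG6_two_lysogens",
        "S4A_no_prophage",
        "S4B_no_drug_low_induction",
        "S4C_no_drug_high_induction",
    ):
        return run_gene_shuffling(config, seed, record=record)
    return run_two_phase(config, seed, record=record)


def run_scenario_replicates(
    config: ScenarioConfig,
    n_reps: int,
    master_seed: int,
    record: bool = False,
    keep_state: bool = False,
) -> tuple[list, dict[str, float]]:
    """Run ``n_reps`` independent replicates (counter-derived seeds) and
    return (results, survival fractions).  Unless ``keep_state`` is set, the
    per-replicate lattices are dropped (their genome registries can reach
    tens of MB each); summary fields like ``final_population`` remain."""
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    results = []
    for k in range(n_reps):
        r = run_scenario(config, replicate_seed(master_seed, k), record=record)
        if not keep_state:
            r.lattice = None
        results.append(r)
    fractions = survival_fractions([r.outcome for r in results])
    return results, fractions


# ---------------------------------------------------------------------------
# lysate-capacity arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LysateCapacityInput:
    """Worked-example inputs: a lysate of ``pfu_per_ml`` infective particles
    with ``transducing_ratio`` transducing particles per infective particle,
    each carrying up to ``headful_bp`` of bacterial DNA, against a reference
    genome of ``genome_bp``."""

    pfu_per_ml: float
    transducing_ratio: float
    headful_bp: float
    genome_bp: float = 2.8e6

    def __post_init__(self) -> None:
        for name in ("pfu_per_ml", "headful_bp", "genome_bp"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.transducing_ratio < 0:
            raise InvalidParameterError("transducing_ratio must be >= 0")


@dataclass(frozen=True)
class LysateCapacity:
    transducing_per_ml: float
    transduced_bp_per_ml: float
    genome_equivalents_per_ml: float


def lysate_capacity(inp: LysateCapacityInput) -> LysateCapacity:
    """Exact arithmetic on the DNA-carrying capacity of a phage lysate."""
    t = inp.pfu_per_ml * inp.transducing_ratio
    bp = t * inp.headful_bp
    return LysateCapacity(
        transducing_per_ml=t,
        transduced_bp_per_ml=bp,
        genome_equivalents_per_ml=bp / inp.genome_bp,
    )
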