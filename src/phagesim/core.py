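"""Domain types and per-event mechanistic kernels.

Bacteria carry explicit gene-level genomes: circular ordered arrays of gene
slots holding essential genes, accessory genes and antibiotic-resistance genes
(active or inactive), plus integrated prophages.  Phages are temperate or
virulent and may produce generalized-transducing particles: capsids filled by
the headful mechanism with a random window of host DNA instead of phage DNA.
Such particles inject DNA but can never replicate, lyse or lysogenize.

All kernels are pure functions of their inputs and an explicit
``numpy.random.Generator``; the lattice scheduler composes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Gene",
    "Prophage",
    "Genome",
    "PhageGenotype",
    "Virion",
    "Bacterium",
    "induction_probability",
    "decide_lifecycle",
    "package_burst",
    "resolve_adsorption",
    "inject_transduced",
    "fitness",
    "antibiotic_action",
    "build_genome",
]

GeneCategory = Literal["essential", "accessory", "resistance"]
Lifestyle = Literal["temperate", "virulent"]


class InvalidParameterError(ValueError):
    """A kernel was called with an out-of-range or non-finite parameter."""


@dataclass(frozen=True)
class Gene:
    """One gene slot occupant.

    ``drug`` and ``active`` are meaningful only for resistance genes: an
    *inactive* resistance gene is a silent copy that does not confer a
    phenotype and (by model assumption) can never be activated by mutation —
    resistance must arrive horizontally, already active.  ``provenance`` is
    the strain-of-origin tag and is preserved verbatim through packaging and
    recombination so genome snapshots can colour DNA by origin.
    """

    gene_id: str
    category: GeneCategory
    drug: Optional[str] = None
    active: Optional[bool] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.category == "resistance":
            if self.drug is None:
                raise InvalidParameterError(
                    f"resistance gene {self.gene_id!r} must name a drug"
                )
            if self.active is None:
                object.__setattr__(self, "active", False)
        elif self.drug is not None:
            raise InvalidParameterError(
                f"gene {self.gene_id!r} ({self.category}) cannot carry drug={self.drug!r}"
            )


@dataclass(frozen=True)
class PhageGenotype:
    """Heritable phage parameters.

    p_gt          probability that a packaged virion is a transducing particle
    burst_size    virions released per lysis
    headful       capsid capacity, in genome slots
    p_lys         maximum lysogenization probability (temperate only)
    k_lys         half-saturation constant of the lysogeny decision, in units
                  of free virions in the Moore neighbourhood
    alpha, kappa  induction-function parameters; the zero-stress (spontaneous)
                  induction rate is 1/(1+alpha)
    """

    name: str
    lifestyle: Lifestyle
    p_gt: float = 0.1
    burst_size: int = 50
    headful: int = 10
    immunity_group: str = "A"
    p_lys: float = 0.8
    k_lys: float = 2.0
    alpha: float = 1e5
    kappa: float = 0.4

    def __post_init__(self) -> None:
        if self.lifestyle not in ("temperate", "virulent"):
            raise InvalidParameterError(f"unknown lifestyle {self.lifestyle!r}")
        if not 0.0 <= self.p_gt <= 1.0:
            raise InvalidParameterError(f"p_gt={self.p_gt} outside [0, 1]")
        if self.burst_size < 0:
            raise InvalidParameterError("burst_size must be >= 0")
        if self.headful < 0:
            raise InvalidParameterError("headful must be >= 0")
        if not 0.0 <= self.p_lys <= 1.0:
            raise InvalidParameterError(f"p_lys={self.p_lys} outside [0, 1]")
        if self.k_lys < 0:
            raise InvalidParameterError("k_lys must be >= 0")
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise InvalidParameterError("alpha must be finite and > 0")
        if not (self.kappa > 0 and math.isfinite(self.kappa)):
            raise InvalidParameterError("kappa must be finite and > 0")


@dataclass(frozen=True)
class Prophage:
    """A phage genome integrated in the host chromosome, spanning ``span``
    slots starting at ``start_locus`` (the spanned slots hold no bacterial
    genes and are skipped by headful packaging)."""

    genotype: PhageGenotype
    start_locus: int
    span: int = 5


@dataclass(frozen=True)
class Genome:
    """Circular ordered array of gene slots plus integrated prophages.

    Slot index arithmetic is modulo ``size``.  Offspring genomes are the
    parent object itself (no mutation); genomes change only on
    lysogenization (prophage slots appended) and transduction (cargo genes
    appended at the integration region).
    """

    loci: tuple[Optional[Gene], ...]
    prophages: tuple[Prophage, ...] = ()

    @property
    def size(self) -> int:
        return len(self.loci)

    @property
    def packageable_loci(self) -> tuple[int, ...]:
        """Indices of slots not occupied by prophage DNA, in circular order."""
        occupied = set()
        for p in self.prophages:
            occupied.update(range(p.start_locus, p.start_locus + p.span))
        return tuple(i for i in range(self.size) if i not in occupied)

    def active_drugs(self) -> frozenset[str]:
        return frozenset(
            g.drug
            for g in self.loci
            if g is not None and g.category == "resistance" and g.active and g.drug
        )

    def n_active_resistance(self) -> int:
        return sum(
            1
            for g in self.loci
            if g is not None and g.category == "resistance" and g.active
        )

    def immunity_groups(self) -> frozenset[str]:
        return frozenset(p.genotype.immunity_group for p in self.prophages)

    def window(self, start: int, headful: int) -> tuple[Gene, ...]:
        """The ``headful`` consecutive non-prophage slots beginning at circular
        position ``start`` of the packageable loci; empty slots carry nothing."""
        pk = self.packageable_loci
        if headful > len(pk):
            raise InvalidParameterError(
                f"headful {headful} exceeds the {len(pk)} packageable loci"
            )
        genes = []
        for j in range(headful):
            g = self.loci[pk[(start + j) % len(pk)]]
            if g is not None:
                genes.append(g)
        return tuple(genes)

    def with_prophage(self, genotype: PhageGenotype, span: int = 5) -> "Genome":
        """Integrate a prophage at the end of the slot array.

        A genome holds at most one prophage per immunity group; repeat
        lysogenization by the same group raises."""
        if genotype.immunity_group in self.immunity_groups():
            raise InvalidParameterError(
                f"genome already lysogenic for immunity group "
                f"{genotype.immunity_group!r}"
            )
        pro = Prophage(genotype=genotype, start_locus=self.size, span=span)
        return Genome(
            loci=self.loci + (None,) * span, prophages=self.prophages + (pro,)
        )

    def with_cargo(self, cargo: Sequence[Gene]) -> "Genome":
        """Recombine transduced cargo into the designated integration region
        (appended at the end of the slot array, provenance preserved)."""
        return Genome(loci=self.loci + tuple(cargo), prophages=self.prophages)


@dataclass(frozen=True)
class Virion:
    """A free phage particle.

    ``cargo_kind='phage_dna'`` is a functional virion; ``'bacterial_dna'`` is
    a defective generalized-transducing particle that injects its cargo but
    can never lysogenize, replicate or lyse a cell.
    """

    genotype: PhageGenotype
    cargo_kind: Literal["phage_dna", "bacterial_dna"] = "phage_dna"
    cargo: tuple[Gene, ...] = ()
    age: int = 0

    def __post_init__(self) -> None:
        if self.cargo_kind == "phage_dna" and self.cargo:
            raise InvalidParameterError("functional virions carry no bacterial cargo")
        if len(self.cargo) > self.genotype.headful:
            raise InvalidParameterError("cargo exceeds headful capacity")

    @property
    def is_transducing(self) -> bool:
        return self.cargo_kind == "bacterial_dna"


@dataclass(frozen=True)
class Bacterium:
    genome: Genome
    strain: str
    age: int = 0
    stress: float = 0.0

    @property
    def is_lysogen(self) -> bool:
        return bool(self.genome.prophages)

    def is_resistant_to(self, drug: str) -> bool:
        return drug in self.genome.active_drugs()


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def induction_probability(stress, alpha: float, kappa: float):
    """Per-iteration probability that a prophage switches to lytic replication.

    P(induce) = 1 / (1 + alpha * exp(-kappa * stress)).

    Strictly increasing in stress; the spontaneous (zero-stress) rate is
    1/(1+alpha), e.g. alpha=1e5 gives 1e-5 and alpha=1e3 gives 1e-3 per
    iteration.  Accepts scalar or array ``stress``.
    """
    if not (np.isfinite(alpha) and alpha > 0):
        raise InvalidParameterError("alpha must be finite and > 0")
    if not (np.isfinite(kappa) and kappa > 0):
        raise InvalidParameterError("kappa must be finite and > 0")
    s = np.asarray(stress, dtype=float)
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise InvalidParameterError("stress must be finite and >= 0")
    p = 1.0 / (1.0 + alpha * np.exp(-kappa * s))
    return float(p) if np.isscalar(stress) else p


def lysogenization_probability(genotype: PhageGenotype, n_local_free: int) -> float:
    """Saturating (Hill-1) probability of choosing the lysogenic cycle given
    the count of free virions in the infecting virion's Moore neighbourhood."""
    if n_local_free < 0:
        raise InvalidParameterError("n_local_free must be >= 0")
    if genotype.lifestyle == "virulent":
        return 0.0
    denom = n_local_free + genotype.k_lys
    if denom == 0.0:  # k_lys == 0 and no local phage
        return 0.0
    return genotype.p_lys * n_local_free / denom


def decide_lifecycle(
    genotype: PhageGenotype, n_local_free: int, rng: np.random.Generator
) -> Literal["lysogenize", "lyse"]:
    """Lytic/lysogenic decision of a productive infection.

    Virulent phages always lyse.  Temperate phages lysogenize with probability
    p_lys * n / (n + k_lys), which grows with the local concentration of free
    phage (a crowded neighbourhood signals scarce hosts).
    """
    p = lysogenization_probability(genotype, n_local_free)
    if p > 0.0 and rng.random() < p:
        return "lysogenize"
    return "lyse"


def package_burst(
    host_genome: Genome, genotype: PhageGenotype, rng: np.random.Generator
) -> list[Virion]:
    """Package the burst released by one lysing host.

    Returns exactly ``burst_size`` virions.  Each is independently a
    transducing particle with probability ``p_gt``; transducing cargo is the
    headful of consecutive non-prophage slots starting at a uniformly random
    position of the circular host genome, with the host's provenance tags.
    """
    pk = host_genome.packageable_loci
    if genotype.headful > len(pk):
        raise InvalidParameterError(
            f"headful {genotype.headful} exceeds the {len(pk)} packageable loci"
        )
    virions: list[Virion] = []
    n = len(pk)
    for _ in range(genotype.burst_size):
        if genotype.p_gt > 0.0 and rng.random() < genotype.p_gt:
            start = int(rng.integers(n))
            cargo = host_genome.window(start, genotype.headful)
            virions.append(
                Virion(genotype=genotype, cargo_kind="bacterial_dna", cargo=cargo)
            )
        else:
            virions.append(Virion(genotype=genotype))
    return virions


def inject_transduced(
    recipient: Bacterium,
    cargo: Sequence[Gene],
    p_recomb: float,
    rng: np.random.Generator,
) -> Bacterium:
    """Inject transduced cargo into a recipient.

    With probability ``p_recomb`` the cargo recombines into the genome
    (appended at the integration region, provenance preserved); an active
    resistance gene immediately confers phenotypic resistance, even alongside
    an inactive native copy.  Otherwise the genome is unchanged.
    """
    if not 0.0 <= p_recomb <= 1.0:
        raise InvalidParameterError("p_recomb must be in [0, 1]")
    if p_recomb > 0.0 and (p_recomb >= 1.0 or rng.random() < p_recomb):
        return replace(recipient, genome=recipient.genome.with_cargo(cargo))
    return recipient


def fitness(bacterium: Bacterium, cost_per_active_resistance: float) -> float:
    """Roulette-wheel reproduction weight: (1 - cost)^k with k the number of
    active resistance genes."""
    if not 0.0 <= cost_per_active_resistance < 1.0:
        raise InvalidParameterError("cost must be in [0, 1)")
    k = bacterium.genome.n_active_resistance()
    return (1.0 - cost_per_active_resistance) ** k


def antibiotic_action(
    bacterium: Bacterium,
    applied_drugs: Iterable[str],
    p_kill: float,
    stress_on_exposure: float,
    rng: np.random.Generator,
) -> tuple[bool, Bacterium]:
    """Apply this iteration's antibiotics to one bacterium.

    Returns ``(alive, updated)``.  Death (probability ``p_kill``) strikes if
    any applied drug lacks a matching *active* resistance gene.  Every cell
    exposed to at least one drug acquires ``stress_on_exposure`` (driving
    antibiotic-associated prophage induction); stress resets to zero on
    iterations without exposure.
    """
    drugs = frozenset(applied_drugs)
    if not drugs:
        return True, replace(bacterium, stress=0.0)
    exposed = replace(bacterium, stress=float(stress_on_exposure))
    if drugs - bacterium.genome.active_drugs():
        if rng.random() < p_kill:
            return False, exposed
    return True, exposed


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def build_genome(
    strain: str,
    size: int = 100,
    n_essential: Optional[int] = None,
    markers: Sequence[tuple[str, bool, int]] = (),
    prophage_of: Optional[PhageGenotype] = None,
    prophage_span: int = 5,
) -> Genome:
    """Construct a founder genome for a strain.

    ``size`` bacterial gene slots are filled with essential genes (80% by
    default), accessory genes, and one resistance gene per ``markers`` entry
    ``(drug, active, locus)``.  If ``prophage_of`` is given the genome is
    founded as a lysogen (prophage slots appended after the bacterial slots,
    so a marker at ``size // 2`` sits maximally distant from the integration
    region).
    """
    if size < 1:
        raise InvalidParameterError("genome size must be >= 1")
    if n_essential is None:
        n_essential = int(round(0.8 * size))
    loci: list[Optional[Gene]] = []
    for i in range(size):
        cat: GeneCategory = "essential" if i < n_essential else "accessory"
        loci.append(Gene(gene_id=f"{strain}_{cat[:3]}_{i}", category=cat, provenance=strain))
    for drug, active, locus in markers:
        if not 0 <= locus < size:
            raise InvalidParameterError(f"marker locus {locus} outside genome")
        loci[locus] = Gene(
            gene_id=f"{strain}_{drug}_res",
            category="resistance",
            drug=drug,
            active=active,
            provenance=strain,
        )
    genome = Genome(loci=tuple(loci))
    if prophage_of is not None:
        genome = genome.with_prophage(prophage_of, span=prophage_span)
    return genome


# ---------------------------------------------------------------------------
# object-level adsorption resolution (the lattice engine implements the same
# rules in vectorized form; this kernel is the unit-testable reference)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdsorptionResult:
    event: Literal["blocked", "transduced", "lysogenized", "lysed"]
    bacterium: Optional[Bacterium]  # updated cell, or None if it died
    burst: tuple[Virion, ...] = ()


def resolve_adsorption(
    bacterium: Bacterium,
    virion: Virion,
    n_local_free: int,
    rng: np.random.Generator,
    p_recomb: float = 1.0,
    prophage_span: int = 5,
) -> AdsorptionResult:
    """Resolve one successfully adsorbed virion on a co-located bacterium.

    Transducing particles inject their cargo regardless of superinfection
    immunity (the repressor blocks phage replication, not DNA injection) and
    are always consumed.  Functional virions are blocked (and lost) on hosts
    lysogenic for the same immunity group; on susceptible hosts they trigger
    the lytic/lysogenic decision.
    """
    if virion.is_transducing:
        updated = inject_transduced(bacterium, virion.cargo, p_recomb, rng)
        return AdsorptionResult("transduced", updated)
    if virion.genotype.immunity_group in bacterium.genome.immunity_groups():
        return AdsorptionResult("blocked", bacterium)
    if decide_lifecycle(virion.genotype, n_local_free, rng) == "lysogenize":
        genome = bacterium.genome.with_prophage(virion.genotype, span=prophage_span)
        return AdsorptionResult("lysogenized", replace(bacterium, genome=genome))
    burst = package_burst(bacterium.genome, virion.genotype, rng)
    return AdsorptionResult("lysed", None, tuple(burst))
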