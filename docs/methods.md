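# Methods

## The model

`phagesim` is a discrete-time, individual-based model of a community of
bacteria and bacteriophages on a toroidal W x H lattice.  Each site holds at
most one bacterium and any number of free virions.  The environment is
well-mixed: all positions are re-randomized at the start of every iteration,
so space enters only through two local mechanisms — single-site occupancy
(free space is the bacterial resource) and the Moore neighbourhood (the 8
surrounding sites), which mediates both reproduction competition and the
local free-phage concentration that drives the lysogeny decision.

### Genomes

Bacteria carry explicit genomes: circular ordered arrays of gene slots.
Slots hold essential genes, accessory genes, or antibiotic-resistance genes;
each gene records its strain of origin (provenance), which is preserved
verbatim through packaging and recombination so that genome snapshots can
colour DNA by origin.  A resistance gene is either *active* (confers
phenotypic resistance to its drug) or *inactive* (a silent copy).  Mutation
is disabled: an inactive gene can never activate spontaneously, so
resistance can only be gained horizontally, already active.  Offspring
genomes are exact copies of the parent.  Genome slots are abstract units of
gene content, not nucleotides; at the default headful of 10 slots against a
genome of 100 slots, one slot corresponds loosely to a few kilobases of a
small bacterial chromosome.

Integrated prophages occupy a run of slots appended at the integration
region; these slots are skipped by headful packaging.  A genome holds at
most one prophage per immunity group.

### Phages

A phage genotype is temperate or virulent and is parameterized by:

| parameter | meaning | default |
|---|---|---|
| `p_gt` | probability a packaged virion is a generalized-transducing particle | 0.1 |
| `burst_size` | virions released per lysis | 50 |
| `headful` | capsid capacity in genome slots | 10 |
| `p_lys` | maximal lysogenization probability (temperate only) | 0.8 |
| `k_lys` | half-saturation of the lysogeny decision (local free virions) | 2 |
| `alpha` | induction offset; spontaneous induction rate is 1/(1+alpha) | 1e5 |
| `kappa` | induction stress sensitivity (per stress unit) | 0.4 |

**Lysogeny decision.**  A productive infection by a temperate phage
lysogenizes with probability `p_lys * n / (n + k_lys)`, where `n` counts the
free virions in the infecting virion's Moore neighbourhood: a crowded
neighbourhood signals scarce hosts and favours the prophage state.  Virulent
phages always lyse.

**Induction.**  A prophage switches to lytic replication with per-iteration
probability

    P(induce | stress s) = 1 / (1 + alpha * exp(-kappa * s)),

a sigmoid chosen so that the zero-stress (spontaneous) rate is exactly
`1/(1+alpha)`: `alpha=1e5` gives 1e-5 per iteration, `alpha=1e3` gives 1e-3.
Antibiotic exposure sets `stress = 10` (all exposed cells, resistant or
not), which raises the induction probability (antibiotic-associated
induction); stress resets to zero on iterations without exposure.

**Headful packaging and transduction.**  A lysing cell releases exactly
`burst_size` virions.  Each is independently a defective transducing
particle with probability `p_gt`; its cargo is the `headful` consecutive
non-prophage slots starting at a uniformly random position of the circular
host genome.  For a single marker on a fully packageable genome the marker
capture probability is therefore exactly `headful / genome_size` (verified
against exhaustive window enumeration in the tests).  Transducing particles
inject their cargo — bypassing superinfection immunity, since the phage
repressor blocks replication rather than DNA injection — but can never
replicate, lyse, or lysogenize, so a population of transducing particles is
strictly nonincreasing.  Injected cargo recombines into the recipient genome
with probability `p_recomb` (default 1.0), appended at the integration
region with provenance preserved.

**Superinfection exclusion.**  Functional virions adsorbing to a lysogen of
their own immunity group are blocked and destroyed (a cost to the phage);
they never lyse the host.

### Scheduling

One iteration executes, in fixed order: (1) well-mixed shuffle;
(2) antibiotic action; (3) prophage induction; (4) adsorption; (5) free-virion
decay (probability `p_decay`); (6) intrinsic death (probability `p_death`);
(7) reproduction; (8) recording.  The ordering is a modelling choice and is
fixed; results at the reported scales are insensitive to it because the
environment is re-mixed every iteration.

Numerical/tie-break choices worth knowing:

- At most one *productive* functional infection per cell per iteration: all
  functional virions adsorbed to a cell in one iteration are consumed, one
  (uniformly chosen) is resolved; this avoids double-lysis ambiguity.
- Transducing injections on a cell resolve before the functional infection
  of the same iteration, so a cell lysed that iteration packages its
  post-injection genome.
- Virions released by lysis become visible (positions, adsorption, decay,
  local-concentration counts) from the next iteration on.
- Reproduction fills all free sites in one pass: for every free site with at
  least one living Moore neighbour, a parent is drawn with probability
  proportional to fitness (roulette wheel) among the bacteria alive at the
  start of the phase, and an exact genome copy fills the site.  A parent may
  win several sites; chained same-iteration colonisation is not modelled.
- Bacterial fitness is `(1 - cost)^k` with `k` the number of active
  resistance genes (`cost` default 0.05); prophage carriage is costless.
- Antibiotic kill is per exposed iteration with probability `p_kill`
  (default 1.0) for any cell lacking an active resistance gene against any
  applied drug; antibiotics persist from their application iteration to the
  end of the run unless a duration is configured.

### Environment-level defaults and their calibration

`p_ads = 0.4` (adsorption per co-located virion per iteration), `p_decay =
0.15`, `p_death = 0.01`, lattice 50 x 50, initial occupancy 10%, MOI 1,
`n_sample = 500`, 100 iterations with phase 1 lasting 10 and the phase-2
antibiotic at phase-2 iteration 7.

These are calibration choices, not measured quantities.  Two deserve
comment.  `p_decay = 0.15` makes free virions vanish well before the
100-iteration horizon once hosts are gone, so "phage survival" at the
horizon means lysogenic persistence, which is the regime where bacterial and
phage survival coincide.  `p_ads = 0.4` balances two opposing constraints of
the two-phase design: slow enough that the phase-1 lysate is not exhausted
by superinfection-blocked adsorption on the lysogenized donor population
before sampling (the sampled inoculum must be able to contain transducing
particles), and fast enough that transducing particles introduced into the
recipient population — and those released by induction in the two-lysogen
design — are delivered within the window before the antibiotic pulse.  With
these defaults the phase-1 lysate at sampling holds a few hundred virions
(the sample takes all of them), carrying about five marker-bearing
transducing particles in expectation — the regime in which rescue of the
recipient population is nearly certain but not trivial.

## The in-silico experiments

**Two-phase protocol (scenarios 1-4).**  Phase 1: a temperate or virulent,
transducing (`p_gt = 0.1`) or non-transducing (`p_gt = 0`) phage is
propagated for 10 iterations on an antibiotic-resistant donor population.
All free virions are collected and 500 are drawn uniformly without
replacement (all, if fewer exist).  Phase 2: the sample is introduced to a
fresh antibiotic-sensitive population (carrying a silent copy of the
resistance gene), and the drug is applied from phase-2 iteration 7 onward.
Only the temperate transducing phage (scenario 1) allows joint
bacteria-plus-phage survival: survivors must have received the active
resistance gene from a transducing particle *and* have become lysogens
(protected from further phage attack); every survivor ends as a resistant
lysogen.  The other three scenarios end in joint extinction: without
transduction there is no route to resistance; without lysogeny, transduced
resistant cells are killed by the phage they cannot become immune to.

**Two-lysogen gene shuffling (`FIG6_two_lysogens` and controls).**  Two
strains, both
lysogens of the same temperate transducing phage (one immunity group), carry
complementary chromosomal markers placed maximally distant from the prophage
integration region — strain A an active erythromycin-resistance gene with a
silent chloramphenicol copy, strain B the converse.  Spontaneous induction
releases bursts whose transducing particles ferry each marker into the other
strain (functional virions are blocked by immunity, so there is no
predation); a dual-drug pulse at iteration 10 then selects the
double-resistant exchange products.  The spontaneous induction rate for this
design is 1e-3 per lysogen-iteration (`alpha = 1e3`): at 1e-5 essentially no
exchange happens before the pulse and the design could not show survival.
Controls: without prophages the population is extinguished by the drug
cocktail (no transfer channel exists); without antibiotics, double-resistant
variants still emerge — commonly at the 1e-3 induction rate, rarely or never
at 1e-5 over the same horizon.

**Lysate capacity.**  Pure arithmetic: a lysate with 1e9 PFU/ml and one
transducing particle per 700 infective particles carries ~1.4e6 transducing
particles/ml; at 43 kbp per headful that is ~6.1e10 bp of bacterial DNA per
ml, or ~2.2e4 genome equivalents of a 2.8 Mbp genome.

## Sensitivity analysis

A random design draws parameter combinations uniformly within declared
ranges and appends a dummy parameter (uniform in {1, 2, 3}) that is never
passed to the simulator; each combination is summarised by the fraction of
replicate simulations with phage survival.  Default ranges: `p_gt` U(0,
0.3), `p_lys` categorical over {0, 0.4, 0.8} (no-lysogeny / middle / high
levels — survival saturates in `p_lys` away from zero, because a
transductant lineage accumulates infection attempts until one lysogenizes,
so a continuous column would carry almost no variance), `burst_size`
10-100, `n_sample` 200-1000, `p_ads` U(0.2, 0.4), `p_decay` U(0.15, 0.25),
antibiotic iteration 3-15.  The phage-biology parameters span their full
off-to-strong regimes; the environment-level rates vary around their
calibrated defaults.  That
asymmetry is deliberate: if adsorption or decay are allowed to starve the
protocol itself (lysate exhausted before sampling, or particles undeliverable
before the drug pulse), the response is decided by plumbing rather than
biology and every importance score collapses onto the environment rates.
Donor genome size is not a design column — it enters only as a heatmap
axis.  The decay range starts at 0.15 so that free virions cannot persist
inertly to the horizon — phage survival remains a statement about lysogeny,
not about particle half-life.

Importance is computed from a random-forest regression of the response on
the design (10,000 trees, `max_features = p//3` as is conventional for
regression forests) as permutation importance on out-of-bag rows: for each
tree, the mean squared error on its out-of-bag rows is compared with the
error after permuting one column within those rows; per-tree increases are
averaged and expressed as a percentage of the baseline out-of-bag error
(%IncMSE).  The dummy column provides the noise floor against which real
effects are judged.

The survival heatmaps cross a `p_gt` grid with genome size, burst size, or
lysate sample size, reporting joint survival of the two-phase protocol per
cell.  Expected trends and their mechanisms: survival falls with donor
genome size (marker capture is `headful/genome_size`); rises with burst size
in the sample-limited regime (at small bursts the phase-1 lysate is smaller
than the 500-virion sample, so fewer transducing particles reach phase 2 —
hence the burst axis spans 2-150); and rises then plateaus with sample size
(the expected number of marker-bearing particles in the inoculum grows
linearly until rescue is nearly certain).

## Problem sizes

The package's reference experiments use a 50 x 50 lattice with 100
replicates per scenario.  The random-forest design defaults to a desk scale
— 300 combinations x 10 replicates on a 30 x 30 lattice — chosen as the
smallest design at which the ranking is stable across seeds; the full-scale
5000 x 20 design is the same call with larger arguments.  The heatmaps (5 x
5 grids, ≥10 replicates per cell) run at the reference 50 x 50 scale: on
smaller lattices the phase-1 lysate falls below the sample sizes being
compared, and the sample-size axis cannot exhibit its plateau.

## What the generators emulate — and what they do not

The scenario initializers generate the study conditions directly: gene-level
genomes (essential/accessory/resistance genes, silent copies, optional
prophage), strain mixes, phage inocula, and antibiotic schedules.  They
emulate a well-mixed batch culture at desk scale.  They do not emulate:
nucleotide-level sequence identity or homology requirements for
recombination; lateral or specialized transduction; plasmid replication and
conjugation (plasmid markers are treated as chromosomal loci); spatial
structure (biofilms); phage evolution; or growth-phase physiology
(iterations are abstract generations, not wall-clock hours).  Passing tests
therefore demonstrate the internal consistency of the mechanism —
transduction plus lysogeny jointly rescuing phage and host under selection —
not quantitative agreement with any particular wet-lab system.

## Known limitations

- The unpublished environment-level rates were reconstructed by calibration
  against the reported scenario outcomes; other calibrations may reproduce
  them too.  All rates are exposed in configuration.
- Scenario-1 joint survival at desk scale sits in the mid-90s and varies a
  few points across master seeds: the inoculum carries only ~5 marker
  particles in expectation, so a replicate can lose all of them to decay or
  mistimed delivery.
- The two-lysogen design models exactly two drugs and one immunity group;
  the registry supports up to 8 drugs per simulation.
- With multiple phage genotypes in one simulation, all must share the
  headful size.
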