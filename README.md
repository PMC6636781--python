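# phagesim

An individual-based simulator of bacteriophage–bacteria communities built to
ask one question: **when does generalized transduction pay off — for the
phage?**  Temperate phages can integrate into the host chromosome as
prophages; generalized-transducing phages sometimes package random fragments
of host DNA into capsids, producing defective particles that inject —
rather than phage genes — whatever they picked up, including antibiotic
resistance genes.  `phagesim` models both processes mechanistically and
shows that they are synergistic: under antibiotic selection, phage lineages
persist only when transducing particles deliver the resistance gene *and*
the recipients become lysogens, protected from the surrounding virions by
superinfection immunity.  The package is aimed at researchers in microbial
ecology and horizontal gene transfer who want a tested, scriptable desk-scale
model of these dynamics.

## The model in brief

Bacteria live on a well-mixed W×H lattice (≤1 cell per site; free space is
the growth resource) with explicit circular genomes of gene slots: essential
and accessory genes, active or silent resistance genes, and integrated
prophages, all tagged with their strain of origin.  Phages adsorb to
co-located cells; a productive temperate infection lysogenizes with
probability

    P(lysogeny) = p_lys · n / (n + K),

where *n* is the local free-virion count (Moore neighbourhood), and
otherwise lyses the cell, releasing `burst_size` virions of which each is a
transducing particle with probability `p_GT`, carrying a uniform circular
window of `headful` host gene slots (marker capture probability =
`headful/L` exactly).  Prophages induce with the stress-dependent sigmoid

    P(induction | s) = 1 / (1 + α·e^(−κs)),

so the spontaneous rate is 1/(1+α) (e.g. 10⁻⁵ at α=10⁵, 10⁻³ at α=10³), and
antibiotic exposure (stress s=10) raises it.  Reproduction into free sites
is fitness-proportional roulette; each active resistance gene costs a factor
(1−c) of fitness.  See `docs/methods.md` for the full account.

Shipped experiments:

- **Scenarios 1–4** — two-phase protocol: propagate a phage (temperate or
  virulent × transducing or not) on resistant donors, sample the lysate,
  infect a sensitive population, add antibiotic.  Only the temperate
  transducing phage rescues host and phage.
- **Two-lysogen gene shuffling** — two lysogens with complementary
  resistance genes exchange markers through spontaneously induced
  transducing particles and survive a dual-drug cocktail; controls without
  prophages or without drugs.
- **Sensitivity analysis** — random parameter designs with a dummy noise
  parameter, random-forest permutation importance (%IncMSE), and survival
  heatmaps over `p_GT` × genome size / burst size / sample size.
- **Lysate capacity** — arithmetic on how much bacterial DNA a millilitre
  of lysate can move.

## Worked example

Run the flagship scenario — temperate, generalized-transducing phage,
two-phase protocol, 100 replicates — from the shell:

```bash
phagesim scenario S1_temperate_GT --reps 100 --seed 1 --out runs/s1
```

which prints

```json
{"scenario": "S1_temperate_GT", "bacteria": 0.96, "phage": 0.96, "joint": 0.96}
```

i.e. in 96% of replicates both the bacterial population and the phage are
alive at iteration 100 — and in every surviving replicate the final bacteria
are lysogens carrying the transduced resistance gene (the phage persists as
prophages).  The run directory contains per-replicate outcomes
(`outcomes.json`), the time series of one recorded replicate
(`totals.csv`, `bacteria.csv`), the seed manifest and the resolved
configuration.  Compare the non-transducing control:

```bash
phagesim scenario S2_temperate_nonGT --reps 100 --seed 1 --out runs/s2
# {"scenario": "S2_temperate_nonGT", "bacteria": 0.0, "phage": 0.0, "joint": 0.0}
```

without transduction the antibiotic extinguishes the hosts and, with them,
the phage.  The lysate-capacity arithmetic from the same command line:

```bash
phagesim capacity --pfu 1e9 --ratio 0.00142857 --headful 43000
# {"transducing_per_ml": 1428570.0, "transduced_bp_per_ml": 61428510000.0,
#  "genome_equivalents_per_ml": 21938.75}
```

a billion-PFU lysate with one transducing particle per 700 infective ones
carries ~6.1×10¹⁰ bp of bacterial DNA per ml — more than 20,000 genome
equivalents.  The same calls are available as library functions
(`phagesim.run_scenario_replicates`, `phagesim.lysate_capacity`, ...), and
`phagesim sweep` / `phagesim rfa` drive the sensitivity analyses.

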