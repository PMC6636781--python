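"""Scheduler-level tests: conservation audits, roulette-wheel reproduction
frequencies, induction rates at the population scale, superinfection
immunity, and bitwise reproducibility under fixed seeds."""

import math

import numpy as np
import pandas as pd
import pytest

from phagesim.core import PhageGenotype, build_genome
from phagesim.lattice import Lattice, SimulationParams, replicate_seed
from phagesim.registry import GenomeRegistry
from phagesim.scenarios import (
    StrainSpec,
    init_population,
    run_gene_shuffling,
    scenario_config,
)


def make_lattice(
    width=20,
    height=20,
    seed=0,
    genotype=None,
    drugs=("CAM",),
    params=None,
    schedule=None,
):
    genotype = genotype or PhageGenotype(name="phi", lifestyle="temperate")
    reg = GenomeRegistry(drugs=list(drugs), genotypes=[genotype])
    return Lattice(
        width,
        height,
        reg,
        params or SimulationParams(),
        np.random.default_rng(seed),
        schedule,
    )


class TestRandomizePositions:
    def test_counts_conserved_and_single_occupancy(self):
        lat = make_lattice()
        init_population(StrainSpec(name="s"), 100, lat)
        lat.seed_functional("phi", 500)
        lat.randomize_positions()
        assert lat.n_bacteria == 100
        assert lat.n_virions == 500
        occupied = lat.bact_site
        assert len(np.unique(occupied)) == 100  # single occupancy
        assert (lat.site2b >= 0).sum() == 100

    def test_identical_seeds_give_identical_layouts(self):
        layouts = []
        for _ in range(2):
            lat = make_lattice(seed=7)
            init_population(StrainSpec(name="s"), 50, lat)
            lat.seed_functional("phi", 100)
            lat.randomize_positions()
            layouts.append((lat.bact_site.copy(), lat.vir_site.copy()))
        np.testing.assert_array_equal(layouts[0][0], layouts[1][0])
        np.testing.assert_array_equal(layouts[0][1], layouts[1][1])


class TestReproduction:
    def test_single_neighbour_reproduces_with_certainty(self):
        lat = make_lattice(width=5, height=5)
        init_population(StrainSpec(name="s"), 1, lat)
        born = lat.reproduction_step()
        assert born >= 1  # every free site adjacent to the cell is filled

    def test_no_living_neighbour_leaves_site_empty(self):
        lat = make_lattice(width=5, height=5)
        assert lat.reproduction_step() == 0

    def test_roulette_frequencies_proportional_to_fitness(self):
        # two candidates with weights 1.0 and 0.5 -> 2/3 vs 1/3
        genotype = PhageGenotype(name="phi", lifestyle="temperate")
        reg = GenomeRegistry(drugs=["CAM"], genotypes=[genotype])
        g_fit = reg.add_founder(build_genome("fit", size=10))
        g_res = reg.add_founder(build_genome("costly", size=10, markers=(("CAM", True, 5),)))
        params = SimulationParams(cost=0.5)  # weights 1.0 vs 0.5
        rng = np.random.default_rng(3)
        lat = Lattice(3, 1, reg, params, rng)
        lat.bact_gid = np.array([g_fit, g_res])
        lat.bact_site = np.array([0, 2])
        lat.bact_strain = np.array([lat.strain_id("fit"), lat.strain_id("costly")])
        lat.bact_stress = np.zeros(2)
        lat.bact_age = np.zeros(2, dtype=np.int64)
        lat.site2b[:] = [0, -1, 1]
        wins = 0
        n_trials = 10_000
        for _ in range(n_trials):
            lat._births_gid, lat._births_strain, lat._births_site = [], [], []
            assert lat.reproduction_step() == 1
            wins += lat._births_gid[0][0] == g_fit
        p = 2 / 3
        se = math.sqrt(p * (1 - p) / n_trials)
        assert abs(wins / n_trials - p) < 3 * se


class TestStep:
    def test_empty_lattice_steps_cleanly(self):
        lat = make_lattice()
        lat.step()
        assert lat.iteration == 1
        assert lat.n_bacteria == 0

    def test_population_reaches_and_never_exceeds_capacity(self):
        lat = make_lattice(width=10, height=10, params=SimulationParams(p_death=0.0))
        init_population(StrainSpec(name="s"), 5, lat)
        sizes = []
        for _ in range(30):
            lat.step()
            sizes.append(lat.n_bacteria)
        assert max(sizes) <= 100
        assert sizes[-1] == 100  # free space is the resource; it fills up
        out = lat.outcome(seed=0)
        assert out.bacteria_survived and not out.phage_survived

    def test_spontaneous_induction_rate_matches_sigmoid(self):
        # lysogens at stress 0 with alpha=1e3 induce at 1/1001 per iteration
        genotype = PhageGenotype(name="phi", lifestyle="temperate", alpha=1e3)
        reg = GenomeRegistry(drugs=["CAM"], genotypes=[genotype])
        params = SimulationParams(p_death=0.0)
        lat = Lattice(40, 40, reg, params, np.random.default_rng(5), None)
        init_population(StrainSpec(name="s", prophage_of="phi"), 1600, lat)
        trials = 0
        for _ in range(63):
            trials += lat.n_bacteria
            lat.step()
        inductions = lat.cum_inductions
        p = 1 / 1001
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(inductions / trials - p) < 3 * se

    def test_bitwise_reproducibility_under_fixed_seed(self):
        cfg = scenario_config("S4C_no_drug_high_induction", width=15, height=15,
                              total_iterations=30)
        a = run_gene_shuffling(cfg, 11, record=True)
        b = run_gene_shuffling(cfg, 11, record=True)
        pd.testing.assert_frame_equal(a.series.totals, b.series.totals)
        pd.testing.assert_frame_equal(a.series.bacteria, b.series.bacteria)
        assert a.outcome == b.outcome


class TestConservationAudit:
    def test_population_and_virion_bookkeeping_balance(self):
        cfg = scenario_config("FIG6_two_lysogens", width=15, height=15,
                              total_iterations=40)
        res = run_gene_shuffling(cfg, 3, record=True)
        lat = res.lattice
        totals = res.series.totals
        n = totals["n_bacteria"].to_numpy()
        free = (totals["free_functional"] + totals["free_transducing"]).to_numpy()
        audit = pd.DataFrame(lat.audit)
        deaths = (
            audit["deaths_antibiotic"]
            + audit["deaths_intrinsic"]
            + audit["inductions"]
            + audit["lysed"]
        ).to_numpy()
        births = audit["births"].to_numpy()
        np.testing.assert_array_equal(n[1:], n[:-1] - deaths + births)
        removed = (audit["adsorbed"] + audit["decayed"]).to_numpy()
        released = audit["virions_released"].to_numpy()
        np.testing.assert_array_equal(free[1:], free[:-1] - removed + released)


class TestReplicateDriver:
    def test_single_replicate_fraction_is_zero_or_one(self):
        from phagesim.lattice import run_replicates, survival_fractions
        from phagesim.scenarios import run_gene_shuffling

        cfg = scenario_config("S4C_no_drug_high_induction", width=12, height=12,
                              total_iterations=15)
        outcomes = run_replicates(
            lambda rng, k: run_gene_shuffling(cfg, rng, record=False).outcome, 1, 3
        )
        frac = survival_fractions(outcomes)
        assert frac["joint"] in (0.0, 1.0)

    def test_replicate_series_median_and_interval(self):
        from phagesim.lattice import series_median_ci, replicate_seed
        from phagesim.scenarios import run_gene_shuffling

        cfg = scenario_config("S4C_no_drug_high_induction", width=12, height=12,
                              total_iterations=15)
        series = [
            run_gene_shuffling(cfg, replicate_seed(3, k), record=True).series.totals
            for k in range(5)
        ]
        summary = series_median_ci(series, ["n_bacteria", "free_functional"])
        assert len(summary) == 16  # iterations 0..15
        assert (summary["n_bacteria_lo"] <= summary["n_bacteria_median"]).all()
        assert (summary["n_bacteria_median"] <= summary["n_bacteria_hi"]).all()


class TestPhageInvariants:
    def test_transducing_particles_never_replicate(self):
        # an inoculum of only transducing particles can never grow
        lat = make_lattice(width=15, height=15)
        gid = init_population(StrainSpec(name="s"), 50, lat)
        cids = [lat.reg.intern_cargo(gid, s) for s in range(100)]
        lat.seed_virions(
            np.zeros(100, dtype=np.int64), np.array(cids, dtype=np.int64)
        )
        counts = []
        for _ in range(30):
            lat.step()
            counts.append(lat.n_virions)
        assert all(b <= a for a, b in zip([100] + counts, counts))
        assert sum(a["lysed"] for a in lat.audit) == 0
        assert lat.cum_transductions > 0  # cargo was delivered, not amplified

    def test_lysogens_never_lysed_by_own_immunity_group(self):
        lat = make_lattice(width=15, height=15, params=SimulationParams(p_death=0.0))
        init_population(StrainSpec(name="s", prophage_of="phi"), 100, lat)
        lat.seed_functional("phi", 1000)
        for _ in range(20):
            lat.step()
        audit = pd.DataFrame(lat.audit)
        assert audit["lysed"].sum() == 0
        assert audit["blocked"].sum() > 0  # immune encounters did occur
        assert lat.n_bacteria >= 100  # population never shrank by lysis

    def test_no_gene_gain_without_transduction(self):
        # p_gt = 0: the distinct-gene pool can never grow
        cfg = scenario_config("S2_temperate_nonGT", width=15, height=15,
                              total_iterations=40)
        from phagesim.scenarios import run_two_phase

        res = run_two_phase(cfg, 4, record=True)
        lat = res.lattice
        assert lat.cum_transductions == 0
        assert len(lat.reg._cargo_key) == 0
        recipes = lat.reg._recipes
        assert all(r[0] in ("founder", "lys") for r in recipes)
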