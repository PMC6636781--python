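"""Unit tests of the mechanistic kernels against independent oracles:
closed-form probabilities, brute-force window enumeration, and Bernoulli /
binomial sampling checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phagesim.core import (
    Bacterium,
    Gene,
    InvalidParameterError,
    PhageGenotype,
    Virion,
    antibiotic_action,
    build_genome,
    decide_lifecycle,
    fitness,
    induction_probability,
    inject_transduced,
    lysogenization_probability,
    package_burst,
    resolve_adsorption,
)


class TestInductionProbability:
    def test_spontaneous_rates_match_parameterizations(self):
        # alpha = 1e5 -> spontaneous induction 1e-5; alpha = 1e3 -> 1e-3
        assert induction_probability(0.0, 1e5, 0.4) == pytest.approx(1 / 100001)
        assert induction_probability(0.0, 1e3, 0.4) == pytest.approx(1 / 1001)
        assert induction_probability(0.0, 1e5, 0.4) == pytest.approx(1e-5, rel=1e-4)
        assert induction_probability(0.0, 1e3, 0.4) == pytest.approx(1e-3, rel=1e-2)

    def test_saturates_to_one_under_high_stress(self):
        assert induction_probability(1e3, 1e3, 0.4) == pytest.approx(1.0)

    def test_strictly_increasing_in_stress(self):
        for alpha in (10.0, 1e3, 1e5):
            for kappa in (0.1, 0.4, 2.0):
                p = induction_probability(np.linspace(0, 50, 101), alpha, kappa)
                assert np.all(np.diff(p) >= 0)
                unsaturated = p[:-1] < 1.0 - 1e-12  # strict until float saturation
                assert np.all(np.diff(p)[unsaturated] > 0)
                assert p[0] == pytest.approx(1 / (1 + alpha))

    @pytest.mark.parametrize(
        "stress,alpha,kappa",
        [(-1.0, 1e3, 0.4), (0.0, 0.0, 0.4), (0.0, -5.0, 0.4), (0.0, 1e3, 0.0),
         (math.nan, 1e3, 0.4), (0.0, math.inf, 0.4)],
    )
    def test_invalid_parameters_raise(self, stress, alpha, kappa):
        with pytest.raises(InvalidParameterError):
            induction_probability(stress, alpha, kappa)


class TestLifecycleDecision:
    def test_virulent_always_lyses(self, virulent, rng):
        assert all(
            decide_lifecycle(virulent, n, rng) == "lyse" for n in (0, 1, 10, 10_000)
        )

    def test_zero_lysogenization_probability_always_lyses(self, rng):
        gt = PhageGenotype(name="p", lifestyle="temperate", p_lys=0.0)
        assert all(decide_lifecycle(gt, n, rng) == "lyse" for n in range(20))

    def test_negative_local_count_raises(self, temperate, rng):
        with pytest.raises(InvalidParameterError):
            decide_lifecycle(temperate, -1, rng)

    def test_empirical_frequency_matches_hill_function(self, rng):
        # p_lys=0.8, k_lys=2, n=2 -> P(lysogenize) = 0.8 * 2/4 = 0.40
        gt = PhageGenotype(name="p", lifestyle="temperate", p_lys=0.8, k_lys=2.0)
        n_draws = 100_000
        hits = sum(
            decide_lifecycle(gt, 2, rng) == "lysogenize" for _ in range(n_draws)
        )
        se = math.sqrt(0.4 * 0.6 / n_draws)
        assert abs(hits / n_draws - 0.40) < 3 * se

    def test_probability_saturates_and_is_nondecreasing(self, temperate):
        probs = [lysogenization_probability(temperate, n) for n in range(0, 200)]
        assert probs[0] == 0.0
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[-1] <= temperate.p_lys


class TestPackageBurst:
    def test_burst_size_and_zero_p_gt(self, donor_genome, rng):
        gt = PhageGenotype(name="p", lifestyle="temperate", p_gt=0.0, burst_size=50)
        burst = package_burst(donor_genome, gt, rng)
        assert len(burst) == 50
        assert all(not v.is_transducing for v in burst)

    def test_all_transducing_at_p_gt_one(self, donor_genome, rng):
        gt = PhageGenotype(name="p", lifestyle="temperate", p_gt=1.0, burst_size=50)
        burst = package_burst(donor_genome, gt, rng)
        assert len(burst) == 50
        assert all(v.is_transducing for v in burst)
        assert all(len(v.cargo) <= gt.headful for v in burst)
        assert all(g.provenance == "donor" for v in burst for g in v.cargo)

    def test_marker_capture_by_exhaustive_window_enumeration(self, donor_genome):
        # 100 packageable slots, headful 10, one marker: exactly 10 of the 100
        # circular windows contain the marker
        hits = sum(
            any(g.drug == "CAM" for g in donor_genome.window(s, 10))
            for s in range(100)
        )
        assert hits == 10

    def test_headful_exceeding_packageable_loci_raises(self, rng):
        genome = build_genome("tiny", size=5)
        gt = PhageGenotype(name="p", lifestyle="temperate", headful=10, burst_size=1)
        with pytest.raises(InvalidParameterError):
            package_burst(genome, gt, rng)

    def test_transducing_fraction_within_binomial_error(self, donor_genome, rng):
        gt = PhageGenotype(name="p", lifestyle="temperate", p_gt=0.2, burst_size=100)
        n_bursts = 200
        trans = sum(
            v.is_transducing
            for _ in range(n_bursts)
            for v in package_burst(donor_genome, gt, rng)
        )
        n = n_bursts * gt.burst_size
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(trans / n - 0.2) < 3 * se


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    size=st.integers(min_value=10, max_value=200),
    headful=st.integers(min_value=1, max_value=200),
)
def test_marker_capture_probability_equals_headful_over_genome(size, headful):
    """For a circular genome with no prophage and a single marker, the
    fraction of headful windows containing the marker is exactly h/L."""
    headful = min(headful, size)
    genome = build_genome("s", size=size, markers=(("CAM", True, size // 3),))
    hits = sum(
        any(g is not None and g.drug == "CAM" for g in genome.window(s, headful))
        for s in range(size)
    )
    assert hits / size == pytest.approx(headful / size)


class TestGenome:
    def test_window_wraps_circularly(self, donor_genome):
        w = donor_genome.window(95, 10)
        ids = [g.gene_id for g in w]
        assert len(ids) == 10  # all slots filled in a founder genome
        assert donor_genome.loci[99].gene_id in ids
        assert donor_genome.loci[0].gene_id in ids

    def test_prophage_slots_are_skipped_by_packaging(self, donor_genome, temperate):
        lysogen = donor_genome.with_prophage(temperate, span=5)
        assert lysogen.size == 105
        assert len(lysogen.packageable_loci) == 100
        for s in range(100):
            assert all(g is not None for g in lysogen.window(s, 10))

    def test_repeat_lysogenization_same_immunity_group_blocked(
        self, donor_genome, temperate
    ):
        lysogen = donor_genome.with_prophage(temperate)
        with pytest.raises(InvalidParameterError):
            lysogen.with_prophage(temperate)

    def test_resistance_gene_must_name_drug(self):
        with pytest.raises(InvalidParameterError):
            Gene(gene_id="x", category="resistance")
        with pytest.raises(InvalidParameterError):
            Gene(gene_id="x", category="essential", drug="CAM")


class TestFitness:
    def test_multiplicative_cost(self, donor_genome, recipient_genome):
        resistant = Bacterium(genome=donor_genome, strain="d")
        sensitive = Bacterium(genome=recipient_genome, strain="r")
        assert fitness(sensitive, 0.05) == 1.0  # inactive gene costs nothing
        assert fitness(resistant, 0.05) == pytest.approx(0.95)
        double = Bacterium(
            genome=donor_genome.with_cargo(
                (Gene("e", "resistance", drug="ERM", active=True, provenance="x"),)
            ),
            strain="d",
        )
        assert fitness(double, 0.05) == pytest.approx(0.9025)

    def test_cost_out_of_range_raises(self, donor_genome):
        b = Bacterium(genome=donor_genome, strain="d")
        for cost in (-0.1, 1.0, 1.5):
            with pytest.raises(InvalidParameterError):
                fitness(b, cost)


class TestInjectTransduced:
    def test_active_gene_confers_resistance_despite_inactive_copy(
        self, recipient_genome, rng
    ):
        cargo = (Gene("c", "resistance", drug="CAM", active=True, provenance="donor"),)
        cell = Bacterium(genome=recipient_genome, strain="r")
        assert not cell.is_resistant_to("CAM")
        updated = inject_transduced(cell, cargo, p_recomb=1.0, rng=rng)
        assert updated.is_resistant_to("CAM")

    def test_no_recombination_leaves_genome_unchanged(self, recipient_genome, rng):
        cargo = (Gene("c", "resistance", drug="CAM", active=True, provenance="donor"),)
        cell = Bacterium(genome=recipient_genome, strain="r")
        updated = inject_transduced(cell, cargo, p_recomb=0.0, rng=rng)
        assert updated.genome == recipient_genome

    def test_non_resistance_cargo_recorded_with_donor_provenance(
        self, recipient_genome, rng
    ):
        cargo = (Gene("a", "accessory", provenance="donor"),)
        cell = Bacterium(genome=recipient_genome, strain="r")
        updated = inject_transduced(cell, cargo, p_recomb=1.0, rng=rng)
        assert updated.genome.active_drugs() == frozenset()
        assert updated.genome.loci[-1].provenance == "donor"


class TestAntibioticAction:
    def test_certain_kill_of_sensitive_cell(self, recipient_genome, rng):
        cell = Bacterium(genome=recipient_genome, strain="r")
        alive, _ = antibiotic_action(cell, {"CAM"}, 1.0, 10.0, rng)
        assert not alive

    def test_resistant_cell_survives_with_raised_stress(self, donor_genome, rng):
        cell = Bacterium(genome=donor_genome, strain="d")
        alive, updated = antibiotic_action(cell, {"CAM"}, 1.0, 10.0, rng)
        assert alive and updated.stress == 10.0

    def test_no_drugs_resets_stress(self, donor_genome, rng):
        cell = Bacterium(genome=donor_genome, strain="d", stress=10.0)
        alive, updated = antibiotic_action(cell, set(), 1.0, 10.0, rng)
        assert alive and updated.stress == 0.0


class TestResolveAdsorption:
    def test_same_immunity_group_blocked(self, donor_genome, temperate, rng):
        lysogen = Bacterium(genome=donor_genome.with_prophage(temperate), strain="d")
        res = resolve_adsorption(lysogen, Virion(genotype=temperate), 5, rng)
        assert res.event == "blocked"
        assert res.bacterium is lysogen

    def test_transducing_particle_bypasses_immunity(
        self, recipient_genome, temperate, rng
    ):
        lysogen = Bacterium(genome=recipient_genome.with_prophage(temperate), strain="r")
        cargo = (Gene("c", "resistance", drug="CAM", active=True, provenance="donor"),)
        v = Virion(genotype=temperate, cargo_kind="bacterial_dna", cargo=cargo)
        res = resolve_adsorption(lysogen, v, 5, rng)
        assert res.event == "transduced"
        assert res.bacterium.is_resistant_to("CAM")

    def test_virulent_phage_lyses_susceptible_host(self, donor_genome, virulent, rng):
        cell = Bacterium(genome=donor_genome, strain="d")
        res = resolve_adsorption(cell, Virion(genotype=virulent), 1000, rng)
        assert res.event == "lysed"
        assert res.bacterium is None
        assert len(res.burst) == virulent.burst_size

    def test_defective_particle_invariants(self, temperate):
        with pytest.raises(InvalidParameterError):
            Virion(
                genotype=temperate,
                cargo_kind="phage_dna",
                cargo=(Gene("a", "accessory", provenance="x"),),
            )
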