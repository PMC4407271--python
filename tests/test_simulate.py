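"""Tests for the gamma-renewal meiosis simulator.

Monte-Carlo expectations: under Poisson placement (nu = 1) the recombinant
fraction of a chromatid across an interval of d Morgans is Haldane's
(1 - exp(-2d))/2, which the oracle comparisons below use; for the small
intervals used in round-trip tests the difference from d itself is far
below Monte-Carlo noise.
"""

import numpy as np
import pytest

import ftltools as ft
from ftltools.simulate import (GeneticMap, ReporterLayout, SimulationModel,
                               simulate_f2_population, simulate_meioses,
                               simulate_per_tetrad_calls,
                               simulate_pollen_three_colour,
                               simulate_pollen_two_colour,
                               simulate_selfed_seed, simulate_tetrad_counts)

CHROM = 1_000_000


def haldane(d_morgans: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


class TestModelValidation:
    def test_decreasing_map_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap(np.array([1.0, 10.0, 20.0]), np.array([0.0, 0.2, 0.1]))

    def test_bad_nu_rejected(self):
        with pytest.raises(ValueError):
            SimulationModel.uniform(CHROM, 10.0, nu=0.0)

    def test_bad_escape_rejected(self):
        with pytest.raises(ValueError):
            SimulationModel.uniform(CHROM, 10.0, escape_fraction=1.5)

    def test_negative_rate_factor_rejected(self):
        with pytest.raises(ValueError):
            SimulationModel.uniform(CHROM, 10.0,
                                    region_modifiers=[(1, 100, -1.0)])

    def test_layout_marker_counts(self):
        with pytest.raises(ValueError):
            ReporterLayout([("a", 1, "G")], "pollen2")
        with pytest.raises(ValueError):
            ReporterLayout([("a", 1, "G"), ("b", 10, "R")], "pollen3")

    def test_layout_positions_increasing(self):
        with pytest.raises(ValueError):
            ReporterLayout([("a", 100, "G"), ("b", 50, "R")], "pollen2")

    def test_zero_meioses_errors(self, make_model):
        with pytest.raises(ValueError):
            simulate_meioses(make_model(10.0), 0)


class TestDeterminism:
    def test_identical_seeds_identical_counts(self, make_model, tetrad_layout,
                                              pollen3_layout):
        for build in (
            lambda m: simulate_tetrad_counts(m, tetrad_layout, 2000),
            lambda m: simulate_pollen_three_colour(m, pollen3_layout, 2000),
        ):
            a = build(make_model(12.0, nu=3.0, escape=0.1, seed=99))
            b = build(make_model(12.0, nu=3.0, escape=0.1, seed=99))
            assert a == b

    def test_different_seeds_differ(self, make_model, tetrad_layout):
        a = simulate_tetrad_counts(make_model(12.0, seed=1), tetrad_layout, 5000)
        b = simulate_tetrad_counts(make_model(12.0, seed=2), tetrad_layout, 5000)
        assert a != b


class TestEventPlacement:
    def test_poisson_recombinant_fraction(self, make_model, pollen2_layout):
        """nu=1: chromatid recombinant fraction matches the Poisson-placement
        (Haldane) expectation within 3 Monte-Carlo SEs."""
        n = 100_000
        counts = simulate_pollen_two_colour(make_model(5.0, seed=10),
                                            pollen2_layout, n)
        rec = (counts.R5 + counts.red_alone) / n
        expect = haldane(0.05)
        mc_se = np.sqrt(expect * (1 - expect) / n)
        assert abs(rec - expect) < 3 * mc_se

    def test_event_count_intensity(self, make_model):
        """Two chiasmata per Morgan on the bivalent, any nu."""
        for nu in (1.0, 5.0):
            model = make_model(50.0, nu=nu, seed=3)
            events = simulate_meioses(model, 20_000)
            mean = np.mean([len(e) for e in events])
            assert mean == pytest.approx(2 * 0.5, rel=0.05)

    def test_escape_mixture_preserves_intensity(self, make_model):
        model = make_model(50.0, nu=10.0, escape=0.3, seed=4)
        events = simulate_meioses(model, 20_000)
        assert np.mean([len(e) for e in events]) == pytest.approx(1.0, rel=0.05)

    def test_chromatid_pairs_non_sister(self, make_model):
        for rec in simulate_meioses(make_model(80.0, seed=5), 500):
            for _, i, j in rec:
                assert i in (0, 1) and j in (2, 3)


class TestTetradSimulation:
    def test_zero_rate_all_parental(self, tetrad_layout):
        model = SimulationModel.uniform(CHROM, 0.0, rng_seed=0)
        counts = simulate_tetrad_counts(model, tetrad_layout, 5000)
        assert (counts.PD, counts.NPD, counts.T) == (5000, 0, 0)

    def test_small_distance_tetratype_fraction(self, make_model, tetrad_layout):
        """At small map distance m, single crossovers dominate: T/n ~ 2m
        and NPD is rare (exhaustive strand-assignment enumeration gives
        2m for the tetratype rate to first order)."""
        n = 100_000
        m = 0.01
        counts = simulate_tetrad_counts(make_model(100 * m, seed=6),
                                        tetrad_layout, n)
        se = np.sqrt(2 * m * (1 - 2 * m) / n)
        assert abs(counts.T / n - 2 * m) < 4 * se
        assert counts.NPD <= 5

    def test_perkins_round_trip(self, make_model, tetrad_layout):
        """Perkins estimate recovers the simulated map distance within 2 SE
        (the NPD term corrects double crossovers; at this distance the
        residual triple-chiasma deficit is ~0.01 cM, below noise)."""
        counts = simulate_tetrad_counts(make_model(5.0, seed=7),
                                        tetrad_layout, 100_000)
        est = ft.tetrad_cm(counts)
        assert abs(est.cm - 5.0) < 2 * est.se + 0.02

    def test_class_sum(self, make_model, tetrad_layout):
        counts = simulate_tetrad_counts(make_model(20.0, seed=8),
                                        tetrad_layout, 4321)
        assert counts.n == 4321


class TestPollenSimulation:
    def test_zero_rate_no_recombinants(self, pollen2_layout):
        model = SimulationModel.uniform(CHROM, 0.0, rng_seed=0)
        counts = simulate_pollen_two_colour(model, pollen2_layout, 5000)
        assert counts.R5 == 0 and counts.red_alone == 0
        assert counts.total == 5000

    def test_artifact_inflates_red_alone_only(self, make_model, pollen2_layout):
        model = make_model(10.0, seed=9)
        counts = simulate_pollen_two_colour(model, pollen2_layout, 50_000,
                                            artifact_fraction=0.05)
        assert counts.red_alone > counts.R5  # symmetric without artifacts
        est = ft.pollen2_cm(counts)
        # estimator conditions on green pollen: immune to the artifact;
        # the expected value is the Haldane recombinant fraction
        assert abs(est.cm - 100 * haldane(0.10)) < 3 * est.se

    def test_bad_artifact_fraction(self, make_model, pollen2_layout):
        with pytest.raises(ValueError):
            simulate_pollen_two_colour(make_model(10.0), pollen2_layout, 100,
                                       artifact_fraction=1.0)

    def test_three_colour_zero_rate(self, pollen3_layout):
        model = SimulationModel.uniform(CHROM, 0.0, rng_seed=0)
        counts = simulate_pollen_three_colour(model, pollen3_layout, 3000)
        assert counts.N_BYR + counts.N_mmm == 3000
        assert counts.N_total == 3000

    def test_three_colour_cm_round_trip(self, make_model, pollen3_layout):
        counts = simulate_pollen_three_colour(make_model(8.0, seed=11),
                                              pollen3_layout, 100_000)
        est_b, est_c = ft.threecolour_cms(counts)
        for est in (est_b, est_c):
            assert abs(est.cm - 4.0) < 3 * est.se + 0.05


class TestInterferenceBehaviour:
    def test_poisson_coc_near_one(self, make_model, pollen3_layout):
        counts = simulate_pollen_three_colour(make_model(40.0, seed=12),
                                              pollen3_layout, 100_000)
        res = ft.coc_threecolour(counts)
        assert abs(res.coc - 1.0) < 0.05

    def test_poisson_with_escape_still_coc_one(self, make_model, pollen3_layout):
        counts = simulate_pollen_three_colour(
            make_model(40.0, nu=1.0, escape=0.4, seed=13), pollen3_layout,
            100_000)
        assert abs(ft.coc_threecolour(counts).coc - 1.0) < 0.05

    def test_strong_interference_detected(self, make_model, pollen3_layout):
        counts = simulate_pollen_three_colour(make_model(40.0, nu=10.0, seed=14),
                                              pollen3_layout, 100_000)
        res = ft.coc_threecolour(counts)
        assert res.interference > 0.3
        assert res.p_value < 1e-6

    def test_tetrad_and_gamete_interference_agree(self, make_model,
                                                  pollen3_layout):
        """The adjacent-CO tetrad ratio and the gamete CoC measure the same
        phenomenon: ratio ~ 1 under Poisson, > 1 under interference."""
        lay_b = ReporterLayout([("CFP", 1, "C"), ("YFP", CHROM // 2, "Y")],
                               "tetrad")
        lay_c = ReporterLayout([("YFP", CHROM // 2, "Y"), ("dsRed", CHROM, "R")],
                               "tetrad")
        calls_null = simulate_per_tetrad_calls(make_model(40.0, seed=15),
                                               lay_b, lay_c, 60_000)
        res_null = ft.tetrad_adjacent_interference(calls_null)
        assert abs(res_null.ratio - 1.0) < 0.15

        calls_int = simulate_per_tetrad_calls(make_model(40.0, nu=10.0, seed=16),
                                              lay_b, lay_c, 60_000)
        res_int = ft.tetrad_adjacent_interference(calls_int)
        assert res_int.ratio > 1.3
        assert res_int.p_value < 1e-4


class TestRegionModifiers:
    def test_modifier_scales_local_rate(self, pollen2_layout):
        base = SimulationModel.uniform(CHROM, 10.0, rng_seed=17)
        boosted = SimulationModel.uniform(
            CHROM, 10.0, rng_seed=17,
            region_modifiers=[(1, CHROM, 2.0)])
        assert boosted.effective_map().length_morgans == pytest.approx(
            2 * base.effective_map().length_morgans)

    def test_map_additivity_nested_intervals(self, make_model):
        model = make_model(30.0, seed=18,)
        emap = model.effective_map()
        inner = emap.morgans_at(600_000) - emap.morgans_at(400_000)
        outer = emap.morgans_at(900_000) - emap.morgans_at(100_000)
        assert inner <= outer

    def test_nested_interval_recombination(self, make_model):
        """Simulated recombinant fraction of a nested interval never exceeds
        the enclosing interval's."""
        model = make_model(30.0, seed=19)
        n = 40_000
        lay_outer = ReporterLayout([("a", 100_000, "G"), ("b", 900_000, "R")],
                                   "pollen2")
        lay_inner = ReporterLayout([("a", 400_000, "G"), ("b", 600_000, "R")],
                                   "pollen2")
        rng = np.random.default_rng(19)
        outer = simulate_pollen_two_colour(model, lay_outer, n, rng=rng)
        rng = np.random.default_rng(19)
        inner = simulate_pollen_two_colour(model, lay_inner, n, rng=rng)
        rec = lambda c: c.R5 + c.red_alone  # noqa: E731
        assert rec(inner) <= rec(outer)


class TestSelfedSeed:
    def test_class_probabilities(self):
        probs = ft.simulate.expected_seed_class_probs(0.2)
        np.testing.assert_allclose(probs, [0.66, 0.09, 0.09, 0.16], atol=1e-12)

    def test_r_zero_class_frequencies(self):
        counts = simulate_selfed_seed(0.0, 20_000, seed=20)
        assert counts.N_G == 0 and counts.N_R == 0
        assert counts.N_N / counts.N_T == pytest.approx(0.25, abs=0.01)

    def test_seed_cm_round_trip(self):
        counts = simulate_selfed_seed(0.18, 10_000, seed=21)
        est = ft.seed_cm(counts)
        assert abs(est.cm - 18.0) < 3 * est.se

    def test_invalid_r(self):
        with pytest.raises(ValueError):
            simulate_selfed_seed(1.2, 100)

    def test_counts_sum(self):
        counts = simulate_selfed_seed(0.2, 12345, seed=22)
        assert counts.N_T == 12345


class TestF2Population:
    def test_requires_individuals_and_markers(self, make_model):
        with pytest.raises(ValueError):
            simulate_f2_population(make_model(15.0), [], None, 10)
        with pytest.raises(ValueError):
            simulate_f2_population(make_model(15.0), [100, 200], None, 0)

    def test_population_shape_and_heterozygous_reporter(self, make_model):
        markers = list(range(100_000, 1_000_000, 100_000))
        pop = simulate_f2_population(
            make_model(15.0, seed=23), markers, None, 30,
            seeds_per_individual=500, reporter=(100_000, 500_000))
        assert len(pop) == 30
        for ind in pop:
            assert set(ind.genotypes) == set(markers)
            assert ind.cm >= 0.0

    def test_marker_segregation_ratio(self):
        """A marker far (in cM) from the reporter segregates near 1:2:1
        despite selection on the transgenes (expected HET fraction
        (1-r)^2 + r^2 with r the Haldane fraction at ~80 cM)."""
        model = SimulationModel.uniform(23_000_000, 90.0, rng_seed=24)
        pop = simulate_f2_population(
            model, [22_500_000], None, 400,
            seeds_per_individual=200, reporter=(1, 2_000_000))
        hets = sum(ind.genotypes[22_500_000] == "HET" for ind in pop)
        r = haldane(0.802)  # ~80.2 cM between distal T-DNA and marker
        expect = (1 - r) ** 2 + r ** 2
        assert abs(hets / len(pop) - expect) < 0.08

    def test_cis_effect_changes_rate(self, make_model):
        markers = [500_000]
        effect = lambda g: 2.0  # noqa: E731
        reporter = (100_000, 900_000)
        base = simulate_f2_population(make_model(10.0, seed=25), markers, None,
                                      40, seeds_per_individual=2000,
                                      reporter=reporter)
        boosted = simulate_f2_population(make_model(10.0, seed=25), markers,
                                         effect, 40, seeds_per_individual=2000,
                                         reporter=reporter)
        assert (np.mean([i.cm for i in boosted])
                > 1.5 * np.mean([i.cm for i in base]))
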