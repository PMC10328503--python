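import math

import numpy as np
import pytest
from scipy import stats as sps

from tardis_barseq import (
    SampleProfile,
    StatsParams,
    array_f1_correlation,
    fit_zt_poisson,
    jackpot_report,
    overlap_analysis,
    pearson_with_log_p,
    position_probabilities,
    promoter_tally,
    sample_zt_poisson,
    select_threshold,
    summarize_diversity,
)
from tardis_barseq.experiments import correlation_experiment
from tardis_barseq.stats import zt_poisson_mean


class TestSelectThreshold:
    def test_bimodal_counts_plateau_just_above_error_tail(self):
        counts = {f"T{i}": 100 for i in range(1000)}
        counts.update({f"E{i}": 1 for i in range(5000)})
        threshold, fallback = select_threshold(counts)
        assert (threshold, fallback) == (2, False)

    def test_uniform_high_counts_return_one(self):
        counts = {f"B{i}": 10 for i in range(100)}
        assert select_threshold(counts) == (1, False)

    def test_geometric_error_tail_decaying_by_five(self):
        # error tail thins geometrically and is gone above count 4, so the
        # first window with <1% relative change starts at 5
        counts = {}
        sizes = {1: 4000, 2: 1000, 3: 250, 4: 60}
        k = 0
        for count, n in sizes.items():
            for _ in range(n):
                counts[f"E{k}"] = count
                k += 1
        counts.update({f"T{i}": 500 for i in range(2000)})
        u = lambda c: sum(1 for v in counts.values() if v >= c)
        # brute-force evaluation of the rule on this fixture
        expected = next(
            c for c in range(1, 501) if (u(c) - u(c + 3)) / u(c) < 0.01
        )
        assert expected == 5
        assert select_threshold(counts) == (5, False)

    def test_no_plateau_falls_back_with_warning(self):
        # geometrically thinning counts: u(c) drops ~20% per unit count at
        # every cutoff, so no window ever flattens below the tolerance
        counts = {}
        k = 0
        for c in range(1, 26):
            for _ in range(max(1, round(1000 * 0.8**c))):
                counts[f"B{k}"] = c
                k += 1
        threshold, fallback = select_threshold(counts)
        assert fallback is True
        assert threshold == StatsParams().default_threshold

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            select_threshold({})

    def test_scale_free_when_all_counts_far_above_threshold(self):
        counts = {f"B{i}": 100 for i in range(50)}
        scaled = {b: c * 7 for b, c in counts.items()}
        assert select_threshold(counts) == select_threshold(scaled)


class TestDiversityAndJackpots:
    def test_single_barcode_profile(self):
        profile = SampleProfile.from_counts("s", {"AAA": 10})
        summary = summarize_diversity(profile)
        assert summary["n_unique"] == 1
        assert summary["frequency_cv"] == 0.0

    def test_simulated_array_diversity_matches_founders(self, small_array):
        counts = {b: int(c) for b, c in small_array.entries.items()}
        profile = SampleProfile.from_counts("array", counts)
        assert summarize_diversity(profile)["n_unique"] == 30

    def test_jackpot_arithmetic(self):
        jackpots, reads_frac, unique_frac = jackpot_report(
            {"A": 60, "B": 10, "C": 30}, cutoff=50
        )
        assert jackpots == {"A"}
        assert reads_frac == pytest.approx(0.6)
        assert unique_frac == pytest.approx(1 / 3)

    def test_no_jackpots_below_cutoff(self):
        assert jackpot_report({"A": 5, "B": 50}, cutoff=50) == (set(), 0.0, 0.0)


class TestPositionProbabilities:
    def test_fixed_template_positions_are_certain(self, template, small_library):
        logo = position_probabilities(small_library.entries)
        for pos, base in ((4, "C"), (7, "T"), (9, "T"), (11, "A")):
            assert logo.loc[pos, base] == 1.0

    def test_two_sequence_unique_weighting(self):
        logo = position_probabilities({"AAAA": 99, "CCCC": 1}, weighting="unique")
        assert np.allclose(logo["A"], 0.5)
        assert np.allclose(logo["C"], 0.5)
        read_weighted = position_probabilities(
            {"AAAA": 99, "CCCC": 1}, weighting="read_weighted"
        )
        assert np.allclose(read_weighted["A"], 0.99)

    def test_free_positions_near_uniform_in_large_library(self, small_library):
        logo = position_probabilities(small_library.entries)
        n = len(small_library.entries)
        sd = math.sqrt(0.25 * 0.75 / n)
        free = [p for p in logo.index if p not in (4, 7, 9, 11)]
        assert np.all(np.abs(logo.loc[free].values - 0.25) < 5 * sd)

    def test_rows_sum_to_one(self, small_library):
        logo = position_probabilities(small_library.entries)
        assert np.allclose(logo.sum(axis=1), 1.0, atol=1e-12)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            position_probabilities({"AAA": 1, "AAAA": 1})


class TestOverlap:
    def test_identical_sets(self):
        result = overlap_analysis([{"x", "y"}, {"x", "y"}])
        assert result["exactly_k"] == {1: 0, 2: 2}
        assert result["containment"][("set1", "set2")] == 1.0

    def test_three_set_enumeration(self):
        result = overlap_analysis([{"x", "y"}, {"y", "z"}, {"w"}])
        assert result["exactly_k"] == {1: 3, 2: 1, 3: 0}
        assert result["exactly_k_pct"][1] == pytest.approx(75.0)
        assert result["exactly_k_pct"][2] == pytest.approx(25.0)

    def test_membership_counts_cover_union(self):
        sets = [{"a", "b", "c"}, {"b", "d"}, {"c", "d", "e"}]
        result = overlap_analysis(sets)
        assert sum(result["exactly_k"].values()) == result["union_size"] == 5
        for i in range(3):
            assert result["containment"][(f"set{i+1}", f"set{i+1}")] == 1.0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_analysis([{"a"}])


class TestZtPoissonFit:
    def test_all_ones_is_boundary(self):
        fit = fit_zt_poisson([1] * 50)
        assert fit["boundary"] is True
        assert fit["lambda"] == 0.0

    def test_recovery_within_tolerance_at_ten_thousand(self):
        x = sample_zt_poisson(3.0, 10_000, np.random.default_rng(7))
        fit = fit_zt_poisson(x)
        assert abs(fit["lambda"] - 3.0) < 0.05
        assert fit["gof_p"] > 0.01

    def test_mean_inversion_closed_form(self):
        # the ZT-Poisson mean at lambda=3 is 3/(1-e^-3) = 3.157...;
        # a sample with exactly that mean must give lambda ~ 3
        assert zt_poisson_mean(3.0) == pytest.approx(3.1571871, abs=1e-6)
        n = 10_000
        target_mean = zt_poisson_mean(3.0)
        # construct integer sample with the target mean
        base = int(target_mean)
        n_high = round((target_mean - base) * n)
        sample = [base + 1] * n_high + [base] * (n - n_high)
        fit = fit_zt_poisson(sample)
        assert fit["lambda"] == pytest.approx(3.0, abs=0.01)

    def test_misfit_distribution_rejected(self):
        # geometric copy numbers are not ZT-Poisson; GOF should reject
        rng = np.random.default_rng(1)
        x = rng.geometric(0.25, size=5000)
        fit = fit_zt_poisson(x)
        assert fit["gof_p"] < 0.01

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_zt_poisson([0, 1, 2])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        r, p, log10p = pearson_with_log_p(x, x)
        assert r == 1.0
        assert p == 0.0

    def test_matches_direct_formula_with_outlier(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        r, p, _ = pearson_with_log_p(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_swap_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.random(50)
        y = 2 * x + rng.normal(0, 0.1, 50)
        r_xy, *_ = pearson_with_log_p(x, y)
        r_yx, *_ = pearson_with_log_p(y, x)
        r_scaled, *_ = pearson_with_log_p(3.5 * x - 1.0, 0.25 * y + 7.0)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_xy == pytest.approx(r_scaled, abs=1e-10)

    def test_extreme_p_survives_in_log_space(self):
        # a near-perfect correlation at n=2000 has p far below float
        # underflow; log10_p must remain finite and informative
        rng = np.random.default_rng(4)
        x = rng.random(2000)
        y = x + rng.normal(0, 1e-3, 2000)
        r, p, log10p = pearson_with_log_p(x, y)
        assert r > 0.999
        assert math.isfinite(log10p)
        assert log10p < -300

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_log_p(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestArrayF1Correlation:
    def test_identical_frequencies_give_r_one_no_outliers(self):
        counts = {f"B{i}": 10 * (i + 1) for i in range(20)}
        array = SampleProfile.from_counts("array", counts)
        reps = [SampleProfile.from_counts(f"r{i}", counts) for i in range(4)]
        result = array_f1_correlation(array, reps)
        assert result["pooled"]["r"] == pytest.approx(1.0)
        assert result["outliers"] == []

    def test_planted_bias_flagged_with_direction(self):
        result = correlation_experiment(3, bias_factors=(4.0, 0.25))
        over, under = result["planted_outliers"]
        flagged = {o["barcode"]: o["direction"] for o in result["outliers"]}
        assert flagged == {over: "over", under: "under"}

    def test_unbiased_experiment_has_no_outliers_and_high_r(self):
        result = correlation_experiment(5)
        assert result["outliers"] == []
        assert result["pooled"]["r"] > 0.99
        assert result["n_universe"] == 91  # all integrants come from the array

    def test_intersection_universe_shrinks_to_common_barcodes(self):
        array = SampleProfile.from_counts("a", {"X": 8, "Y": 4, "Z": 2, "W": 1})
        rep = SampleProfile.from_counts("r", {"X": 9, "Y": 3, "Z": 2, "Q": 1})
        union = array_f1_correlation(array, [rep])
        inter = array_f1_correlation(
            array, [rep], StatsParams(correlation_universe="intersection")
        )
        assert union["n_universe"] == 5
        assert inter["n_universe"] == 3


def test_promoter_panel_tally():
    tally = promoter_tally()
    assert tally == {"n_injected": 13, "n_in_array": 12, "n_integrated": 9}
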