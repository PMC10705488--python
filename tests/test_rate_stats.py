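"""Rate estimators, resampling tests, BH correction and windowing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lohdrive import (MarkerMap, arm_chisq, bh_adjust, bootstrap_ci,
                      conversion_rate, event_rate, normalized_rate,
                      permutation_test, wasserstein_test, window_rates)


class TestEventRate:
    def test_control_strain_rate(self):
        # 785 corrected events over 79 lines x 800 generations
        assert event_rate(785, 79, 800) == pytest.approx(1.24e-2, abs=5e-5)

    def test_cas9_strain_rate(self):
        assert event_rate(936, 83, 800) == pytest.approx(1.41e-2, abs=5e-5)

    def test_events_per_line(self):
        assert event_rate(553, 79, 1) == pytest.approx(7.0, abs=0.01)
        assert event_rate(936, 83, 1) == pytest.approx(11.2, abs=0.1)

    def test_zero_events(self):
        assert event_rate(0, 79, 800) == 0.0

    def test_per_bp_variant(self):
        assert event_rate(8, 2, 100, L=1000) == pytest.approx(8 / (2 * 100 * 1000))

    def test_division_guards(self):
        with pytest.raises(ValueError):
            event_rate(1, 0, 800)
        with pytest.raises(ValueError):
            event_rate(1, 10, 800, L=0)


class TestConversionRate:
    def test_typical_control_clone(self):
        # 6.1% of the genome converted over 800 generations
        assert conversion_rate([0.061], 800) == pytest.approx(7.6e-5, abs=0.05e-5)

    def test_bounds(self):
        assert conversion_rate([0.0, 0.0], 800) == 0.0
        assert conversion_rate([1.0], 1) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            conversion_rate([1.2], 800)

    def test_simulated_fractions_in_unit_interval(self, small_cohort):
        gm, _, _ = small_cohort
        frac = gm.het_fraction_converted()
        assert ((frac >= 0) & (frac <= 1)).all()


class TestBootstrapCI:
    def test_identical_values_zero_width(self):
        lo, hi = bootstrap_ci([4.0] * 10, seed=0)
        assert lo == hi == 4.0

    def test_seed_reproducibility(self):
        values = [1, 5, 3, 8, 2, 9, 4]
        assert bootstrap_ci(values, seed=7) == bootstrap_ci(values, seed=7)

    def test_interval_brackets_sample_mean(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(10, 60)
        lo, hi = bootstrap_ci(v, seed=2)
        assert lo <= v.mean() <= hi

    def test_coverage_close_to_nominal(self):
        # Poisson clones: the 95% interval covers the true mean ~95% of cohorts
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            v = rng.poisson(13.2, 95)
            lo, hi = bootstrap_ci(v, n_boot=500, seed=rng)
            hits += lo <= 13.2 <= hi
        assert 0.90 <= hits / n_rep <= 0.985

    def test_needs_two_clones(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


class TestPermutationTest:
    def test_identical_groups_p_near_one(self):
        res = permutation_test([1, 2, 3, 4], [1, 2, 3, 4], n_perm=500, seed=0)
        assert res.p_value > 0.9

    def test_exact_matches_manual_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 9.0, 11.0]
        res = permutation_test(a, b, method="exact")
        pooled = a + b
        observed = np.mean(a) - np.mean(b)
        diffs = []
        for idx in combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            diffs.append(np.mean(ga) - np.mean(gb))
        expected_p = np.mean(np.abs(diffs) >= abs(observed))
        assert res.n_resamples == 20
        assert res.p_value == pytest.approx(expected_p)

    def test_monte_carlo_approaches_exact(self):
        a, b = [1.0, 4.0, 6.0, 2.0], [7.0, 9.0, 11.0, 8.0]
        exact = permutation_test(a, b, method="exact")
        mc = permutation_test(a, b, method="mc", n_perm=20_000, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_one_sided_option(self):
        a, b = [10.0, 11.0, 12.0], [1.0, 2.0, 3.0]
        greater = permutation_test(a, b, sidedness="greater", method="exact")
        less = permutation_test(a, b, sidedness="less", method="exact")
        assert greater.p_value < less.p_value

    def test_median_statistic(self):
        res = permutation_test([1, 1, 1, 10], [1, 1, 1, 1], statistic="median",
                               n_perm=200, seed=0)
        assert res.p_value > 0.5    # medians identical

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning):
            permutation_test([1, 2, 3], [7, 8, 9], n_perm=50, method="mc", seed=0)


class TestWassersteinTest:
    def test_identical_samples_zero_statistic(self):
        res = wasserstein_test([5.0, 10.0, 20.0], [5.0, 10.0, 20.0],
                               n_mc=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value > 0.9

    def test_separated_samples(self):
        a = [100.0, 200.0, 300.0, 150.0, 250.0]
        b = [90_100.0, 90_200.0, 90_300.0, 90_150.0, 90_250.0]
        res = wasserstein_test(a, b, n_mc=500, seed=0)
        assert res.statistic == pytest.approx(90_000.0)
        assert res.p_value < 0.02

    def test_exact_matches_manual_enumeration(self):
        a, b = [1.0, 5.0], [8.0, 12.0]
        res = wasserstein_test(a, b, method="exact")
        pooled = a + b
        observed = sps.wasserstein_distance(a, b)
        dists = []
        for idx in combinations(range(4), 2):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(4) if i not in idx]
            dists.append(sps.wasserstein_distance(ga, gb))
        assert res.p_value == pytest.approx(np.mean(np.array(dists) >= observed))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_test([], [1.0])


class TestArmChisq:
    def test_matches_hand_formula_2x2(self):
        a, b, c, d = 10, 20, 20, 10
        n = a + b + c + d
        chi2_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = arm_chisq(np.array([[a, b], [c, d]]))
        assert res.statistic == pytest.approx(chi2_hand)
        assert res.p_value == pytest.approx(sps.chi2.sf(chi2_hand, 1))

    def test_identical_distributions(self):
        res = arm_chisq(np.array([[25, 25, 25], [25, 25, 25]]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_count_arms_pooled_out(self):
        res = arm_chisq(np.array([[10, 0, 20], [12, 0, 18]]))
        assert np.isfinite(res.statistic)

    def test_rejection_rate_matches_alpha(self):
        rng = np.random.default_rng(4)
        alpha, n_rep = 0.05, 400
        rejections = 0
        for _ in range(n_rep):
            table = rng.poisson(25, size=(2, 8))
            if (table.sum(axis=0) == 0).any():
                continue
            rejections += arm_chisq(table).p_value <= alpha
        rate = rejections / n_rep
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_rep)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            arm_chisq(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            arm_chisq(np.array([[0, 5], [0, 7]]))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        adjusted, reject = bh_adjust([0.03])
        assert adjusted[0] == pytest.approx(0.03)
        assert reject[0]

    def test_equal_ps_unchanged(self):
        adjusted, _ = bh_adjust([0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(adjusted, 0.2)

    def test_matches_textbook_step_up(self):
        # worked by hand: sorted p*(m/rank), then running min from the top
        p = [0.005, 0.04, 0.03, 0.01, 0.20]
        adjusted, _ = bh_adjust(p)
        np.testing.assert_allclose(adjusted, [0.025, 0.05, 0.05, 0.025, 0.20])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 30)
        adjusted, _ = bh_adjust(p)
        assert np.all(adjusted >= p - 1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestNormalizedRate:
    @pytest.mark.parametrize("rs,rw,expected", [
        (3.0, 3.0, 0.0), (5.0, 0.0, 1.0), (2.0, 1.0, 1 / 3),
    ])
    def test_known_values(self, rs, rw, expected):
        assert normalized_rate(rs, rw) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert np.isnan(normalized_rate(0.0, 0.0))

    @settings(max_examples=100, deadline=None)
    @given(a=st.floats(0, 1e3), b=st.floats(0, 1e3))
    def test_antisymmetry(self, a, b):
        if a + b == 0:
            return
        assert normalized_rate(a, b) == pytest.approx(-normalized_rate(b, a))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            normalized_rate(-1.0, 1.0)


class TestWindowRates:
    @pytest.fixture()
    def one_chrom_map(self):
        return MarkerMap([("c", 230_000)], {"c": (100_000, 100_200)},
                         {"c": np.array([1_000, 225_000])})

    def test_terminal_window_shorter_and_flagged(self, one_chrom_map):
        events = pd.DataFrame({"chrom": [], "breakpoint": []})
        tab = window_rates(events, one_chrom_map, n=10, T=800)
        assert len(tab) == 5
        assert tab.iloc[-1]["L"] == 30_000
        assert bool(tab.iloc[-1]["short_window"])
        assert not tab.iloc[0]["short_window"]

    def test_boundary_breakpoint_in_first_window(self, one_chrom_map):
        events = pd.DataFrame({"chrom": ["c", "c"], "breakpoint": [50_000, 50_001]})
        tab = window_rates(events, one_chrom_map, n=10, T=800)
        assert tab.iloc[0]["k"] == 1 and tab.iloc[1]["k"] == 1

    def test_counts_conserved(self, one_chrom_map):
        rng = np.random.default_rng(2)
        events = pd.DataFrame({
            "chrom": ["c"] * 40,
            "breakpoint": rng.uniform(1, 230_000, 40),
        })
        tab = window_rates(events, one_chrom_map, n=10, T=800)
        assert tab["k"].sum() == 40

    def test_sliding_windows_overlap(self, one_chrom_map):
        events = pd.DataFrame({"chrom": ["c"], "breakpoint": [55_000.0]})
        tab = window_rates(events, one_chrom_map, n=10, T=800, slide=10_000)
        # a single event lands in every 50-kb window covering position 55 kb
        assert (tab["k"] == 1).sum() == 5
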