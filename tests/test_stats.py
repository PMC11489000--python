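"""Cohort statistics: comparison paths, variance gating, correlation
screens, power, and summary-table construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lungmap as lm
from lungmap.cohort import CohortParams, sample_cohort_truth
from lungmap.stats import (
    _two_sample_power,
    adjust_benjamini_hochberg,
    build_summary_tables,
)


class TestPaired:
    def test_identical_vectors(self):
        r = lm.paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_zero_variance_nonzero_differences_flagged(self):
        r = lm.paired_comparison([0, 0, 0, 0], [1, 1, 1, 1])
        assert r.p_value == np.finfo(float).tiny
        assert "degenerate" in r.extra

    def test_textbook_closed_form(self):
        """Three pairs with differences {1, 2, 0}: t = dbar/(s/sqrt(n)) =
        1/(1/sqrt(3)) = sqrt(3), df = 2."""
        r = lm.paired_comparison([1.0, 2.0, 3.0], [2.0, 4.0, 3.0])
        t_hand = np.sqrt(3.0)
        assert r.statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.p_value == pytest.approx(2 * sps.t.sf(t_hand, 2), rel=1e-12)
        assert r.estimate == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lm.paired_comparison([1, 2, 3], [1, 2])

    def test_monte_carlo_power_hr_effect(self):
        """A +3 bpm shift with SD 4 at n=14 is detected (p<0.05) in at
        least 70% of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 500
        for _ in range(reps):
            pre = rng.normal(68.0, 10.0, 14)
            post = pre + rng.normal(3.0, 4.0, 14)
            hits += lm.paired_comparison(pre, post).p_value < 0.05
        assert hits / reps >= 0.70


class TestIndependent:
    def test_equal_groups_zero_statistic(self):
        r = lm.independent_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0

    def test_variance_gate_selects_welch(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, np.sqrt(10), 20)
        r = lm.independent_comparison(a, b)
        assert r.method == "welch-t"
        assert r.extra["levene_p"] <= 0.05

    def test_matched_variances_pool(self):
        rng = np.random.default_rng(2)
        r = lm.independent_comparison(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert r.method == "independent-t"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            lm.independent_comparison([1.0], [1.0, 2.0])


class TestTypeOneErrorCalibration:
    def test_paired_path_calibrated(self):
        rng = np.random.default_rng(7)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            pre = rng.normal(0, 1, 14)
            post = pre + rng.normal(0, 1, 14)
            rejections += lm.paired_comparison(pre, post).p_value < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_independent_path_calibrated(self):
        rng = np.random.default_rng(8)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            rejections += lm.independent_comparison(a, b).p_value < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02


class TestCorrelationScreen:
    def test_monotone_gives_unit_spearman(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        df["y"] = df.x**3
        (r,) = lm.correlation_screen(df, [("x", "y")], method="spearman")
        assert r.estimate == pytest.approx(1.0)

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": -x + rng.normal(0, 0.01, 50)})
        (r,) = lm.correlation_screen(df, [("x", "y")], method="pearson")
        assert r.estimate < -0.99
        assert r.p_value < 1e-6

    def test_pairwise_deletion_counts(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan, 6],
                           "y": [2.0, 4, 6, 8, 10, np.nan]})
        (r,) = lm.correlation_screen(df, [("x", "y")], method="pearson")
        assert r.n == (4,)
        assert r.extra["n_dropped"] == 2

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        (r,) = lm.correlation_screen(df, [("x", "y")])
        assert np.isnan(r.estimate)
        assert "flag" in r.extra

    def test_bmi_perfusion_slope_detected_in_majority_of_replicates(self):
        """A BMI->dQ slope giving population Spearman rho ~ -0.7 at n=14 is
        flagged significant in the majority of replicates."""
        rng = np.random.default_rng(11)
        reps, sig, neg = 500, 0, 0
        for _ in range(reps):
            bmi = rng.normal(24.6, 4.0, 14)
            dq = -0.06 * (bmi - 24.6) + rng.normal(0, 0.25, 14)
            df = pd.DataFrame({"bmi": bmi, "dq": dq})
            (r,) = lm.correlation_screen(df, [("bmi", "dq")], method="spearman")
            sig += r.p_value < 0.05
            neg += r.estimate < 0
        assert sig / reps > 0.5
        assert neg / reps > 0.9

    def test_bh_adjustment_passthrough(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)[::-1]})
        res = lm.correlation_screen(df, [("x", "y")], method="pearson")
        adj = adjust_benjamini_hochberg(res)
        assert adj.shape == (1,)
        assert adj[0] >= res[0].p_value - 1e-15


class TestRequiredSampleSize:
    def test_medium_effect_reference_value(self):
        n = lm.required_sample_size(0.5, alpha=0.05, power=0.80)
        assert n == 64
        # bracketing check against the exact power function
        assert _two_sample_power(63, 0.5, 0.05) < 0.80 <= _two_sample_power(64, 0.5, 0.05)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        sm_n = TTestIndPower().solve_power(effect_size=0.5, alpha=0.05, power=0.80)
        assert lm.required_sample_size(0.5) == int(np.ceil(sm_n))

    def test_tiny_effect_needs_huge_sample(self):
        assert lm.required_sample_size(0.009, 0.05, 0.80) > 185_000
        assert lm.required_sample_size(0.009, 0.05, 0.80, method="normal") > 185_000

    def test_power_near_alpha_needs_minimum_n(self):
        assert lm.required_sample_size(2.0, alpha=0.05, power=0.06) == 2

    def test_monotone_in_effect_and_power(self):
        ns_d = [lm.required_sample_size(d) for d in (0.2, 0.5, 0.8)]
        assert ns_d == sorted(ns_d, reverse=True)
        ns_p = [lm.required_sample_size(0.5, power=p) for p in (0.5, 0.8, 0.95)]
        assert ns_p == sorted(ns_p)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            lm.required_sample_size(0.0)


@pytest.fixture(scope="module")
def null_cohort():
    params = CohortParams(
        sv_mean_control=0.20, sv_sd_control=0.05,
        sv_mean_vaper=0.20, sv_post_shift=0.0,
        q_mean_control=1.45, q_mean_vaper=1.45,
        hr_post_increase=0.0, bmi_dq_slope=0.0,
        n_controls=10, n_vapers=10,
    )
    truth = sample_cohort_truth(params, seed=5)
    return truth.rename(columns={
        "mean_sv_true": "mean_sv", "mean_q_true": "mean_q",
        "rd_sv_true": "rd_sv", "rd_q_true": "rd_q",
    })


class TestSummaryTables:
    def test_row_count_matches_metrics(self, null_cohort):
        report = build_summary_tables(null_cohort, metrics=["mean_sv", "mean_q"])
        assert len(report) == 2

    def test_null_cohort_shows_no_systematic_effects(self, null_cohort):
        report = build_summary_tables(
            null_cohort, metrics=["mean_sv", "mean_q", "heart_rate"]
        )
        p = report[["p_control_vs_pre", "p_control_vs_post", "p_pre_vs_post"]]
        assert (p.to_numpy() > 0.01).mean() >= 0.8

    def test_formatted_strings_round_trip(self, null_cohort):
        report = build_summary_tables(null_cohort, metrics=["mean_sv"])
        row = report.iloc[0]
        mean_str, sd_str = row["pre"].replace(")", "").split(" (")
        assert float(mean_str) == pytest.approx(row["pre_mean"], abs=5e-3)
        assert float(sd_str) == pytest.approx(row["pre_sd"], abs=5e-3)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_summary_tables(pd.DataFrame({"a": [1]}))
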