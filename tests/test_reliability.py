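import itertools
import math

import numpy as np
import pytest
from scipy import stats

from slskit.errors import DegenerateDataError
from slskit.kinematics import filter_available, score_cohort
from slskit.reliability import (
    PairedSeries,
    VarianceComponents,
    analyze_reliability,
    analyze_variable,
    bland_altman,
    descriptives,
    icc_agreement,
    icc_label,
    mean_difference_ci,
    sem_agreement,
    smallest_detectable_change,
    spearman_label,
    spearman_rho,
    variance_components,
    wilcoxon_signed_rank,
)
from slskit.synthetic import CohortConfig, generate_cohort, generate_true_angles


def series(t1, t2, name="var"):
    return PairedSeries(name=name, t1=np.asarray(t1, float), t2=np.asarray(t2, float))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact p by brute force over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def anova_ss_oracle(y):
    """Sum-of-squares decomposition computed from cell deviations."""
    y = np.asarray(y, float)
    n, k = y.shape
    grand = y.mean()
    row = y.mean(axis=1, keepdims=True)
    col = y.mean(axis=0, keepdims=True)
    msr = (k * ((row - grand) ** 2).sum()) / (n - 1)
    msc = (n * ((col - grand) ** 2).sum()) / (k - 1)
    resid = y - row - col + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return msr, msc, mse


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

class TestDescriptives:
    def test_grand_median_pools_both_occasions(self):
        d = descriptives(series([1, 2, 3], [1, 2, 3]))
        assert d.grand_median == 2.0

    def test_pooled_even_count_interpolates(self):
        d = descriptives(series([1, 2], [3, 4]))
        assert d.grand_median == 2.5

    def test_against_sort_and_interpolate_oracle(self, rng):
        t1 = rng.normal(size=11)
        t2 = rng.normal(size=11)
        d = descriptives(series(t1, t2))

        def quantile_oracle(values, q):
            v = np.sort(values)
            h = (len(v) - 1) * q
            lo, hi = int(math.floor(h)), int(math.ceil(h))
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        assert d.median_t1 == pytest.approx(quantile_oracle(t1, 0.5))
        assert d.q1_t2 == pytest.approx(quantile_oracle(t2, 0.25))
        assert d.q3_t1 == pytest.approx(quantile_oracle(t1, 0.75))
        pooled = np.concatenate([t1, t2])
        assert d.grand_median == pytest.approx(quantile_oracle(pooled, 0.5))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_three_pairs(self):
        # all 2^3 sign assignments: only the all-positive one reaches W+ = 6
        res = wilcoxon_signed_rank(series([0, 0, 0], [1, 2, 3]))
        assert res.exact
        assert res.p_value == pytest.approx(0.25)

    def test_symmetric_differences(self):
        res = wilcoxon_signed_rank(series([0, 0], [1, -1]))
        assert res.p_value == 1.0

    def test_matches_enumeration_oracle_n10(self, rng):
        for _ in range(10):
            t1 = rng.normal(size=10)
            t2 = t1 + rng.normal(0.3, 1.0, size=10)
            res = wilcoxon_signed_rank(series(t1, t2))
            expected = wilcoxon_enumeration_oracle(t2 - t1)
            assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_with_tied_ranks(self):
        t1 = np.zeros(6)
        t2 = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(series(t1, t2))
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(t2), abs=1e-12)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank(series([1, 2, 3, 4], [1, 2, 4, 5]))
        assert res.n_used == 2

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(series([1, 2, 3], [1, 2, 3]))
        assert res.p_value == 1.0

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        t1 = rng.normal(size=40)
        t2 = t1 + rng.normal(0.2, 1.0, size=40)
        res = wilcoxon_signed_rank(series(t1, t2))
        assert not res.exact
        expected = stats.wilcoxon(t2, t1, correction=True, method="approx").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_significance_flag(self):
        res = wilcoxon_signed_rank(series(np.zeros(8), np.arange(1, 9)))
        assert res.p_value < 0.05
        assert res.significant


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_increasing(self):
        res = spearman_rho(series([1, 2, 3, 4], [10, 20, 30, 40]))
        assert res.rho == pytest.approx(1.0)

    def test_perfect_reversed(self):
        res = spearman_rho(series([1, 2, 3, 4], [8, 6, 4, 2]))
        assert res.rho == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho(series([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize(
        "rho,label",
        [(0.2, "low"), (0.53, "fair"), (0.61, "moderately strong"),
         (0.85, "very strong"), (-0.7, "moderately strong")],
    )
    def test_labels(self, rho, label):
        assert spearman_label(rho) == label


# ---------------------------------------------------------------------------
# variance components / ICC / SEM / SDC
# ---------------------------------------------------------------------------

class TestVarianceComponents:
    def test_hand_worked_example(self):
        # subjects (1,2), (3,4), (5,6): MSR=8, MSC=1.5, MSE=0
        vc = variance_components(series([1, 3, 5], [2, 4, 6]))
        assert vc.msr == pytest.approx(8.0)
        assert vc.msc == pytest.approx(1.5)
        assert vc.mse == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_p == pytest.approx(4.0)
        assert vc.sigma2_o == pytest.approx(0.5)
        assert vc.sigma2_res == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_have_no_error_variance(self):
        vc = variance_components(series([1, 5, 9], [1, 5, 9]))
        assert vc.sigma2_o == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_res == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_p > 0

    def test_against_sum_of_squares_oracle(self, rng):
        t1 = rng.normal(size=15)
        t2 = rng.normal(size=15)
        vc = variance_components(series(t1, t2))
        msr, msc, mse = anova_ss_oracle(np.column_stack([t1, t2]))
        assert vc.msr == pytest.approx(msr)
        assert vc.msc == pytest.approx(msc)
        assert vc.mse == pytest.approx(mse)

    def test_negative_estimates_truncated(self, rng):
        # with pure noise the occasion component is often negative pre-truncation
        for seed in range(5):
            r = np.random.default_rng(seed)
            vc = variance_components(series(r.normal(size=8), r.normal(size=8)))
            assert vc.sigma2_o >= 0
            assert vc.sigma2_p >= 0


class TestICC:
    def test_worked_example(self):
        vc = variance_components(series([1, 3, 5], [2, 4, 6]))
        res = icc_agreement(vc)
        assert res.icc == pytest.approx(4.0 / 4.5)

    def test_perfect_agreement(self):
        vc = VarianceComponents(sigma2_p=3.0, sigma2_o=0.0, sigma2_res=0.0,
                                msr=6.0, msc=0.0, mse=0.0, n=10, k=2)
        assert icc_agreement(vc).icc == 1.0

    def test_formula_on_target_components(self):
        vc = VarianceComponents(sigma2_p=75.0, sigma2_o=5.0, sigma2_res=20.0,
                                msr=170.0, msc=120.0, mse=20.0, n=20, k=2)
        res = icc_agreement(vc)
        assert res.icc == pytest.approx(0.75)
        assert res.label == "substantial"

    def test_all_zero_components_undefined(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, n=5, k=2)
        with pytest.raises(DegenerateDataError):
            icc_agreement(vc)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t1 = rng.normal(10, 3, size=20)
        t2 = t1 + rng.normal(0.5, 1.5, size=20)
        res = icc_agreement(variance_components(series(t1, t2)))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 2),
            "rater": np.tile(["a", "b"], 20),
            "score": np.column_stack([t1, t2]).ravel(),
        })
        icc_table = pingouin.intraclass_corr(long, targets="subject",
                                             raters="rater", ratings="score")
        icc_table["Type"] = icc_table["Type"].str.replace("ICC2", "ICC(A,1)")
        ref = icc_table.set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-6)
        ci_col = "CI95%" if "CI95%" in ref.index else "CI95"
        lo, hi = ref[ci_col]  # pingouin rounds its interval to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=0.006)
        assert res.ci_high == pytest.approx(hi, abs=0.006)

    def test_shift_invariance(self, rng):
        t1 = rng.normal(size=12)
        t2 = rng.normal(size=12)
        a = icc_agreement(variance_components(series(t1, t2))).icc
        b = icc_agreement(variance_components(series(t1 + 100, t2 + 100))).icc
        assert a == pytest.approx(b)

    def test_inflating_occasion_variance_lowers_icc(self, rng):
        t1 = rng.normal(10, 3, size=15)
        t2 = t1 + rng.normal(0, 1, size=15)
        base = icc_agreement(variance_components(series(t1, t2))).icc
        shifted = icc_agreement(variance_components(series(t1, t2 + 5.0))).icc
        assert shifted < base

    @pytest.mark.parametrize(
        "icc,label",
        [(0.1, "slight"), (0.3, "fair"), (0.5, "moderate"),
         (0.69, "substantial"), (0.9, "almost perfect"), (-0.1, "poor")],
    )
    def test_labels(self, icc, label):
        assert icc_label(icc) == label


class TestSemSdc:
    def test_sem_square_root_oracle(self):
        vc = VarianceComponents(4.0, 0.5, 0.0, 8.0, 1.5, 0.0, n=3, k=2)
        assert sem_agreement(vc) == pytest.approx(math.sqrt(0.5))
        assert sem_agreement(vc) == pytest.approx(0.707, abs=5e-4)

    def test_sem_zero(self):
        vc = VarianceComponents(4.0, 0.0, 0.0, 8.0, 0.0, 0.0, n=3, k=2)
        assert sem_agreement(vc) == 0.0

    def test_sem_backconstructed_scale(self):
        vc = VarianceComponents(100.0, 50.0, 63.6, 0.0, 0.0, 63.6, n=30, k=2)
        assert sem_agreement(vc) == pytest.approx(10.66, abs=0.005)

    @pytest.mark.parametrize("sem,sdc", [(10.66, 29.55), (9.85, 27.30),
                                         (9.04, 25.06), (9.09, 25.20), (0.0, 0.0)])
    def test_sdc_examples(self, sem, sdc):
        assert round(smallest_detectable_change(sem), 2) == pytest.approx(sdc)

    def test_sdc_sem_ratio_constant(self):
        for sem in (0.3, 1.0, 9.04, 10.66, 50.0):
            ratio = smallest_detectable_change(sem) / sem
            assert ratio == pytest.approx(2.77185, abs=1e-5)

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            smallest_detectable_change(-1.0)


# ---------------------------------------------------------------------------
# mean difference and Bland-Altman
# ---------------------------------------------------------------------------

class TestMeanDifference:
    def test_constant_positive_shift_is_systematic(self):
        res = mean_difference_ci(series([1, 2, 3], [6, 7, 8]))
        assert res.mean == pytest.approx(5.0)
        assert res.ci_low == res.ci_high == pytest.approx(5.0)
        assert res.systematic

    def test_symmetric_differences_not_systematic(self):
        res = mean_difference_ci(series([0, 0, 0, 0], [2, -2, 1, -1]))
        assert not res.systematic

    def test_against_t_interval_oracle(self, rng):
        t1 = rng.normal(size=20)
        t2 = t1 + rng.normal(1.0, 2.0, size=20)
        res = mean_difference_ci(series(t1, t2))
        d = t2 - t1
        lo, hi = stats.t.interval(0.95, len(d) - 1, loc=d.mean(),
                                  scale=d.std(ddof=1) / math.sqrt(len(d)))
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman(series([1, 2, 3], [1, 2, 3]))
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman(series([1, 2, 3], [4, 5, 6]))
        assert res.bias == pytest.approx(3.0)
        assert res.loa_low == pytest.approx(3.0)
        assert res.loa_high == pytest.approx(3.0)

    def test_against_sd_oracle(self, rng):
        t1 = rng.normal(size=25)
        t2 = t1 + rng.normal(0.5, 1.0, size=25)
        res = bland_altman(series(t1, t2))
        d = t2 - t1
        sd = math.sqrt(((d - d.mean()) ** 2).sum() / (len(d) - 1))
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * sd)
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * sd)
        assert len(res.means) == 25


# ---------------------------------------------------------------------------
# parameter recovery and whole-table analysis
# ---------------------------------------------------------------------------

class TestParameterRecovery:
    @pytest.mark.parametrize(
        "sigma2_p,sigma2_err,target",
        [(20.0, 20.0, 0.5), (44.5, 20.0, 0.69), (90.0, 10.0, 0.9)],
    )
    def test_icc_recovered_within_monte_carlo_tolerance(self, sigma2_p, sigma2_err, target):
        estimates = []
        for rep in range(40):
            config = CohortConfig(
                n_subjects=250, legs=("left",), sigma2_p=sigma2_p,
                sigma2_o=sigma2_err / 2, sigma2_res=sigma2_err / 2,
                seed=1000 + rep,
            )
            angles = generate_true_angles(config)
            down = angles[angles["direction"] == "down"].pivot(
                index=["subject", "leg"], columns="occasion",
                values="true_angle_medial",
            )
            vc = variance_components(series(down[1], down[2]))
            estimates.append(icc_agreement(vc).icc)
        assert np.mean(estimates) == pytest.approx(target, abs=0.03)

    def test_ci_coverage_near_nominal(self):
        target = 0.75
        hits = 0
        reps = 120
        for rep in range(reps):
            config = CohortConfig(
                n_subjects=60, legs=("left",), sigma2_p=75.0, sigma2_o=5.0,
                sigma2_res=20.0, seed=5000 + rep,
            )
            angles = generate_true_angles(config)
            down = angles[angles["direction"] == "down"].pivot(
                index=["subject", "leg"], columns="occasion",
                values="true_angle_medial",
            )
            res = icc_agreement(variance_components(series(down[1], down[2])))
            if res.ci_low <= target <= res.ci_high:
                hits += 1
        assert hits / reps == pytest.approx(0.95, abs=0.06)


class TestAnalyzeReliability:
    def test_full_table_on_simulated_cohort(self, small_scores):
        filtered = filter_available(small_scores, "reliability")
        rows = analyze_reliability(filtered.table)
        assert [r.name for r in rows] == [
            "left knee up", "left knee down", "right knee up", "right knee down",
        ]
        for row in rows:
            assert 0.0 <= row.icc.icc <= 1.0
            assert row.icc.ci_low <= row.icc.icc <= row.icc.ci_high
            assert row.sdc == pytest.approx(1.96 * math.sqrt(2) * row.sem)

    def test_occasion_shift_detected_as_systematic(self):
        config = CohortConfig(n_subjects=25, sigma2_p=40.0, sigma2_o=0.5,
                              sigma2_res=1.0, occasion_shift=6.0,
                              sensor_noise_sd=0.0, seed=77)
        cohort = generate_cohort(config)
        scores = score_cohort(cohort.trajectories)
        rows = analyze_reliability(scores)
        # the medial-positive shift appears in every variable
        for row in rows:
            assert row.wilcoxon.significant
            assert row.mean_difference.systematic

    def test_row_smoke_values(self, small_scores):
        from slskit.reliability import paired_series_from_scores

        filtered = filter_available(small_scores, "reliability")
        row = analyze_variable(paired_series_from_scores(filtered.table, "left", "down"))
        assert row.n_measurements == 2 * len(row.bland_altman.means)
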