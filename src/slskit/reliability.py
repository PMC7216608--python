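"""Test-retest reliability statistics for paired two-occasion measurements.

Implements the full per-variable analysis of a test-retest study:
descriptive medians and quartiles, Wilcoxon signed-rank test for a
systematic between-occasion difference, Spearman rank correlation, a
two-way ANOVA variance-component decomposition with the absolute-agreement
intraclass correlation, the standard error of measurement
``SEM = sqrt(sigma2_o + sigma2_res)``, the smallest detectable change
``SDC = 1.96 * sqrt(2) * SEM``, the t-based mean-difference confidence
interval, and Bland-Altman limits of agreement.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "PairedSeries",
    "Descriptives",
    "WilcoxonResult",
    "SpearmanResult",
    "VarianceComponents",
    "ICCResult",
    "MeanDifference",
    "BlandAltman",
    "ReliabilityRow",
    "descriptives",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "variance_components",
    "icc_agreement",
    "sem_agreement",
    "smallest_detectable_change",
    "mean_difference_ci",
    "bland_altman",
    "analyze_variable",
    "analyze_reliability",
    "icc_label",
    "spearman_label",
]

#: largest n for which the exact Wilcoxon null distribution is used
EXACT_WILCOXON_MAX_N = 25

SDC_FACTOR = 1.96 * math.sqrt(2.0)

#: Table-2 variable order: (name, leg, direction)
VARIABLES = (
    ("left knee up", "left", "up"),
    ("left knee down", "left", "down"),
    ("right knee up", "right", "up"),
    ("right knee down", "right", "down"),
)


@dataclass(frozen=True)
class PairedSeries:
    """Paired scores (deg) for one variable on two test occasions."""

    name: str
    t1: np.ndarray
    t2: np.ndarray

    def __post_init__(self):
        t1 = np.asarray(self.t1, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        if t1.ndim != 1 or t1.shape != t2.shape:
            raise ValueError("t1 and t2 must be 1-D arrays of equal length")
        if t1.size < 1:
            raise ValueError("series must be non-empty")
        if not (np.isfinite(t1).all() and np.isfinite(t2).all()):
            raise ValueError("series must be finite (apply pairwise deletion first)")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)

    @property
    def n(self) -> int:
        return int(self.t1.size)

    @property
    def differences(self) -> np.ndarray:
        return self.t2 - self.t1


@dataclass(frozen=True)
class Descriptives:
    median_t1: float
    q1_t1: float
    q3_t1: float
    median_t2: float
    q1_t2: float
    q3_t2: float
    grand_median: float
    grand_q1: float
    grand_q3: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    exact: bool

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    label: str


@dataclass(frozen=True)
class VarianceComponents:
    """Two-way ANOVA variance components (subjects × occasions)."""

    sigma2_p: float
    sigma2_o: float
    sigma2_res: float
    msr: float  # mean square rows (subjects)
    msc: float  # mean square columns (occasions)
    mse: float  # mean square error
    n: int
    k: int

    @property
    def sigma2_error(self) -> float:
        return self.sigma2_o + self.sigma2_res


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    label: str


@dataclass(frozen=True)
class MeanDifference:
    mean: float
    ci_low: float
    ci_high: float

    @property
    def systematic(self) -> bool:
        """True iff the 95% CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class BlandAltman:
    means: np.ndarray
    differences: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    proportional_slope: float


@dataclass(frozen=True)
class ReliabilityRow:
    """All Table-style statistics for one variable."""

    name: str
    n_measurements: int  # measurements = 2 * pairs
    descriptives: Descriptives
    wilcoxon: WilcoxonResult
    spearman: SpearmanResult
    components: VarianceComponents
    icc: ICCResult
    sem: float
    sdc: float
    mean_difference: MeanDifference
    bland_altman: BlandAltman


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation (type-7) quartiles
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def descriptives(series: PairedSeries) -> Descriptives:
    """Medians and quartiles per occasion plus the pooled grand median."""
    med1, q1_1, q3_1 = _quartiles(series.t1)
    med2, q1_2, q3_2 = _quartiles(series.t2)
    pooled = np.concatenate([series.t1, series.t2])
    gmed, gq1, gq3 = _quartiles(pooled)
    return Descriptives(med1, q1_1, q3_1, med2, q1_2, q3_2, gmed, gq1, gq3)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments by W+ (on ranks scaled x2 to integers)."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(series: PairedSeries) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of T2 vs T1.

    Zero differences are dropped (Wilcoxon's rule); ties in the absolute
    differences get mid-ranks.  For up to 25 remaining pairs the exact null
    distribution of the positive-rank sum is enumerated; beyond that a
    normal approximation with continuity and tie correction is used.  The
    two-sided p is ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    d = series.differences
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p-value degenerate at 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, exact=True)

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        scaled = np.round(2.0 * ranks).astype(int)  # mid-ranks are half-integers
        counts = _signed_rank_distribution(scaled)
        total = counts.sum()
        w_scaled = int(round(2.0 * w_plus))
        p_le = counts[: w_scaled + 1].sum() / total
        p_ge = counts[w_scaled:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, p_value=float(p), n_used=n, exact=True)

    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(np.abs(d), return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if sigma2 <= 0:
        warnings.warn("degenerate rank variance; p-value set to 1")
        return WilcoxonResult(statistic=w_plus, p_value=1.0, n_used=n, exact=False)
    correction = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - correction) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), n_used=n, exact=False)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman_label(rho: float) -> str:
    """Qualitative correlation-magnitude label."""
    r = abs(rho)
    if r < 0.3:
        return "low"
    if r < 0.6:
        return "fair"
    if r < 0.8:
        return "moderately strong"
    return "very strong"


def spearman_rho(series: PairedSeries) -> SpearmanResult:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    if series.n < 3:
        raise DegenerateDataError("Spearman correlation needs at least 3 pairs")
    if np.ptp(series.t1) == 0 or np.ptp(series.t2) == 0:
        raise DegenerateDataError("Spearman correlation undefined for a constant series")
    rho, p = stats.spearmanr(series.t1, series.t2)
    return SpearmanResult(rho=float(rho), p_value=float(p), label=spearman_label(float(rho)))


# ---------------------------------------------------------------------------
# variance components / ICC / SEM / SDC
# ---------------------------------------------------------------------------

def variance_components(series: PairedSeries) -> VarianceComponents:
    """Two-way ANOVA decomposition of an n-subjects × 2-occasions layout.

    sigma2_res = MSE; sigma2_o = max(0, (MSC - MSE) / n);
    sigma2_p = max(0, (MSR - MSE) / k).  Negative moment estimates are
    truncated at zero.
    """
    if series.n < 2:
        raise DegenerateDataError("variance components need at least 2 subjects")
    y = np.column_stack([series.t1, series.t2])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(0.0, sse) / ((n - 1) * (k - 1))
    return VarianceComponents(
        sigma2_p=max(0.0, (msr - mse) / k),
        sigma2_o=max(0.0, (msc - mse) / n),
        sigma2_res=mse,
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n=n,
        k=k,
    )


def icc_label(icc: float) -> str:
    """Qualitative agreement label for an intraclass correlation."""
    if icc < 0.0:
        return "poor"
    if icc <= 0.20:
        return "slight"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "substantial"
    return "almost perfect"


def icc_agreement(vc: VarianceComponents, alpha: float = 0.05) -> ICCResult:
    """Absolute-agreement single-measure ICC with an F-based 95% CI.

    Point estimate from the variance components::

        ICC = sigma2_p / (sigma2_p + sigma2_o + sigma2_res)

    The confidence interval is the McGraw-Wong interval for the two-way
    absolute-agreement single-measure coefficient, with Satterthwaite
    degrees of freedom.
    """
    denom = vc.sigma2_p + vc.sigma2_o + vc.sigma2_res
    if denom == 0:
        raise DegenerateDataError("all variance components zero; ICC undefined")
    icc = vc.sigma2_p / denom

    n, k = vc.n, vc.k
    msr, msc, mse = vc.msr, vc.msc, vc.mse
    if icc >= 1.0 or mse == 0 and msc <= mse:
        lo, hi = icc, icc
    else:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        lo, hi = min(lo, hi), max(lo, hi)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     label=icc_label(float(icc)))


def sem_agreement(vc: VarianceComponents) -> float:
    """Standard error of measurement: sqrt(sigma2_o + sigma2_res)."""
    return math.sqrt(vc.sigma2_o + vc.sigma2_res)


def smallest_detectable_change(sem: float) -> float:
    """Smallest detectable change: 1.96 * sqrt(2) * SEM."""
    if sem < 0:
        raise ValueError("SEM must be >= 0")
    return SDC_FACTOR * sem


# ---------------------------------------------------------------------------
# mean difference and Bland-Altman
# ---------------------------------------------------------------------------

def mean_difference_ci(series: PairedSeries, alpha: float = 0.05) -> MeanDifference:
    """t-based confidence interval for the mean T2 - T1 difference."""
    if series.n < 2:
        raise DegenerateDataError("mean-difference CI needs at least 2 pairs")
    d = series.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return MeanDifference(mean=mean, ci_low=mean, ci_high=mean)
    half = stats.t.ppf(1.0 - alpha / 2.0, series.n - 1) * sd / math.sqrt(series.n)
    return MeanDifference(mean=mean, ci_low=mean - half, ci_high=mean + half)


def bland_altman(series: PairedSeries) -> BlandAltman:
    """Bland-Altman points, bias, 95% limits of agreement, trend slope."""
    if series.n < 2:
        raise DegenerateDataError("Bland-Altman needs at least 2 pairs")
    means = (series.t1 + series.t2) / 2.0
    diffs = series.differences
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if np.ptp(means) > 0:
        slope = float(np.polynomial.polynomial.polyfit(means, diffs, 1)[1])
    else:
        slope = float("nan")
    return BlandAltman(
        means=means,
        differences=diffs,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_slope=slope,
    )


# ---------------------------------------------------------------------------
# per-variable and whole-table analysis
# ---------------------------------------------------------------------------

def analyze_variable(series: PairedSeries) -> ReliabilityRow:
    """Run the complete test-retest analysis for one variable."""
    vc = variance_components(series)
    sem = sem_agreement(vc)
    return ReliabilityRow(
        name=series.name,
        n_measurements=2 * series.n,
        descriptives=descriptives(series),
        wilcoxon=wilcoxon_signed_rank(series),
        spearman=spearman_rho(series),
        components=vc,
        icc=icc_agreement(vc),
        sem=sem,
        sdc=smallest_detectable_change(sem),
        mean_difference=mean_difference_ci(series),
        bland_altman=bland_altman(series),
    )


def paired_series_from_scores(score_table: pd.DataFrame, leg: str, direction: str,
                              value_prefix: str = "nta") -> PairedSeries:
    """Build a complete-pairs T1/T2 series for one variable from a score table.

    Uses the signed reported angles (``nta_down`` / ``nta_up``) by default;
    pass ``value_prefix='medial'`` for medial-positive values.  Subjects
    lacking a finite value on either occasion are dropped.
    """
    col = f"{value_prefix}_{direction}"
    sub = score_table[score_table["leg"] == leg]
    wide = sub.pivot_table(index="subject", columns="occasion", values=col, sort=False)
    if 1 not in wide.columns or 2 not in wide.columns:
        raise DegenerateDataError(f"need occasions 1 and 2 for {leg} knee {direction}")
    wide = wide[[1, 2]].dropna()
    return PairedSeries(
        name=f"{leg} knee {direction}",
        t1=wide[1].to_numpy(),
        t2=wide[2].to_numpy(),
    )


def analyze_reliability(score_table: pd.DataFrame) -> list[ReliabilityRow]:
    """Per-variable test-retest analysis in the standard reporting order."""
    rows = []
    for name, leg, direction in VARIABLES:
        series = paired_series_from_scores(score_table, leg, direction)
        rows.append(analyze_variable(series))
    return rows
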