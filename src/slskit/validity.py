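"""Construct validity of the dichotomized squat score against visual ratings.

The continuous down-phase medial-displacement angle is dichotomized at a
grid of cut-offs (fail iff medial displacement >= cut-off, so a tie counts
as fail and lateral values always pass) and each dichotomization is
compared with the consensus visual rating in a 2x2 table.  Per cut-off the
report carries percent agreement, Cohen's kappa ``(P0 - Pe)/(1 - Pe)`` with
an asymptotic 95% CI, sensitivity/specificity and predictive values with
exact Clopper-Pearson intervals, and the two-segment ROC area
``AUC = (Se + Sp)/2`` with a Hanley-McNeil standard error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up
from .errors import DegenerateDataError

DEFAULT_CUTOFFS: tuple[int, ...] = tuple(range(2, 21, 2))

PASS, FAIL = "pass", "fail"

REPORT_COLUMNS = [
    "cutoff_deg",
    "pa",
    "kappa", "kappa_ci_low", "kappa_ci_high",
    "sensitivity", "se_ci_low", "se_ci_high",
    "specificity", "sp_ci_low", "sp_ci_high",
    "ppv", "ppv_ci_low", "ppv_ci_high",
    "npv", "npv_ci_low", "npv_ci_high",
    "auc", "auc_se", "auc_ci_low", "auc_ci_high", "auc_label",
    "index_positive_rate",
]


@dataclass(frozen=True)
class Contingency2x2:
    """Index test vs reference standard (positive = fail rating)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        """Proportion of reference-positive (fail-rated) recordings."""
        return (self.tp + self.fn) / self.n

    @property
    def prevalence_percent(self) -> int:
        return int(round_half_up(100.0 * self.prevalence, 0))

    @property
    def index_positive_rate(self) -> float:
        return (self.tp + self.fp) / self.n


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with an exact 95% CI; may be undefined."""

    value: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class AgreementResult:
    pa: float
    kappa: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class DiagnosticStats:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    label: str


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-cut-off validity statistics plus the best cut-off by AUC."""

    table: pd.DataFrame
    prevalence: float
    prevalence_percent: int
    best_cutoff: float
    n: int


def dichotomize(medial_deg: float, cutoff: float) -> str:
    """Fail iff the medial displacement reaches the cut-off (tie = fail)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return FAIL if medial_deg >= cutoff else PASS


def consensus_label(label1: str, label2: str, adjudicator: str | None = None) -> str:
    """Resolve two raters into a consensus.

    Agreeing raters decide directly; a disagreement needs an adjudicating
    third rating.
    """
    for label in (label1, label2):
        if label not in (PASS, FAIL):
            raise ValueError(f"labels must be 'pass'/'fail', got {label!r}")
    if label1 == label2:
        return label1
    if adjudicator is None:
        raise DegenerateDataError("raters disagree and no adjudicator was provided")
    if adjudicator not in (PASS, FAIL):
        raise ValueError(f"adjudicator must be 'pass'/'fail', got {adjudicator!r}")
    return adjudicator


def contingency(index_labels: Iterable[str], reference_labels: Iterable[str]) -> Contingency2x2:
    """Cross-tabulate index-test vs reference labels."""
    index = list(index_labels)
    reference = list(reference_labels)
    if len(index) != len(reference):
        raise ValueError("index and reference label lists differ in length")
    tp = fp = fn = tn = 0
    for i, r in zip(index, reference):
        if i == FAIL and r == FAIL:
            tp += 1
        elif i == FAIL and r == PASS:
            fp += 1
        elif i == PASS and r == FAIL:
            fn += 1
        elif i == PASS and r == PASS:
            tn += 1
        else:
            raise ValueError(f"labels must be 'pass'/'fail', got ({i!r}, {r!r})")
    return Contingency2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def agreement_stats(t: Contingency2x2) -> AgreementResult:
    """Percent agreement and Cohen's kappa with an asymptotic 95% CI.

    ``kappa = (P0 - Pe) / (1 - Pe)`` with the chance agreement ``Pe``
    computed from the table margins; ``CI = kappa +- 1.96 * SE`` with the
    standard large-sample standard error.  A degenerate margin (Pe = 1)
    leaves kappa undefined and flagged.
    """
    n = t.n
    p0 = (t.tp + t.tn) / n
    row_fail = (t.tp + t.fp) / n  # index margin
    col_fail = (t.tp + t.fn) / n  # reference margin
    pe = row_fail * col_fail + (1 - row_fail) * (1 - col_fail)
    if pe >= 1.0:
        return AgreementResult(pa=p0, kappa=float("nan"),
                               ci_low=float("nan"), ci_high=float("nan"),
                               degenerate=True)
    kappa = (p0 - pe) / (1.0 - pe)
    se = math.sqrt(p0 * (1.0 - p0) / n) / (1.0 - pe)
    return AgreementResult(pa=p0, kappa=kappa,
                           ci_low=kappa - 1.96 * se, ci_high=kappa + 1.96 * se)


def _clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


def _proportion(x: int, n: int) -> ProportionEstimate:
    if n == 0:
        return ProportionEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    lo, hi = _clopper_pearson(x, n)
    return ProportionEstimate(x / n, lo, hi)


def diagnostic_stats(t: Contingency2x2) -> DiagnosticStats:
    """Se, Sp, PPV, NPV with exact Clopper-Pearson 95% CIs.

    Statistics with a zero denominator are returned undefined and flagged
    rather than raising.
    """
    return DiagnosticStats(
        sensitivity=_proportion(t.tp, t.tp + t.fn),
        specificity=_proportion(t.tn, t.tn + t.fp),
        ppv=_proportion(t.tp, t.tp + t.fp),
        npv=_proportion(t.tn, t.tn + t.fn),
    )


def auc_label(auc: float) -> str:
    """Accuracy label: >0.9 high, 0.7-0.9 moderate, >0.5 low, 0.5 chance."""
    if auc > 0.9:
        return "high accuracy"
    if auc >= 0.7:
        return "moderate accuracy"
    if auc > 0.5:
        return "low accuracy"
    if math.isclose(auc, 0.5):
        return "chance result"
    return "worse than chance"


def binary_auc(se: float, sp: float,
               n_positive: int | None = None,
               n_negative: int | None = None) -> AUCResult:
    """Area under the two-segment ROC of a dichotomous test.

    The ROC through (0,0), (1-Sp, Se), (1,1) has area ``(Se + Sp)/2``.  The
    standard error follows Hanley-McNeil when the reference-positive and
    -negative counts are supplied, with ``CI = AUC +- 1.96 * SE``.
    """
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    auc = (se + sp) / 2.0
    if n_positive and n_negative:
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc * auc / (1.0 + auc)
        var = (
            auc * (1.0 - auc)
            + (n_positive - 1) * (q1 - auc * auc)
            + (n_negative - 1) * (q2 - auc * auc)
        ) / (n_positive * n_negative)
        se_auc = math.sqrt(max(0.0, var))
        lo, hi = auc - 1.96 * se_auc, auc + 1.96 * se_auc
    else:
        se_auc, lo, hi = float("nan"), float("nan"), float("nan")
    return AUCResult(auc=auc, se=se_auc, ci_low=lo, ci_high=hi, label=auc_label(auc))


def cutoff_sweep(
    medial_deg: Sequence[float],
    reference_labels: Sequence[str],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> DiagnosticReport:
    """Full diagnostic-accuracy report over a grid of cut-offs.

    ``medial_deg`` are continuous down-phase medial displacements aligned
    with the consensus reference labels.  The best cut-off is the first
    argmax of AUC.
    """
    medial = np.asarray(medial_deg, dtype=float)
    reference = list(reference_labels)
    if medial.size == 0:
        raise DegenerateDataError("no recordings to sweep")
    if medial.size != len(reference):
        raise ValueError("scores and reference labels differ in length")
    if len(cutoffs) < 1:
        raise ValueError("need at least one cutoff")
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")

    prevalence_table = contingency([PASS] * len(reference), reference)
    rows = []
    for cutoff in cutoffs:
        index = [dichotomize(m, cutoff) for m in medial]
        t = contingency(index, reference)
        agreement = agreement_stats(t)
        diag = diagnostic_stats(t)
        auc = binary_auc(
            diag.sensitivity.value,
            diag.specificity.value,
            n_positive=t.tp + t.fn,
            n_negative=t.tn + t.fp,
        )
        rows.append({
            "cutoff_deg": float(cutoff),
            "pa": agreement.pa,
            "kappa": agreement.kappa,
            "kappa_ci_low": agreement.ci_low,
            "kappa_ci_high": agreement.ci_high,
            "sensitivity": diag.sensitivity.value,
            "se_ci_low": diag.sensitivity.ci_low,
            "se_ci_high": diag.sensitivity.ci_high,
            "specificity": diag.specificity.value,
            "sp_ci_low": diag.specificity.ci_low,
            "sp_ci_high": diag.specificity.ci_high,
            "ppv": diag.ppv.value,
            "ppv_ci_low": diag.ppv.ci_low,
            "ppv_ci_high": diag.ppv.ci_high,
            "npv": diag.npv.value,
            "npv_ci_low": diag.npv.ci_low,
            "npv_ci_high": diag.npv.ci_high,
            "auc": auc.auc,
            "auc_se": auc.se,
            "auc_ci_low": auc.ci_low,
            "auc_ci_high": auc.ci_high,
            "auc_label": auc.label,
            "index_positive_rate": t.index_positive_rate,
        })
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    best = float(table.loc[table["auc"].idxmax(), "cutoff_deg"])
    return DiagnosticReport(
        table=table,
        prevalence=prevalence_table.prevalence,
        prevalence_percent=prevalence_table.prevalence_percent,
        best_cutoff=best,
        n=int(medial.size),
    )


def consensus_from_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Extract per-recording consensus labels from a long ratings table.

    If a ``consensus`` rater row is present it is used directly; otherwise
    the two raters must agree (a disagreement without a consensus row is an
    error).
    """
    out = []
    for rec_id, group in ratings.groupby("recording_id", sort=False):
        by_rater = dict(zip(group["rater"], group["label"]))
        if "consensus" in by_rater:
            label = by_rater["consensus"]
        else:
            raters = [v for k, v in by_rater.items() if k != "consensus"]
            if len(raters) != 2:
                raise DegenerateDataError(
                    f"recording {rec_id}: expected two raters, got {len(raters)}"
                )
            label = consensus_label(raters[0], raters[1])
        out.append((rec_id, label))
    return pd.DataFrame(out, columns=["recording_id", "label"])
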