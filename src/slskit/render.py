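"""Report rendering: reliability and validity tables as CSV and Markdown.

Values are displayed rounded half-up to two decimals; statistically
significant p-values (p < 0.05) and mean differences whose 95% CI excludes
zero are starred.  The underlying CSV reports keep full numeric precision
in separate columns so they can be re-parsed losslessly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from ._utils import round_half_up
from .reliability import ReliabilityRow
from .validity import DiagnosticReport


def _fmt(x: float, ndigits: int = 2) -> str:
    return f"{round_half_up(float(x), ndigits):.{ndigits}f}"


def _fmt_p(p: float, ndigits: int = 3) -> str:
    text = f"{round_half_up(float(p), ndigits):.{ndigits}f}"
    return text + "*" if p < 0.05 else text


def reliability_table(rows: Sequence[ReliabilityRow]) -> pd.DataFrame:
    """Full-precision tidy table of the test-retest analysis."""
    out = []
    for row in rows:
        d = row.descriptives
        out.append({
            "variable": row.name,
            "n_measurements": row.n_measurements,
            "t1_median": d.median_t1, "t1_q1": d.q1_t1, "t1_q3": d.q3_t1,
            "t2_median": d.median_t2, "t2_q1": d.q1_t2, "t2_q3": d.q3_t2,
            "grand_median": d.grand_median,
            "grand_q1": d.grand_q1, "grand_q3": d.grand_q3,
            "wilcoxon_p": row.wilcoxon.p_value,
            "spearman_r": row.spearman.rho,
            "spearman_p": row.spearman.p_value,
            "icc": row.icc.icc,
            "icc_ci_low": row.icc.ci_low,
            "icc_ci_high": row.icc.ci_high,
            "icc_label": row.icc.label,
            "sem": row.sem,
            "sdc": row.sdc,
            "mean_diff": row.mean_difference.mean,
            "mean_diff_ci_low": row.mean_difference.ci_low,
            "mean_diff_ci_high": row.mean_difference.ci_high,
            "systematic_change": row.mean_difference.systematic,
        })
    return pd.DataFrame(out)


def reliability_markdown(rows: Sequence[ReliabilityRow], ndigits: int = 2) -> str:
    """Reliability report as a Markdown table in the standard column order."""
    header = (
        "| Variable | n | T1 Median (Q1, Q3) | T2 Median (Q1, Q3) | "
        "Grand Median (Q1, Q3) | T1 vs. T2 p | Spearman r (p) | "
        "ICC (95% CI) | SEM | SDC | Mean difference T2-T1 (95% CI) |"
    )
    sep = "|" + "---|" * 11
    lines = [header, sep]
    for row in rows:
        d = row.descriptives
        md = row.mean_difference
        star = "*" if md.systematic else ""
        lines.append(
            "| {name} | {n} | {t1} | {t2} | {grand} | {p} | {rho} | {icc} | "
            "{sem} | {sdc} | {diff} |".format(
                name=row.name,
                n=row.n_measurements,
                t1=f"{_fmt(d.median_t1, ndigits)} ({_fmt(d.q1_t1, ndigits)}, {_fmt(d.q3_t1, ndigits)})",
                t2=f"{_fmt(d.median_t2, ndigits)} ({_fmt(d.q1_t2, ndigits)}, {_fmt(d.q3_t2, ndigits)})",
                grand=f"{_fmt(d.grand_median, ndigits)} ({_fmt(d.grand_q1, ndigits)}, {_fmt(d.grand_q3, ndigits)})",
                p=_fmt_p(row.wilcoxon.p_value),
                rho=f"{_fmt(row.spearman.rho, ndigits)} ({_fmt_p(row.spearman.p_value)})",
                icc=f"{_fmt(row.icc.icc, ndigits)} ({_fmt(row.icc.ci_low, ndigits)} to {_fmt(row.icc.ci_high, ndigits)})",
                sem=_fmt(row.sem, ndigits),
                sdc=_fmt(row.sdc, ndigits),
                diff=f"{_fmt(md.mean, ndigits)} ({_fmt(md.ci_low, ndigits)} to {_fmt(md.ci_high, ndigits)}){star}",
            )
        )
    return "\n".join(lines) + "\n"


def validity_markdown(report: DiagnosticReport, ndigits: int = 2) -> str:
    """Diagnostic-accuracy report as a Markdown table, one row per cut-off."""
    header = (
        "| Cut-off | PA | Kappa (95% CI) | Sensitivity (95% CI) | "
        "Specificity (95% CI) | PPV (95% CI) | NPV (95% CI) | AUC (SE, 95% CI) |"
    )
    sep = "|" + "---|" * 8
    lines = [header, sep]
    for _, r in report.table.iterrows():
        best = " (best)" if r["cutoff_deg"] == report.best_cutoff else ""
        lines.append(
            "| {cut} | {pa} | {kappa} | {se} | {sp} | {ppv} | {npv} | {auc} |".format(
                cut=f"{r['cutoff_deg']:g}°{best}",
                pa=_fmt(r["pa"], ndigits),
                kappa=f"{_fmt(r['kappa'], ndigits)} ({_fmt(r['kappa_ci_low'], ndigits)} to {_fmt(r['kappa_ci_high'], ndigits)})",
                se=f"{_fmt(r['sensitivity'], ndigits)} ({_fmt(r['se_ci_low'], ndigits)} to {_fmt(r['se_ci_high'], ndigits)})",
                sp=f"{_fmt(r['specificity'], ndigits)} ({_fmt(r['sp_ci_low'], ndigits)} to {_fmt(r['sp_ci_high'], ndigits)})",
                ppv=f"{_fmt(r['ppv'], ndigits)} ({_fmt(r['ppv_ci_low'], ndigits)} to {_fmt(r['ppv_ci_high'], ndigits)})",
                npv=f"{_fmt(r['npv'], ndigits)} ({_fmt(r['npv_ci_low'], ndigits)} to {_fmt(r['npv_ci_high'], ndigits)})",
                auc=f"{_fmt(r['auc'], ndigits)} ({_fmt(r['auc_se'], ndigits)}, {_fmt(r['auc_ci_low'], ndigits)} to {_fmt(r['auc_ci_high'], ndigits)})",
            )
        )
    lines.append("")
    lines.append(f"Prevalence of fail rating: {report.prevalence_percent}% "
                 f"(n = {report.n}); best cut-off by AUC: {report.best_cutoff:g}°.")
    return "\n".join(lines) + "\n"


def roc_points(report: DiagnosticReport) -> pd.DataFrame:
    """Per-cut-off ROC coordinates (false positive rate, sensitivity)."""
    return pd.DataFrame({
        "cutoff_deg": report.table["cutoff_deg"],
        "fpr": 1.0 - report.table["specificity"],
        "tpr": report.table["sensitivity"],
    })


def bland_altman_points(rows: Sequence[ReliabilityRow]) -> dict[str, pd.DataFrame]:
    """Bland-Altman point sets per variable, with bias/limits columns."""
    out = {}
    for row in rows:
        ba = row.bland_altman
        out[row.name] = pd.DataFrame({
            "mean": ba.means,
            "difference": ba.differences,
            "bias": ba.bias,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
        })
    return out


def write_reports(
    reliability_rows: Sequence[ReliabilityRow],
    diagnostic_report: DiagnosticReport,
    outdir: str | Path,
    ndigits: int = 2,
) -> dict[str, Path]:
    """Write all report artifacts to ``outdir``; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rel_csv = outdir / "reliability_report.csv"
    reliability_table(reliability_rows).to_csv(rel_csv, index=False)
    paths["reliability_csv"] = rel_csv
    rel_md = outdir / "reliability_report.md"
    rel_md.write_text(reliability_markdown(reliability_rows, ndigits))
    paths["reliability_md"] = rel_md

    val_csv = outdir / "validity_report.csv"
    diagnostic_report.table.to_csv(val_csv, index=False)
    paths["validity_csv"] = val_csv
    val_md = outdir / "validity_report.md"
    val_md.write_text(validity_markdown(diagnostic_report, ndigits))
    paths["validity_md"] = val_md

    roc_csv = outdir / "roc_points.csv"
    roc_points(diagnostic_report).to_csv(roc_csv, index=False)
    paths["roc_csv"] = roc_csv

    for name, points in bland_altman_points(reliability_rows).items():
        slug = name.replace(" ", "_")
        ba_csv = outdir / f"bland_altman_{slug}.csv"
        points.to_csv(ba_csv, index=False)
        paths[f"bland_altman_{slug}"] = ba_csv
    return paths
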