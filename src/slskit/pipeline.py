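"""End-to-end pipeline: simulate → score → filter → analyse → render.

Every run is fully determined by its configuration (including the seed):
identical config gives byte-identical output files.  The run log records
the seed, a hash of the configuration, and the exclusion bookkeeping of
both study arms.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as slsio
from .config import PipelineConfig
from .errors import PipelineError
from .kinematics import Bookkeeping, FilterResult, filter_available, score_cohort
from .reliability import ReliabilityRow, analyze_reliability
from .render import write_reports
from .synthetic import contaminate, generate_cohort, generate_rater_labels
from .validity import DiagnosticReport, consensus_from_ratings, cutoff_sweep

logger = logging.getLogger("slskit")

# fixed offsets deriving stage seeds from the master seed
_CONTAMINATION_SEED_OFFSET = 1_000_003
_RATER_SEED_OFFSET = 2_000_003


@dataclass(frozen=True)
class PipelineResult:
    """Artifacts and bookkeeping of one pipeline run."""

    scores: pd.DataFrame
    reliability_rows: Sequence[ReliabilityRow]
    diagnostic_report: DiagnosticReport
    reliability_bookkeeping: Bookkeeping
    validity_bookkeeping: Bookkeeping
    paths: dict[str, Path]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    return wrap


def simulate(config: PipelineConfig):
    """Generate the contaminated cohort and the rater labels."""
    cohort = generate_cohort(config.cohort)
    trajectories, counts = contaminate(
        cohort.trajectories,
        config.cohort.easy_mode_rate,
        config.cohort.missing_rate,
        seed=config.seed + _CONTAMINATION_SEED_OFFSET,
    )
    ratings = generate_rater_labels(
        cohort.true_angles,
        label_threshold=config.cohort.label_threshold,
        rater_error_prob=config.cohort.rater_error_prob,
        seed=config.seed + _RATER_SEED_OFFSET,
    )
    logger.info("simulated %d recordings (status counts: %s)", len(trajectories), counts)
    return trajectories, cohort.true_angles, ratings


def validity_inputs(scores: pd.DataFrame, ratings: pd.DataFrame) -> tuple[FilterResult, pd.DataFrame]:
    """Filter recordings for the validity arm and align scores with labels.

    Only the down-phase medial displacement enters the comparison.  A
    recording contributes when its score is available *and* it has a
    consensus rating.
    """
    filtered = filter_available(scores, "validity")
    table = filtered.table.copy()
    table["recording_id"] = (
        table["subject"].astype(str) + ":" + table["leg"] + ":" + table["occasion"].astype(str)
    )
    consensus = consensus_from_ratings(ratings)
    merged = table.merge(consensus, on="recording_id", how="inner")
    return filtered, merged


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the full simulation → report pipeline into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    logger.info("run seed=%d config_hash=%s", config.seed, config.config_hash())

    trajectories, true_angles, ratings = _stage("simulate")(simulate, config)

    paths: dict[str, Path] = {}
    if config.write_trajectory_files:
        paths["trajectories"] = _stage("write_trajectories")(
            slsio.write_trajectories, trajectories, outdir / "trajectories"
        )
    paths["true_angles"] = _stage("write_true_angles")(
        slsio.write_true_angles, true_angles, outdir / "true_angles.csv"
    )
    paths["ratings"] = _stage("write_ratings")(
        slsio.write_ratings, ratings, outdir / "ratings.csv"
    )

    scores = _stage("score")(score_cohort, trajectories)
    paths["scores"] = _stage("write_scores")(
        slsio.write_scores, scores, outdir / "scores.csv"
    )

    rel_filtered = _stage("filter_reliability")(filter_available, scores, "reliability")
    rel_book = rel_filtered.bookkeeping
    logger.info(
        "reliability arm: %d of %d planned measures available (%d%%)",
        rel_book.available, rel_book.planned, rel_book.availability_percent,
    )
    reliability_rows = _stage("reliability")(analyze_reliability, rel_filtered.table)

    val_filtered, val_table = _stage("filter_validity")(validity_inputs, scores, ratings)
    val_book = val_filtered.bookkeeping
    logger.info(
        "validity arm: %d of %d planned recordings available (%d%%)",
        val_book.available, val_book.planned, val_book.availability_percent,
    )
    diagnostic_report = _stage("validity")(
        cutoff_sweep,
        val_table["medial_down"].to_numpy(),
        list(val_table["label"]),
        config.cutoffs,
    )
    logger.info(
        "validity arm: prevalence %d%%, best cut-off %g deg",
        diagnostic_report.prevalence_percent, diagnostic_report.best_cutoff,
    )

    paths.update(
        _stage("render")(write_reports, reliability_rows, diagnostic_report, outdir,
                         config.ndigits)
    )

    bookkeeping = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "reliability": _book_dict(rel_book),
        "validity": _book_dict(val_book),
        "prevalence_percent": diagnostic_report.prevalence_percent,
        "best_cutoff_deg": diagnostic_report.best_cutoff,
    }
    book_path = outdir / "bookkeeping.json"
    book_path.write_text(json.dumps(bookkeeping, indent=2, sort_keys=True) + "\n")
    paths["bookkeeping"] = book_path

    return PipelineResult(
        scores=scores,
        reliability_rows=reliability_rows,
        diagnostic_report=diagnostic_report,
        reliability_bookkeeping=rel_book,
        validity_bookkeeping=val_book,
        paths=paths,
    )


def _book_dict(book: Bookkeeping) -> dict:
    return {
        "planned": book.planned,
        "excluded": dict(book.excluded),
        "available": book.available,
        "availability_percent": book.availability_percent,
    }
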