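"""Reading and writing of trajectory, score, rating and report tables.

All tabular I/O is plain CSV.  A cohort of trajectories is stored as a
directory with one CSV per scoreable recording (``time_s, knee_x_cm,
knee_y_cm`` with ``# key: value`` metadata header lines) plus a
``manifest.csv`` listing every planned recording with its status; flagged
recordings (easy-mode / missing / improper) appear in the manifest only.
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .kinematics import SCORE_COLUMNS, STATUSES, SquatTrajectory
from .synthetic import RATER_COLUMNS, TRUE_ANGLE_COLUMNS

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = ["subject", "leg", "occasion", "status", "file"]
TRAJECTORY_COLUMNS = ["time_s", "knee_x_cm", "knee_y_cm"]


def _traj_filename(traj: SquatTrajectory) -> str:
    return f"traj_{traj.subject}_{traj.leg}_{traj.occasion}.csv"


def write_trajectories(trajectories: Iterable[SquatTrajectory], outdir: str | Path) -> Path:
    """Write a cohort to ``outdir`` and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for traj in trajectories:
        fname = ""
        if traj.status == "ok":
            fname = _traj_filename(traj)
            with open(outdir / fname, "w") as fh:
                fh.write(f"# subject: {traj.subject}\n")
                fh.write(f"# leg: {traj.leg}\n")
                fh.write(f"# occasion: {traj.occasion}\n")
                fh.write(f"# status: {traj.status}\n")
                fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
                for t, x, y in zip(traj.time_s, traj.knee_x_cm, traj.knee_y_cm):
                    fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")
        manifest_rows.append((traj.subject, traj.leg, traj.occasion, traj.status, fname))
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest_path = outdir / MANIFEST_NAME
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def _read_trajectory_file(path: Path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    try:
        data = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise ParseError(f"unreadable trajectory file: {exc}", path=str(path)) from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in data.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=str(path))
    return meta, data


def read_trajectories(path: str | Path) -> tuple[SquatTrajectory, ...]:
    """Read a cohort back from a trajectory directory (or its manifest)."""
    path = Path(path)
    manifest_path = path if path.is_file() else path / MANIFEST_NAME
    base = manifest_path.parent
    if not manifest_path.exists():
        raise ParseError("manifest not found", path=str(manifest_path))
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ParseError(f"manifest missing columns {missing}", path=str(manifest_path))

    cohort = []
    for i, row in manifest.iterrows():
        status = row["status"]
        if status not in STATUSES:
            raise ParseError(f"unknown status {status!r}", path=str(manifest_path), line=i + 2)
        if status == "ok":
            fpath = base / row["file"]
            if not fpath.exists():
                raise ParseError("trajectory file not found", path=str(fpath))
            meta, data = _read_trajectory_file(fpath)
            times = data["time_s"].to_numpy(dtype=float)
            if times.size >= 2 and not np.all(np.diff(times) > 0):
                bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
                raise ParseError(
                    "sample times not strictly increasing",
                    path=str(fpath),
                    line=bad + 6,  # 4 metadata lines + header + 1-based
                )
            traj = SquatTrajectory(
                subject=str(row["subject"]),
                leg=row["leg"],
                occasion=int(row["occasion"]),
                time_s=times,
                knee_x_cm=data["knee_x_cm"].to_numpy(dtype=float),
                knee_y_cm=data["knee_y_cm"].to_numpy(dtype=float),
                status="ok",
            )
        else:
            traj = SquatTrajectory(
                subject=str(row["subject"]),
                leg=row["leg"],
                occasion=int(row["occasion"]),
                time_s=np.array([]),
                knee_x_cm=np.array([]),
                knee_y_cm=np.array([]),
                status=status,
            )
        cohort.append(traj)
    return tuple(cohort)


def _read_table(path: str | Path, required: Sequence[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{name} file not found", path=str(path))
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{name} missing columns {missing}", path=str(path))
    return table


def write_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    scores.to_csv(path, index=False)
    return Path(path)


def read_scores(path: str | Path) -> pd.DataFrame:
    scores = _read_table(path, SCORE_COLUMNS, "score table")
    scores["subject"] = scores["subject"].astype(str)
    return scores


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> Path:
    ratings.to_csv(path, index=False)
    return Path(path)


def read_ratings(path: str | Path) -> pd.DataFrame:
    ratings = _read_table(path, RATER_COLUMNS, "ratings table")
    bad = ~ratings["label"].isin(["pass", "fail"])
    if bad.any():
        raise ParseError(
            f"invalid rating labels at rows {list(ratings.index[bad])}", path=str(path)
        )
    ratings["subject"] = ratings["subject"].astype(str)
    return ratings


def write_true_angles(angles: pd.DataFrame, path: str | Path) -> Path:
    angles.to_csv(path, index=False)
    return Path(path)


def read_true_angles(path: str | Path) -> pd.DataFrame:
    angles = _read_table(path, TRUE_ANGLE_COLUMNS, "true-angle table")
    angles["subject"] = angles["subject"].astype(str)
    return angles
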