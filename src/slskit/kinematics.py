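"""Frontal-plane squat kinematics: phase segmentation and net trajectory angles.

A single-leg squat is recorded as a 30 Hz time series of the knee's
frontal-plane position (horizontal ``knee_x`` in cm, positive toward the
subject's right; vertical ``knee_y`` in cm, 0 at standing and negative when
squatting).  The squat is split at its deepest point into a *down* and an
*up* phase, and each phase is summarised by the angle between the
least-squares line through the knee path and the vertical axis — the net
trajectory angle (NTA) — together with the horizontal travel of that fitted
line over the phase ("shift", in cm).

Reported sign convention
------------------------
Negative NTA denotes medial displacement for the *left* knee and lateral
displacement for the right knee; positive denotes medial displacement for
the *right* knee and lateral for the left.  :func:`medial_displacement`
converts to a leg-independent medial-positive value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .errors import (
    NoTurningPointError,
    SegmentationError,
    UndefinedAngleError,
)

Leg = Literal["left", "right"]
Direction = Literal["down", "up"]

LEGS: tuple[str, ...] = ("left", "right")
DIRECTIONS: tuple[str, ...] = ("down", "up")
STATUSES: tuple[str, ...] = ("ok", "easy_mode", "no_go", "missing")

#: minimum number of samples for a scoreable recording
MIN_SAMPLES = 5

SCORE_COLUMNS = [
    "subject",
    "leg",
    "occasion",
    "nta_down",
    "nta_up",
    "medial_down",
    "medial_up",
    "shift_down_cm",
    "shift_up_cm",
    "status",
]


@dataclass(frozen=True)
class SquatTrajectory:
    """One leg's knee coordinate series for one test occasion.

    Parameters
    ----------
    subject : str
        Subject identifier.
    leg : {'left', 'right'}
    occasion : int
        Test occasion index (1-based).
    time_s, knee_x_cm, knee_y_cm : ndarray
        Equal-length sample arrays; times strictly increasing.
    status : {'ok', 'easy_mode', 'no_go', 'missing'}
        Recording validity flag; only ``ok`` recordings are scoreable.
    """

    subject: str
    leg: str
    occasion: int
    time_s: np.ndarray
    knee_x_cm: np.ndarray
    knee_y_cm: np.ndarray
    status: str = "ok"

    def __post_init__(self):
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.knee_x_cm, dtype=float)
        y = np.asarray(self.knee_y_cm, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("time/x/y must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "knee_x_cm", x)
        object.__setattr__(self, "knee_y_cm", y)

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def recording_id(self) -> str:
        return f"{self.subject}:{self.leg}:{self.occasion}"

    def with_status(self, status: str) -> "SquatTrajectory":
        return replace(self, status=status)


@dataclass(frozen=True)
class Segment:
    """A contiguous slice of a trajectory covering one squat phase."""

    time_s: np.ndarray
    knee_x_cm: np.ndarray
    knee_y_cm: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def vertical_excursion(self) -> float:
        return float(self.knee_y_cm.max() - self.knee_y_cm.min())


@dataclass(frozen=True)
class PhaseAngle:
    """Net trajectory angle for one phase, in the reported sign convention."""

    nta_deg: float
    shift_cm: float
    leg: str
    direction: str


@dataclass(frozen=True)
class NTAResult:
    """Down- and up-phase net trajectory angles for one recording."""

    subject: str
    leg: str
    occasion: int
    nta_down: float
    nta_up: float
    shift_down_cm: float
    shift_up_cm: float
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class MedialDisplacement:
    """Leg-independent medial-positive displacement angle in degrees."""

    degrees: float
    direction: str
    leg: str


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x; exactly 0 for constant y."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise UndefinedAngleError("regressor has zero variance")
    return float(np.dot(xc, yc) / denom)


def turning_index(knee_y: np.ndarray) -> int:
    """Index of the squat's deepest point (first sample on ties).

    Raises
    ------
    NoTurningPointError
        If the minimum lies at the first or last sample, i.e. the vertical
        series has no interior bottom.
    """
    y = np.asarray(knee_y, dtype=float)
    idx = int(np.argmin(y))  # argmin takes the first of tied minima
    if idx == 0 or idx == y.size - 1:
        raise NoTurningPointError(
            "vertical series has no interior minimum; not a squat"
        )
    return idx


def segment_phases(traj: SquatTrajectory) -> tuple[Segment, Segment]:
    """Split a recording at the turning point into (down, up) segments.

    The turning-point sample belongs to both segments, so each phase has at
    least two samples.
    """
    if traj.status != "ok":
        raise SegmentationError(
            f"cannot segment recording {traj.recording_id} with status {traj.status!r}"
        )
    if traj.n_samples < MIN_SAMPLES:
        raise SegmentationError(
            f"recording {traj.recording_id} has {traj.n_samples} samples; "
            f"need >= {MIN_SAMPLES}"
        )
    turn = turning_index(traj.knee_y_cm)
    down = Segment(
        traj.time_s[: turn + 1],
        traj.knee_x_cm[: turn + 1],
        traj.knee_y_cm[: turn + 1],
    )
    up = Segment(
        traj.time_s[turn:],
        traj.knee_x_cm[turn:],
        traj.knee_y_cm[turn:],
    )
    return down, up


def compute_nta(segment: Segment, leg: str, direction: str) -> PhaseAngle:
    """Net trajectory angle of one phase.

    Fits an ordinary-least-squares line of horizontal on vertical position
    and takes the arctangent of its slope, so the angle is measured against
    the vertical axis.  The raw angle is re-signed for the up phase (travel
    direction reversed) so that the reported convention holds for both
    phases: negative = medial left knee / lateral right knee, positive =
    medial right knee / lateral left knee.

    ``shift`` is the horizontal travel of the fitted line over the phase's
    vertical excursion, carrying the same sign as the angle.
    """
    if leg not in LEGS:
        raise ValueError(f"leg must be one of {LEGS}, got {leg!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if segment.n_samples < 2:
        raise UndefinedAngleError("need at least 2 samples to fit a line")
    excursion = segment.vertical_excursion
    if excursion <= 0:
        raise UndefinedAngleError("zero vertical excursion; angle undefined")
    slope = _ols_slope(segment.knee_y_cm, segment.knee_x_cm)
    sign = 1.0 if direction == "down" else -1.0
    nta = sign * math.degrees(math.atan(slope))
    shift = sign * slope * excursion
    return PhaseAngle(nta_deg=nta, shift_cm=shift, leg=leg, direction=direction)


def medial_displacement(nta: float | PhaseAngle, leg: str | None = None,
                        direction: str | None = None) -> MedialDisplacement:
    """Convert a signed NTA to a medial-positive displacement.

    Left leg: medial = -nta.  Right leg: medial = +nta.
    """
    if isinstance(nta, PhaseAngle):
        leg = nta.leg
        direction = nta.direction
        value = nta.nta_deg
    else:
        value = float(nta)
    if leg not in LEGS:
        raise ValueError(f"leg must be one of {LEGS}, got {leg!r}")
    medial = -value if leg == "left" else value
    return MedialDisplacement(degrees=medial, direction=direction or "down", leg=leg)


def score_trajectory(traj: SquatTrajectory) -> NTAResult:
    """Segment a recording and compute both phase angles."""
    down_seg, up_seg = segment_phases(traj)
    down = compute_nta(down_seg, traj.leg, "down")
    up = compute_nta(up_seg, traj.leg, "up")
    return NTAResult(
        subject=traj.subject,
        leg=traj.leg,
        occasion=traj.occasion,
        nta_down=down.nta_deg,
        nta_up=up.nta_deg,
        shift_down_cm=down.shift_cm,
        shift_up_cm=up.shift_cm,
    )


def score_cohort(trajectories: Iterable[SquatTrajectory]) -> pd.DataFrame:
    """Score every recording in a cohort into a tidy table.

    Recordings whose status is not ``ok`` appear as rows with NaN scores so
    that downstream exclusion bookkeeping can see them.
    """
    rows = []
    for traj in trajectories:
        if traj.status == "ok":
            res = score_trajectory(traj)
            med_down = medial_displacement(res.nta_down, traj.leg, "down").degrees
            med_up = medial_displacement(res.nta_up, traj.leg, "up").degrees
            rows.append(
                dict(
                    subject=traj.subject,
                    leg=traj.leg,
                    occasion=traj.occasion,
                    nta_down=res.nta_down,
                    nta_up=res.nta_up,
                    medial_down=med_down,
                    medial_up=med_up,
                    shift_down_cm=res.shift_down_cm,
                    shift_up_cm=res.shift_up_cm,
                    status=traj.status,
                )
            )
        else:
            rows.append(
                dict(
                    subject=traj.subject,
                    leg=traj.leg,
                    occasion=traj.occasion,
                    nta_down=np.nan,
                    nta_up=np.nan,
                    medial_down=np.nan,
                    medial_up=np.nan,
                    shift_down_cm=np.nan,
                    shift_up_cm=np.nan,
                    status=traj.status,
                )
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# availability bookkeeping
# ---------------------------------------------------------------------------

#: map from recording status to the exclusion reason used in reports
_EXCLUSION_REASON = {"easy_mode": "easy_mode", "missing": "missing", "no_go": "improper"}

#: precedence when a reliability pair is excluded for several reasons at once
_REASON_PRECEDENCE = ("easy_mode", "missing", "improper")


@dataclass(frozen=True)
class Bookkeeping:
    """Planned / excluded / available counts with the availability percentage."""

    planned: int
    excluded: Mapping[str, int]
    available: int
    availability_percent: int

    def __post_init__(self):
        total_excluded = sum(self.excluded.values())
        if self.planned != self.available + total_excluded:
            raise ValueError(
                "bookkeeping does not balance: "
                f"{self.planned} planned != {self.available} available "
                f"+ {total_excluded} excluded"
            )


@dataclass(frozen=True)
class FilterResult:
    """Available score rows plus exclusion bookkeeping."""

    table: pd.DataFrame
    bookkeeping: Bookkeeping


def availability(planned: int, excluded: Mapping[str, int]) -> Bookkeeping:
    """Availability bookkeeping from a planned count and exclusion counts.

    The availability percentage is rounded to the nearest integer.
    """
    if planned <= 0:
        raise ValueError("planned count must be positive")
    total_excluded = sum(excluded.values())
    if total_excluded > planned:
        raise ValueError("excluded count exceeds planned count")
    available = planned - total_excluded
    percent = int(round_half_up(100.0 * available / planned, 0))
    return Bookkeeping(
        planned=planned,
        excluded=dict(excluded),
        available=available,
        availability_percent=percent,
    )


def filter_available(score_table: pd.DataFrame,
                     purpose: Literal["reliability", "validity"]) -> FilterResult:
    """Apply the exclusion rules and account for every planned measure.

    ``reliability``: the unit is a single *measure* (one variable at one
    occasion, i.e. two per recording: down and up).  A subject's pair for a
    variable is deleted pairwise — if either occasion's recording is
    easy-mode, missing, or improper, both occasions' measures for that leg
    are excluded (attributed to the worst-status reason, in the order
    easy_mode > missing > improper).

    ``validity``: the unit is one recording; recordings are deleted
    individually.
    """
    if purpose == "validity":
        planned = len(score_table)
        excluded: dict[str, int] = {}
        for status, reason in _EXCLUSION_REASON.items():
            count = int((score_table["status"] == status).sum())
            if count:
                excluded[reason] = excluded.get(reason, 0) + count
        kept = score_table[score_table["status"] == "ok"].reset_index(drop=True)
        return FilterResult(kept, availability(planned, excluded))

    if purpose != "reliability":
        raise ValueError(f"unknown purpose {purpose!r}")

    planned = 2 * len(score_table)  # down + up measures per recording
    excluded = {}
    keep_mask = pd.Series(True, index=score_table.index)
    for (_, _), group in score_table.groupby(["subject", "leg"], sort=False):
        statuses = set(group["status"])
        if statuses == {"ok"}:
            continue
        keep_mask[group.index] = False
        reasons = {_EXCLUSION_REASON[s] for s in statuses if s != "ok"}
        reason = next(r for r in _REASON_PRECEDENCE if r in reasons)
        excluded[reason] = excluded.get(reason, 0) + 2 * len(group)
    kept = score_table[keep_mask].reset_index(drop=True)
    return FilterResult(kept, availability(planned, excluded))
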