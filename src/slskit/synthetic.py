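"""Synthetic single-leg-squat cohorts with a known variance structure.

The generator produces everything the downstream stages consume — 30 Hz
knee trajectories, a two-occasion cohort whose true displacement angles
follow a between-subject / between-occasion / residual variance-component
model, recording contamination (easy-mode and missing recordings), and two
error-prone visual raters with a consensus label — so the full pipeline can
be exercised and parameter recovery can be tested without any external
data.

True angles are kept in a leg-independent *medial-positive* convention
internally; the conversion to the signed reporting convention happens at
scoring time in :mod:`slskit.kinematics`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import check_non_negative, check_probability
from .kinematics import LEGS, SquatTrajectory

SAMPLE_RATE_HZ = 30.0

TRUE_ANGLE_COLUMNS = ["subject", "leg", "occasion", "direction", "true_angle_medial"]
RATER_COLUMNS = ["recording_id", "subject", "leg", "occasion", "rater", "label"]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-occasion squat cohort.

    Variances are in deg² on the true medial-displacement angle; the
    sensor noise is additive Gaussian noise on the horizontal knee
    coordinate in cm.  ``occasion_shift`` adds a systematic change (deg,
    medial-positive) to every angle on the second and later occasions, for
    scenarios with a genuine between-occasion difference.
    """

    n_subjects: int = 37
    legs: Sequence[str] = ("left", "right")
    occasions: int = 2
    sigma2_p: float = 75.0
    sigma2_o: float = 5.0
    sigma2_res: float = 20.0
    mean_angle_down: float = 2.0
    mean_angle_up: float = 0.0
    occasion_shift: float = 0.0
    sensor_noise_sd: float = 0.15
    squat_depth: float = 15.0
    samples_per_phase: int = 30
    rater_error_prob: float = 0.1
    label_threshold: float = 6.0
    easy_mode_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        legs = tuple(self.legs)
        if not legs or any(leg not in LEGS for leg in legs):
            raise ValueError(f"legs must be a non-empty subset of {LEGS}")
        object.__setattr__(self, "legs", legs)
        if self.occasions < 2:
            raise ValueError("occasions must be >= 2 for test-retest use")
        if self.samples_per_phase < 2:
            raise ValueError("samples_per_phase must be >= 2")
        if self.squat_depth <= 0:
            raise ValueError("squat_depth must be > 0")
        for name in ("sigma2_p", "sigma2_o", "sigma2_res", "sensor_noise_sd"):
            check_non_negative(getattr(self, name), name)
        for name in ("rater_error_prob", "easy_mode_rate", "missing_rate"):
            check_probability(getattr(self, name), name)
        if self.easy_mode_rate + self.missing_rate > 1:
            raise ValueError("easy_mode_rate + missing_rate must be <= 1")

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * len(self.legs) * self.occasions

    @property
    def n_planned_measures(self) -> int:
        """Recordings × 2 movement directions (down, up)."""
        return 2 * self.n_recordings


@dataclass(frozen=True)
class RaterLabel:
    """One rater's dichotomous visual rating of one recording."""

    recording_id: str
    rater: str
    label: str

    def __post_init__(self):
        if self.label not in ("pass", "fail"):
            raise ValueError(f"label must be 'pass' or 'fail', got {self.label!r}")


@dataclass(frozen=True)
class Cohort:
    """Simulated trajectories plus the generating true-angle table."""

    trajectories: tuple[SquatTrajectory, ...]
    true_angles: pd.DataFrame
    config: CohortConfig
    status_counts: dict = field(default_factory=dict)


def _half_cosine_descent(depth: float, n: int) -> np.ndarray:
    """Smooth 0 → depth descent profile over n samples (inclusive ends)."""
    phase = np.linspace(0.0, np.pi, n)
    return depth * (1.0 - np.cos(phase)) / 2.0


def generate_trajectory(
    true_angle_down: float,
    true_angle_up: float,
    depth: float,
    samples_per_phase: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    *,
    leg: str = "left",
    subject: str = "S1",
    occasion: int = 1,
) -> SquatTrajectory:
    """Simulate one squat recording at 30 Hz.

    The vertical coordinate descends from 0 to ``-depth`` along a
    half-cosine over ``samples_per_phase`` samples, then returns the same
    way (the bottom sample is shared, so the series has
    ``2 * samples_per_phase - 1`` samples).  The horizontal coordinate
    moves medially by ``tan(angle) *`` (vertical distance covered) within
    each phase, with angles given medial-positive, plus i.i.d. Gaussian
    sensor noise of standard deviation ``noise_sd`` (cm).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if samples_per_phase < 2:
        raise ValueError("samples_per_phase must be >= 2")
    check_non_negative(noise_sd, "noise_sd")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    descent = _half_cosine_descent(depth, samples_per_phase)
    ascent = descent[-2::-1]  # bottom sample shared with the down phase
    knee_y = np.concatenate([-descent, -ascent])

    # medial direction in the subject frame: +x for the left knee, -x for right
    medial_sign = 1.0 if leg == "left" else -1.0
    tan_down = np.tan(np.deg2rad(true_angle_down))
    tan_up = np.tan(np.deg2rad(true_angle_up))
    x_down = medial_sign * tan_down * descent
    x_bottom = x_down[-1]
    ascended = depth - ascent  # vertical distance covered since the bottom
    x_up = x_bottom + medial_sign * tan_up * ascended
    knee_x = np.concatenate([x_down, x_up])
    if noise_sd > 0:
        knee_x = knee_x + rng.normal(0.0, noise_sd, size=knee_x.size)

    time_s = np.arange(knee_y.size) / SAMPLE_RATE_HZ
    return SquatTrajectory(
        subject=subject,
        leg=leg,
        occasion=occasion,
        time_s=time_s,
        knee_x_cm=knee_x,
        knee_y_cm=knee_y,
        status="ok",
    )


def generate_true_angles(config: CohortConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the true medial-displacement angle for every planned measure.

    Model per subject s, leg l, occasion o, direction d::

        angle = mean(d) + a[s,l] + b[s,l,o] + e[s,l,o,d] + shift(o)

    with ``a ~ N(0, sigma2_p)``, ``b ~ N(0, sigma2_o)``,
    ``e ~ N(0, sigma2_res)``.  Legs are simulated independently (separate
    subject effects per leg); the occasion effect is drawn per
    subject-occasion, not as a global shift — a systematic shift is the
    separate ``occasion_shift`` parameter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    means = {"down": config.mean_angle_down, "up": config.mean_angle_up}
    sd_p = np.sqrt(config.sigma2_p)
    sd_o = np.sqrt(config.sigma2_o)
    sd_res = np.sqrt(config.sigma2_res)

    rows = []
    for s in range(1, config.n_subjects + 1):
        subject = f"S{s:03d}"
        for leg in config.legs:
            a = rng.normal(0.0, sd_p)
            for occ in range(1, config.occasions + 1):
                b = rng.normal(0.0, sd_o)
                shift = config.occasion_shift if occ > 1 else 0.0
                for direction in ("down", "up"):
                    e = rng.normal(0.0, sd_res)
                    rows.append(
                        (subject, leg, occ, direction, means[direction] + a + b + e + shift)
                    )
    return pd.DataFrame(rows, columns=TRUE_ANGLE_COLUMNS)


def generate_cohort(config: CohortConfig, *, with_trajectories: bool = True) -> Cohort:
    """Simulate a full cohort: true angles and (optionally) trajectories.

    The true-angle table is always returned so parameter-recovery tests can
    compare estimates against the generating values.  With
    ``with_trajectories=False`` only the table is produced (fast path for
    Monte-Carlo studies).
    """
    rng = np.random.default_rng(config.seed)
    angles = generate_true_angles(config, rng)

    trajectories: list[SquatTrajectory] = []
    if with_trajectories:
        wide = angles.pivot_table(
            index=["subject", "leg", "occasion"],
            columns="direction",
            values="true_angle_medial",
            sort=False,
        )
        for (subject, leg, occasion), row in wide.iterrows():
            trajectories.append(
                generate_trajectory(
                    true_angle_down=float(row["down"]),
                    true_angle_up=float(row["up"]),
                    depth=config.squat_depth,
                    samples_per_phase=config.samples_per_phase,
                    noise_sd=config.sensor_noise_sd,
                    seed=rng,
                    leg=leg,
                    subject=subject,
                    occasion=int(occasion),
                )
            )
    return Cohort(
        trajectories=tuple(trajectories),
        true_angles=angles,
        config=config,
        status_counts={"ok": len(trajectories)},
    )


def contaminate(
    trajectories: Iterable[SquatTrajectory],
    easy_mode_rate: float,
    missing_rate: float,
    seed: int | np.random.Generator,
) -> tuple[tuple[SquatTrajectory, ...], dict[str, int]]:
    """Independently flag recordings easy-mode or missing at the given rates.

    Returns the re-flagged recordings and the per-status counts, which by
    construction sum to the number of recordings.
    """
    check_probability(easy_mode_rate, "easy_mode_rate")
    check_probability(missing_rate, "missing_rate")
    if easy_mode_rate + missing_rate > 1:
        raise ValueError("easy_mode_rate + missing_rate must be <= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    out: list[SquatTrajectory] = []
    counts = {"ok": 0, "easy_mode": 0, "missing": 0}
    for traj in trajectories:
        u = rng.uniform()
        if u < easy_mode_rate:
            out.append(traj.with_status("easy_mode"))
            counts["easy_mode"] += 1
        elif u < easy_mode_rate + missing_rate:
            out.append(traj.with_status("missing"))
            counts["missing"] += 1
        else:
            out.append(traj)
            counts["ok"] += 1
    return tuple(out), counts


def generate_rater_labels(
    true_angles: pd.DataFrame,
    label_threshold: float,
    rater_error_prob: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate two error-prone visual raters plus a consensus label.

    The true state of a recording is *fail* (knee medial to foot) iff the
    down-phase true medial displacement is >= ``label_threshold`` degrees.
    Each rater independently flips the true label with probability
    ``rater_error_prob``.  When the raters disagree, the consensus falls
    back to an adjudicating third rating drawn from the same error model
    (truth flipped with ``rater_error_prob``), so error-free raters always
    reproduce the truth while fully random raters yield chance-level
    consensus labels.
    """
    if not np.isfinite(label_threshold):
        raise ValueError("label_threshold must be finite")
    check_probability(rater_error_prob, "rater_error_prob")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    down = true_angles[true_angles["direction"] == "down"]
    rows = []
    for _, rec in down.iterrows():
        truth = "fail" if rec["true_angle_medial"] >= label_threshold else "pass"
        rec_id = f"{rec['subject']}:{rec['leg']}:{rec['occasion']}"
        ratings = {}
        for rater in ("R1", "R2"):
            flip = rng.uniform() < rater_error_prob
            ratings[rater] = _flip(truth) if flip else truth
        if ratings["R1"] == ratings["R2"]:
            consensus = ratings["R1"]
        else:
            adjudicated = rng.uniform() < rater_error_prob
            consensus = _flip(truth) if adjudicated else truth
        for rater in ("R1", "R2"):
            rows.append((rec_id, rec["subject"], rec["leg"], rec["occasion"],
                         rater, ratings[rater]))
        rows.append((rec_id, rec["subject"], rec["leg"], rec["occasion"],
                     "consensus", consensus))
    return pd.DataFrame(rows, columns=RATER_COLUMNS)


def _flip(label: str) -> str:
    return "fail" if label == "pass" else "pass"
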