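"""Domain types, task geometry, and session CSV readers/writers.

The screening task asks a participant to slide their thumb from the center of
a circle (radius 2 cm by default) outward to targets appearing in 12 numbered
directions, twice around the clock.  Everything downstream (kinematics,
feature images, anomaly scores) is built from the trajectory records defined
here.

Coordinate convention: origin at the circle center, x rightward, y upward,
units centimeters.  Only the distance to the center enters the analysis, so
no screen/pixel conversion is needed or provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "TaskGeometry",
    "TrialTrajectory",
    "SessionRecord",
    "SessionFormatError",
    "SessionValidationError",
    "direction_angle",
    "read_sessions",
    "write_sessions",
    "GROUPS",
    "SIDES",
]

GROUPS = ("healthy", "cts", "unknown")
SIDES = ("left", "right")

#: tolerance (fraction of the radius) within which a collected trial's final
#: sample must sit relative to the target circle
REACH_TOL = 0.05


class SessionFormatError(ValueError):
    """Raised when a session file does not match the documented format."""


class SessionValidationError(ValueError):
    """Raised when session contents violate a domain invariant.

    The message always names the offending hand_id and, where applicable,
    the direction, so malformed inputs can be traced back to their rows.
    """


@dataclass(frozen=True)
class Sample:
    """One timestamped thumb position.

    t is seconds since trial start; x, y are centimeters from the circle
    center.
    """

    t: float
    x: float
    y: float

    def distance(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry and timing of the reaching task."""

    radius: float = 2.0  # cm
    n_directions: int = 12
    timeout: float = 5.0  # s
    sample_rate: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.timeout <= 0 or self.sample_rate <= 0:
            raise ValueError("timeout and sample_rate must be positive")

    @property
    def frames_per_trial(self) -> int:
        """Number of fixed-rate frames spanning one trial (50 by default)."""
        return round(self.timeout * self.sample_rate)

    @property
    def frame_times(self) -> np.ndarray:
        """Times of the fixed frame grid: 0, 1/rate, ..., (frames-1)/rate."""
        return np.arange(self.frames_per_trial) / self.sample_rate


@dataclass
class TrialTrajectory:
    """One outward reach: center toward the target in a numbered direction.

    Return-to-center legs are not recorded; every trial starts near the
    origin.  ``collect_time`` is the moment the thumb reached the target
    circle (absent for timed-out trials).
    """

    direction: int
    lap: int
    samples: list[Sample]
    collected: bool
    collect_time: Optional[float] = None

    def validate(self, geometry: TaskGeometry, hand_id: str = "?") -> None:
        where = f"hand {hand_id!r} lap {self.lap} direction {self.direction}"
        if not 1 <= self.direction <= geometry.n_directions:
            raise SessionValidationError(f"{where}: direction out of range")
        times = [s.t for s in self.samples]
        if any(t < 0 for t in times):
            raise SessionValidationError(f"{where}: negative timestamp")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SessionValidationError(
                f"{where}: timestamps not strictly increasing"
            )
        if self.collected:
            if self.collect_time is None:
                raise SessionValidationError(f"{where}: collected without collect_time")
            if self.collect_time > geometry.timeout + 1e-9:
                raise SessionValidationError(
                    f"{where}: collect_time {self.collect_time} exceeds timeout"
                )
            if self.samples:
                final = self.samples[-1]
                if abs(final.distance() - geometry.radius) > REACH_TOL * geometry.radius:
                    raise SessionValidationError(
                        f"{where}: final sample not on the target circle"
                    )


@dataclass
class SessionRecord:
    """One hand's full measurement game: metadata plus ordered trials.

    Sessions hold only the two measurement laps (the practice phase is not
    analyzed and not represented).
    """

    hand_id: str
    group: str
    side: str
    trials: list[TrialTrajectory]
    severity: Optional[int] = None  # Bland grade 1-6, CTS hands only

    def validate(self, geometry: TaskGeometry) -> None:
        if self.group not in GROUPS:
            raise SessionValidationError(
                f"hand {self.hand_id!r}: unknown group {self.group!r}"
            )
        if self.side not in SIDES:
            raise SessionValidationError(
                f"hand {self.hand_id!r}: unknown side {self.side!r}"
            )
        if self.severity is not None and not 1 <= self.severity <= 6:
            raise SessionValidationError(
                f"hand {self.hand_id!r}: severity {self.severity} outside Bland 1-6"
            )
        seen: set[tuple[int, int]] = set()
        for trial in self.trials:
            key = (trial.lap, trial.direction)
            if key in seen:
                raise SessionValidationError(
                    f"hand {self.hand_id!r}: duplicate trial for lap {trial.lap}"
                    f" direction {trial.direction}"
                )
            seen.add(key)
            trial.validate(geometry, self.hand_id)

    def trials_for_lap(self, lap: int) -> dict[int, TrialTrajectory]:
        return {t.direction: t for t in self.trials if t.lap == lap}


def direction_angle(direction: int, side: str = "right", n_directions: int = 12) -> float:
    """Angle (radians, x-axis convention) of a numbered target direction.

    The default layout is a clock face for the right hand: direction
    ``n_directions`` (12) at the top, numbers increasing clockwise, so
    direction 3 points along +x.  The left-hand layout mirrors the right
    about the vertical axis, matching how the app reverses the numbers
    between hands.
    """
    if not 1 <= direction <= n_directions:
        raise ValueError(f"direction {direction} outside 1..{n_directions}")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    step = 2.0 * math.pi / n_directions
    angle = math.pi / 2.0 - (direction % n_directions) * step
    if side == "left":
        angle = math.pi - angle
    # normalize to (-pi, pi]
    return math.atan2(math.sin(angle), math.cos(angle))


# ---------------------------------------------------------------------------
# Session CSV format
#
# Flat UTF-8 CSV, one row per sample, columns:
#   hand_id, group, side, severity, lap, direction, collected, t, x, y
# severity empty for hands without a Bland grade.  collected is 0/1 and
# constant within a trial.  For collected trials the final sample lies on
# the target circle at the collect time, so collect_time round-trips as the
# last timestamp.
# ---------------------------------------------------------------------------

_COLUMNS = ["hand_id", "group", "side", "severity", "lap", "direction",
            "collected", "t", "x", "y"]


def write_sessions(sessions: Sequence[SessionRecord], path: str | Path) -> Path:
    """Write sessions to the flat CSV format; full float precision."""
    path = Path(path)
    rows: list[tuple] = []
    for s in sessions:
        for trial in s.trials:
            for smp in trial.samples:
                rows.append((s.hand_id, s.group, s.side,
                             "" if s.severity is None else s.severity,
                             trial.lap, trial.direction, int(trial.collected),
                             repr(smp.t), repr(smp.x), repr(smp.y)))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_sessions(path: str | Path, geometry: TaskGeometry | None = None
                  ) -> list[SessionRecord]:
    """Read and validate sessions from the flat CSV format.

    Trials are ordered by lap then direction within each session.  Raises
    :class:`SessionFormatError` for structural problems and
    :class:`SessionValidationError` (naming the hand and direction) for
    invariant violations.
    """
    geometry = geometry or TaskGeometry()
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such session file: {path}")
    try:
        df = pd.read_csv(path, dtype={"hand_id": str, "group": str, "side": str},
                         float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise SessionFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        return []

    sessions: list[SessionRecord] = []
    for hand_id, hand_df in df.groupby("hand_id", sort=False):
        meta = hand_df.iloc[0]
        severity = meta["severity"]
        severity = None if pd.isna(severity) or severity == "" else int(severity)
        trials: list[TrialTrajectory] = []
        # sort=False keeps file row order, i.e. the presentation order the
        # writer emitted; the stable sort below then orders by lap only.
        for (lap, direction), trial_df in hand_df.groupby(["lap", "direction"],
                                                          sort=False):
            samples = [Sample(float(r.t), float(r.x), float(r.y))
                       for r in trial_df.itertuples()]
            collected = bool(int(trial_df["collected"].iloc[0]))
            collect_time = samples[-1].t if (collected and samples) else None
            trials.append(TrialTrajectory(int(direction), int(lap), samples,
                                          collected, collect_time))
        trials.sort(key=lambda tr: tr.lap)
        record = SessionRecord(str(hand_id), str(meta["group"]),
                               str(meta["side"]), trials, severity)
        record.validate(geometry)
        sessions.append(record)
    return sessions
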