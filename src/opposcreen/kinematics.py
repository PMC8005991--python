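"""Per-direction movement summaries and group-comparison statistics.

For each trial we report the time to collect the target (the timeout for
failed reaches), and the mean and maximum thumb speed over consecutive-sample
finite differences.  Group contrasts use two-tailed two-sample t tests per
direction and metric; categorical metadata (sex, playing side) can be
compared with a chi-square test on 2x2 counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SessionRecord, TaskGeometry, TrialTrajectory

__all__ = [
    "DirectionKinematics",
    "GroupComparison",
    "trial_kinematics",
    "cohort_kinematics",
    "compare_groups",
    "chi_square_2x2",
    "METRICS",
]

log = logging.getLogger(__name__)

METRICS = ("time_to_collect", "mean_velocity", "max_velocity")


class InsufficientDataError(ValueError):
    """A trial has too few samples to compute velocities."""


@dataclass(frozen=True)
class DirectionKinematics:
    direction: int
    time_to_collect: float  # s
    mean_velocity: float  # cm/s
    max_velocity: float  # cm/s
    collected: bool


@dataclass(frozen=True)
class GroupComparison:
    direction: Optional[int]
    metric: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float


def _segment_speeds(trial: TrialTrajectory,
                    smooth_window: int | None = None) -> np.ndarray:
    t = np.array([s.t for s in trial.samples])
    xy = np.array([[s.x, s.y] for s in trial.samples])
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(xy, ((pad, smooth_window - 1 - pad), (0, 0)), mode="edge")
        xy = np.column_stack([np.convolve(padded[:, i], kernel, mode="valid")
                              for i in range(2)])
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return disp / np.diff(t)


def trial_kinematics(trial: TrialTrajectory, geometry: TaskGeometry | None = None,
                     smooth_window: int | None = None) -> DirectionKinematics:
    """Summarize one trial.

    Velocities come from raw consecutive-sample differences (Euclidean
    displacement over the time step); ``smooth_window`` optionally applies a
    moving-average position pre-filter (off by default).  Timed-out trials
    contribute the timeout as their time and their observed samples to the
    velocity metrics.
    """
    geometry = geometry or TaskGeometry()
    if len(trial.samples) < 2:
        raise InsufficientDataError(
            f"trial direction {trial.direction}: need >= 2 samples, "
            f"got {len(trial.samples)}"
        )
    speeds = _segment_speeds(trial, smooth_window)
    time = trial.collect_time if trial.collected else geometry.timeout
    return DirectionKinematics(trial.direction, float(time),
                               float(speeds.mean()), float(speeds.max()),
                               trial.collected)


def cohort_kinematics(sessions: Sequence[SessionRecord], lap: int = 2,
                      geometry: TaskGeometry | None = None,
                      smooth_window: int | None = None) -> pd.DataFrame:
    """One row per (hand, direction) for the requested lap.

    Missing trials are emitted as rows with NaN metrics and ``missing=True``
    rather than silently dropped; hands lacking the lap entirely are logged.
    """
    geometry = geometry or TaskGeometry()
    rows = []
    for s in sessions:
        by_dir = s.trials_for_lap(lap)
        if not by_dir:
            log.warning("hand %r has no trials for lap %d", s.hand_id, lap)
        for direction in range(1, geometry.n_directions + 1):
            trial = by_dir.get(direction)
            if trial is None:
                rows.append((s.hand_id, s.group, s.side, direction,
                             np.nan, np.nan, np.nan, False, True))
                continue
            k = trial_kinematics(trial, geometry, smooth_window)
            rows.append((s.hand_id, s.group, s.side, direction,
                         k.time_to_collect, k.mean_velocity, k.max_velocity,
                         k.collected, False))
    return pd.DataFrame(rows, columns=["hand_id", "group", "side", "direction",
                                       "time_to_collect", "mean_velocity",
                                       "max_velocity", "collected", "missing"])


def compare_groups(table: pd.DataFrame, group_a: str = "healthy",
                   group_b: str = "cts", metrics: Sequence[str] = METRICS,
                   equal_var: bool = True) -> pd.DataFrame:
    """Two-sample two-tailed t test per (direction, metric).

    ``equal_var=True`` gives Student's pooled-variance t (the default);
    False selects Welch's variant.  Returns one row per direction and
    metric with group means, t and p.
    """
    for g in (group_a, group_b):
        if not (table["group"] == g).any():
            raise ValueError(f"group {g!r} is empty")
    out = []
    for direction, ddf in table.groupby("direction", sort=True):
        a = ddf[ddf["group"] == group_a]
        b = ddf[ddf["group"] == group_b]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"direction {direction}: need >= 2 hands per group for a t test"
            )
        for metric in metrics:
            xa = a[metric].dropna().to_numpy()
            xb = b[metric].dropna().to_numpy()
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            out.append(GroupComparison(int(direction), metric,
                                       float(xa.mean()), float(xb.mean()),
                                       float(t), float(p)))
    return pd.DataFrame([c.__dict__ for c in out])


def chi_square_2x2(counts) -> tuple[float, float]:
    """Chi-square test on a 2x2 contingency table of categorical metadata
    (e.g. sex by group, playing side by group).  Returns (chi2, p)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)
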