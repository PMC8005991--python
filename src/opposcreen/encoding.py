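"""Trajectory-to-image feature encoding.

Each hand's second-lap trajectories become a 12-row x 50-column grayscale
grid: one row per direction, one column per 0.1-s frame over the 5-s trial
window.  Pixel intensity is the thumb's distance from the circle center
normalized by the circle radius (0 at the center, 1 on the circle, clipped
above).  The frame at which the thumb reaches the circumference is set to
white (1.0) and every later frame to black (0.0); timed-out trials fill all
50 frames with their observed normalized distances and contain no forced
white frame.  Row-major flattening yields the 600-dimensional model input;
4-direction windows (with wraparound, e.g. "12-3") yield 200 dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import Sample, SessionRecord, TaskGeometry

__all__ = [
    "FeatureImage",
    "normalize_distance",
    "encode_image",
    "flatten",
    "slice_window",
    "window_label",
    "encode_cohort",
    "MissingLapError",
]

log = logging.getLogger(__name__)

#: default tolerance for reach detection from distances alone (fraction of
#: the radius); the recorded collect_time, when present, takes precedence
REACH_EPS = 0.02


class MissingLapError(ValueError):
    """The requested lap is absent from a session."""


@dataclass
class FeatureImage:
    """n_directions x frames_per_trial intensity grid in [0, 1]."""

    intensities: np.ndarray
    geometry: TaskGeometry
    hand_id: Optional[str] = None
    #: directions whose trial was missing and whose row was zero-filled
    flagged_directions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (self.geometry.n_directions, self.geometry.frames_per_trial)
        if self.intensities.shape != expected:
            raise ValueError(
                f"image shape {self.intensities.shape} != geometry {expected}"
            )
        if ((self.intensities < 0) | (self.intensities > 1)).any():
            raise ValueError("intensities must lie in [0, 1]")


def normalize_distance(sample: Sample, geometry: TaskGeometry) -> float:
    """Distance-to-center mapped to [0, 1]: d / radius, clipped at 1."""
    return min(sample.distance() / geometry.radius, 1.0)


def _encode_row(trial, geometry: TaskGeometry, reach_eps: float) -> np.ndarray:
    t = np.array([s.t for s in trial.samples])
    d = np.minimum(
        np.hypot([s.x for s in trial.samples], [s.y for s in trial.samples])
        / geometry.radius,
        1.0,
    )
    grid = geometry.frame_times
    # linear interpolation onto the fixed frame grid; hold the boundary
    # values outside the observed span
    row = np.interp(grid, t, d)

    if trial.collected and trial.collect_time is not None:
        reach_frame = int(round(trial.collect_time * geometry.sample_rate))
    else:
        above = np.nonzero(row >= 1.0 - reach_eps)[0]
        reach_frame = int(above[0]) if above.size else None
        if reach_frame is None:
            return row  # timed out: observed distances only, no white frame
    reach_frame = min(reach_frame, geometry.frames_per_trial - 1)
    row[reach_frame] = 1.0
    row[reach_frame + 1:] = 0.0
    return row


def encode_image(session: SessionRecord, lap: int = 2,
                 geometry: TaskGeometry | None = None,
                 reach_eps: float = REACH_EPS) -> FeatureImage:
    """Encode one session's lap into a feature image.

    Rows are ordered by direction number (1 at the top).  A direction with
    no trial in the lap produces a zero row and is flagged; flagged hands
    should be excluded from model training.
    """
    geometry = geometry or TaskGeometry()
    by_dir = session.trials_for_lap(lap)
    if not by_dir:
        raise MissingLapError(f"hand {session.hand_id!r}: no trials for lap {lap}")
    img = np.zeros((geometry.n_directions, geometry.frames_per_trial))
    flagged: list[int] = []
    for direction in range(1, geometry.n_directions + 1):
        trial = by_dir.get(direction)
        if trial is None or not trial.samples:
            flagged.append(direction)
            log.warning("hand %r lap %d: direction %d missing, row zero-filled",
                        session.hand_id, lap, direction)
            continue
        img[direction - 1] = _encode_row(trial, geometry, reach_eps)
    return FeatureImage(img, geometry, session.hand_id, flagged)


def flatten(image: FeatureImage) -> np.ndarray:
    """Row-major flattening: direction 1's 50 frames first, then direction 2,
    ...; length n_directions * frames_per_trial (600 by default)."""
    return image.intensities.reshape(-1).copy()


def window_label(start_direction: int, width: int, n_directions: int = 12) -> str:
    """Human-readable window label, e.g. start 8 width 4 -> "8-11",
    start 12 -> "12-3" (wraparound)."""
    end = (start_direction + width - 2) % n_directions + 1
    return f"{start_direction}-{end}"


def slice_window(image: FeatureImage, start_direction: int,
                 width: int = 4) -> np.ndarray:
    """Flattened block of ``width`` consecutive direction rows starting at
    ``start_direction``, wrapping past direction 12 back to 1."""
    n = image.geometry.n_directions
    if not 1 <= start_direction <= n:
        raise ValueError(f"start_direction {start_direction} outside 1..{n}")
    if width > n:
        raise ValueError(f"width {width} exceeds n_directions {n}")
    rows = [(start_direction - 1 + k) % n for k in range(width)]
    return image.intensities[rows].reshape(-1).copy()


def encode_cohort(sessions: Sequence[SessionRecord], lap: int = 2,
                  geometry: TaskGeometry | None = None,
                  start_direction: int | None = None,
                  width: int = 4) -> pd.DataFrame:
    """Feature table: one row per hand with metadata plus intensity columns
    v0..v599 (or v0..v199 for a window slice)."""
    geometry = geometry or TaskGeometry()
    records = []
    for s in sessions:
        image = encode_image(s, lap, geometry)
        vec = (flatten(image) if start_direction is None
               else slice_window(image, start_direction, width))
        records.append((s.hand_id, s.group, bool(image.flagged_directions), vec))
    cols = [f"v{i}" for i in range(len(records[0][3]))] if records else []
    df = pd.DataFrame([r[3] for r in records], columns=cols)
    df.insert(0, "hand_id", [r[0] for r in records])
    df.insert(1, "group", [r[1] for r in records])
    df.insert(2, "flagged", [r[2] for r in records])
    return df
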