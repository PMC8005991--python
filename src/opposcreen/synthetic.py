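"""Synthetic thumb-reaching cohorts.

Generates center-to-target reaches with the statistical structure the
screening analysis assumes: a smooth bell-shaped (minimum-jerk) speed
profile, per-hand and per-trial variability, additive positional tremor,
and an impaired profile that is globally slower, disproportionately slower
in the opposition-like directions, and occasionally times out.

The minimum-jerk time course s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 is the
standard model of point-to-point reaching; its peak-to-mean speed ratio is
exactly 1.875, which the tests use as a closed-form oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional

import numpy as np

from .core_io import Sample, SessionRecord, TaskGeometry, TrialTrajectory, direction_angle

__all__ = [
    "MotorProfile",
    "CohortSpec",
    "healthy_profile",
    "cts_profile",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "MIN_JERK_PEAK_TO_MEAN",
]

#: peak/mean speed ratio of a minimum-jerk reach (15/8)
MIN_JERK_PEAK_TO_MEAN = 1.875

#: Bland severity grades and their frequencies among the impaired hands the
#: cohort emulates (grades 1,2,3,5,6)
_BLAND_GRADES = np.array([1, 2, 3, 5, 6])
_BLAND_WEIGHTS = np.array([5, 6, 15, 9, 1]) / 36.0


@dataclass(frozen=True)
class MotorProfile:
    """Kinematic parameters of one group's reaching behaviour.

    base_speed is the mean peak thumb speed (cm/s) of an unimpaired reach;
    speed_scale <= 1 slows every reach multiplicatively (impairment dial);
    opposition_penalty multiplies movement time in ``penalty_directions``
    (the directions requiring thumb opposition); tremor_sd is isotropic
    per-sample positional noise (cm); timeout_prob is the chance a reach
    stalls short of the target; reaction_time (s) precedes movement onset.
    hand_speed_cv and time_jitter_cv add between-hand and between-trial
    lognormal variability so cohorts have realistic within-group spread.
    """

    base_speed: float = 7.5  # cm/s, peak speed of a healthy reach
    speed_scale: float = 1.0
    opposition_penalty: float = 1.0
    penalty_directions: FrozenSet[int] = frozenset(range(6, 12))  # {6..11}
    tremor_sd: float = 0.03  # cm; at 10 Hz this is ~0.5 cm/s of apparent speed
    timeout_prob: float = 0.0
    reaction_time: float = 0.3  # s
    hand_speed_cv: float = 0.10
    time_jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.base_speed <= 0 or not 0 < self.speed_scale <= 1:
            raise ValueError("base_speed > 0 and speed_scale in (0, 1] required")
        if self.opposition_penalty < 1:
            raise ValueError("opposition_penalty must be >= 1")
        if not 0 <= self.timeout_prob <= 1:
            raise ValueError("timeout_prob must be a probability")
        if min(self.tremor_sd, self.reaction_time,
               self.hand_speed_cv, self.time_jitter_cv) < 0:
            raise ValueError("noise and timing parameters must be non-negative")


def healthy_profile() -> MotorProfile:
    """Default unimpaired profile."""
    return MotorProfile()


def cts_profile(speed_scale: float = 0.6, opposition_penalty: float = 1.5) -> MotorProfile:
    """Default impaired profile: globally slowed, extra time in the
    opposition directions, noisier, with occasional timeouts."""
    return MotorProfile(speed_scale=speed_scale,
                        opposition_penalty=opposition_penalty,
                        tremor_sd=0.05, timeout_prob=0.05)


@dataclass(frozen=True)
class CohortSpec:
    """Composition and reproducibility of a simulated cohort.

    Default counts (27 unimpaired, 36 impaired hands) mirror the clinical
    study design the pipeline targets.
    """

    n_healthy: int = 27
    n_cts: int = 36
    healthy_profile: MotorProfile = field(default_factory=healthy_profile)
    cts_profile: MotorProfile = field(default_factory=cts_profile)
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_cts < 0:
            raise ValueError("cohort counts must be non-negative")


def _min_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized path position for normalized time tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def movement_time(profile: MotorProfile, direction: int,
                  geometry: TaskGeometry, speed_multiplier: float = 1.0) -> float:
    """Deterministic center-to-circle movement time (s), before jitter.

    Derived from the minimum-jerk identity mean_speed = peak_speed / 1.875
    with peak_speed = base_speed * speed_scale * speed_multiplier, then
    stretched by the opposition penalty where it applies.
    """
    peak = profile.base_speed * profile.speed_scale * speed_multiplier
    t = MIN_JERK_PEAK_TO_MEAN * geometry.radius / peak
    if direction in profile.penalty_directions:
        t *= profile.opposition_penalty
    return t


def simulate_trial(profile: MotorProfile, direction: int, geometry: TaskGeometry,
                   rng: np.random.Generator, lap: int = 2,
                   side: str = "right", speed_multiplier: float = 1.0
                   ) -> TrialTrajectory:
    """Simulate one outward reach.

    The thumb rests at the center through the reaction time, then follows a
    minimum-jerk path along the direction's angle.  With probability
    ``timeout_prob`` the reach stalls partway and the trial times out.
    Collected trials end with a terminal sample exactly on the circle at the
    collect time.
    """
    angle = direction_angle(direction, side, geometry.n_directions)
    ux, uy = math.cos(angle), math.sin(angle)
    dt = 1.0 / geometry.sample_rate

    jitter = (rng.lognormal(0.0, profile.time_jitter_cv)
              if profile.time_jitter_cv > 0 else 1.0)
    t_move = movement_time(profile, direction, geometry, speed_multiplier) * jitter
    onset = profile.reaction_time
    collect_time = onset + t_move

    timed_out = (rng.random() < profile.timeout_prob
                 or collect_time > geometry.timeout)
    if timed_out:
        # stall short of the circle: same bell-shaped course, slower and
        # truncated, then hover with tremor until the target disappears
        stall_frac = rng.uniform(0.4, 0.8)
        times = np.arange(0.0, geometry.timeout, dt)
        tau = (times - onset) / max(t_move * 1.5, dt)
        dist = stall_frac * geometry.radius * _min_jerk_position(tau)
        collected = False
        collect_time = None
    else:
        grid = np.arange(0.0, collect_time, dt)
        grid = grid[grid < collect_time - dt / 4]  # keep the terminal sample strictly last
        tau = (grid - onset) / t_move
        dist = geometry.radius * _min_jerk_position(tau)
        times = np.append(grid, collect_time)
        dist = np.append(dist, geometry.radius)
        collected = True

    xs = dist * ux
    ys = dist * uy
    if profile.tremor_sd > 0:
        noise = rng.normal(0.0, profile.tremor_sd, size=(len(times), 2))
        if collected:
            noise[-1] = 0.0  # terminal sample is the registered touch on the circle
        xs = xs + noise[:, 0]
        ys = ys + noise[:, 1]

    samples = [Sample(float(t), float(x), float(y))
               for t, x, y in zip(times, xs, ys)]
    return TrialTrajectory(direction, lap, samples, collected,
                           None if not collected else float(collect_time))


def simulate_session(hand_id: str, group: str, profile: MotorProfile,
                     geometry: TaskGeometry, rng: np.random.Generator,
                     side: str = "right", severity: Optional[int] = None,
                     n_laps: int = 2) -> SessionRecord:
    """Simulate one hand's full game: ``n_laps`` laps over all directions,
    each lap in a fresh random presentation order (as in the app)."""
    hand_mult = (rng.lognormal(0.0, profile.hand_speed_cv)
                 if profile.hand_speed_cv > 0 else 1.0)
    trials: list[TrialTrajectory] = []
    for lap in range(1, n_laps + 1):
        order = rng.permutation(np.arange(1, geometry.n_directions + 1))
        for direction in order:
            trials.append(simulate_trial(profile, int(direction), geometry,
                                         rng, lap=lap, side=side,
                                         speed_multiplier=hand_mult))
    return SessionRecord(hand_id, group, side, trials, severity)


def simulate_cohort(spec: CohortSpec) -> list[SessionRecord]:
    """Simulate a labelled case/control cohort, fully reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sessions: list[SessionRecord] = []
    for i in range(spec.n_healthy):
        side = "right" if rng.random() < 0.55 else "left"
        sessions.append(simulate_session(f"H{i + 1:03d}", "healthy",
                                         spec.healthy_profile, spec.geometry,
                                         rng, side=side))
    for i in range(spec.n_cts):
        side = "right" if rng.random() < 0.5 else "left"
        severity = int(rng.choice(_BLAND_GRADES, p=_BLAND_WEIGHTS))
        sessions.append(simulate_session(f"C{i + 1:03d}", "cts",
                                         spec.cts_profile, spec.geometry,
                                         rng, side=side, severity=severity))
    for s in sessions:
        s.validate(spec.geometry)
    return sessions
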