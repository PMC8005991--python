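"""Screening evaluation: ROC curve, AUC, Youden cutoff, confusion matrix,
and the 4-consecutive-direction window sweep.

The positive class is always "cts" and anomaly points in the direction of
higher reconstruction error; a hand is predicted positive when its score is
at or above the cutoff.  The AUC is the trapezoidal area under the ROC
curve, which equals the Mann-Whitney probability that a randomly chosen
positive outscores a randomly chosen negative (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .core_io import SessionRecord, TaskGeometry
from .encoding import encode_cohort, window_label

__all__ = [
    "RocCurve",
    "ConfusionMatrix",
    "CutoffChoice",
    "roc_curve",
    "youden_cutoff",
    "confusion_at",
    "window_sweep",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "cts"


class EvaluationError(ValueError):
    """Scores/labels unusable for ROC analysis (e.g. one class absent)."""


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep: (threshold, sensitivity, specificity) triples plus
    the trapezoidal AUC.  Thresholds are decreasing; sensitivity rises from
    0 to 1 while specificity falls from 1 to 0 along the sweep."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: str = POSITIVE_LABEL


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at one cutoff; positive = CTS."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> int:
        """Sensitivity as nearest-integer percent (presentation form)."""
        return round(100 * self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return round(100 * self.specificity)


@dataclass(frozen=True)
class CutoffChoice:
    threshold: float
    youden: float  # sensitivity + specificity - 1
    sensitivity: float
    specificity: float


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if lab == POSITIVE_LABEL else 0 for lab in labels])
    if y.all() or not y.any():
        raise EvaluationError("both classes must be present for ROC analysis")
    return y


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> RocCurve:
    """ROC curve over all distinct score thresholds (higher score => CTS).

    AUC is computed by the trapezoidal rule; with thresholds at every
    distinct score this is identical to the Mann-Whitney pair-counting
    estimate, ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise EvaluationError("scores must be finite")
    y = _as_binary(labels)
    fpr, tpr, thr = skmetrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    return RocCurve(thr, tpr, 1.0 - fpr, auc)


def youden_cutoff(curve: RocCurve) -> CutoffChoice:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (the screen feeds a
    confirmatory work-up, so false positives carry explicit cost).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    idx = best[np.argmax(curve.specificity[best])]
    thr = float(curve.thresholds[idx])
    if np.isinf(thr):
        # the sweep's sentinel above the top score: pick the smallest finite
        # cutoff that still classifies every hand as negative
        top = float(curve.thresholds[1]) if len(curve.thresholds) > 1 else 0.0
        thr = float(np.nextafter(top, np.inf))
    return CutoffChoice(thr, float(j[idx]),
                        float(curve.sensitivity[idx]),
                        float(curve.specificity[idx]))


def confusion_at(scores: Sequence[float], labels: Sequence[str],
                 threshold: float) -> ConfusionMatrix:
    """Confusion counts at a cutoff; scores equal to the cutoff are
    classified CTS (inclusive on the anomalous side)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels])
    pred = s >= threshold
    return ConfusionMatrix(tp=int((pred & y).sum()), fn=int((~pred & y).sum()),
                           tn=int((~pred & ~y).sum()), fp=int((pred & ~y).sum()))


def window_sweep(sessions: Sequence[SessionRecord],
                 geometry: TaskGeometry | None = None,
                 ae_config=None, width: int = 4,
                 train_hand_ids: Sequence[str] | None = None,
                 lap: int = 2) -> pd.DataFrame:
    """Modified screening models on every 4-consecutive-direction window.

    For each start direction 1..12 (with wraparound), the feature images are
    sliced to that window, a fresh autoencoder (input width x 50) is trained
    on the same healthy training hands as the full model, the remaining
    hands are scored, and the window's AUC and Youden-point sensitivity/
    specificity (integer percent) are reported.  Output rows are labelled
    "1-4" ... "12-3".
    """
    from .anomaly import AEConfig, score_cohort, train_autoencoder

    geometry = geometry or TaskGeometry()
    if train_hand_ids is None:
        raise ValueError("train_hand_ids is required (the healthy training split)")
    train_hand_ids = list(train_hand_ids)
    frames = geometry.frames_per_trial
    rows = []
    for start in range(1, geometry.n_directions + 1):
        label = window_label(start, width, geometry.n_directions)
        try:
            features = encode_cohort(sessions, lap=lap, geometry=geometry,
                                     start_direction=start, width=width)
            train = features[features["hand_id"].isin(train_hand_ids)]
            cfg = (AEConfig(input_dim=width * frames) if ae_config is None
                   else replace(ae_config, input_dim=width * frames))
            value_cols = [c for c in train.columns if c.startswith("v")]
            model = train_autoencoder(train[value_cols].to_numpy(), cfg,
                                      hand_ids=train["hand_id"].tolist())
            scored = score_cohort(model, features)
            curve = roc_curve(scored["mse"], scored["group"])
            cut = youden_cutoff(curve)
            cm = confusion_at(scored["mse"], scored["group"], cut.threshold)
        except Exception as exc:
            raise type(exc)(f"window {label}: {exc}") from exc
        rows.append((label, cm.sensitivity_pct, cm.specificity_pct,
                     round(curve.auc, 4)))
    return pd.DataFrame(rows, columns=["window", "sensitivity_pct",
                                       "specificity_pct", "auc"])
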