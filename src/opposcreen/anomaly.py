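"""One-class anomaly detection with a fully connected autoencoder.

The detector is a 3-layer network (600-dim input, 10-dim hidden bottleneck,
600-dim output by default) trained by full-batch gradient descent with Adam
to reconstruct feature vectors from healthy hands only.  Any hand is then
scored by the mean squared reconstruction error of its feature vector:
hands whose movement pattern lies off the healthy manifold reconstruct
poorly and receive high scores.

Because the feature intensities live in [0, 1], both the hidden and output
activations default to the logistic sigmoid and no further input scaling is
applied.  All stochastic choices (weight initialization) are driven by the
config seed, so identical data and config reproduce the model bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AEConfig",
    "AnomalyModel",
    "train_autoencoder",
    "reconstruct",
    "reconstruction_error",
    "score_cohort",
    "save_model",
    "load_model",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder architecture and training hyperparameters.

    input_dim is 600 for full images and 200 for 4-direction windows;
    hidden_dim (default 10) must be smaller than input_dim so the network
    actually compresses.  Training runs up to ``epochs`` full-batch Adam
    steps at ``learning_rate``, stopping early once the training loss has
    not improved by more than ``min_improvement`` for ``patience`` epochs.
    """

    input_dim: int
    hidden_dim: int = 10
    epochs: int = 2000
    learning_rate: float = 0.01
    batch_size: Optional[int] = None  # None = full batch
    seed: int = 0
    activation: str = "sigmoid"
    patience: int = 200
    min_improvement: float = 1e-7

    def __post_init__(self) -> None:
        if self.hidden_dim >= self.input_dim:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} must be < input_dim "
                f"{self.input_dim} (the bottleneck must compress)"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.activation not in ("sigmoid", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")


@dataclass
class AnomalyModel:
    """Trained autoencoder: weights, config, loss trace and provenance."""

    w_enc: np.ndarray  # (input_dim, hidden_dim)
    b_enc: np.ndarray  # (hidden_dim,)
    w_dec: np.ndarray  # (hidden_dim, input_dim)
    b_dec: np.ndarray  # (input_dim,)
    config: AEConfig
    loss_trace: np.ndarray
    trained_on: list[str] = field(default_factory=list)


def _act(z: np.ndarray, name: str) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


def _act_grad(a: np.ndarray, name: str) -> np.ndarray:
    # expressed in terms of the activation value
    if name == "sigmoid":
        return a * (1.0 - a)
    return 1.0 - a * a


def _forward(model_params, x: np.ndarray, activation: str):
    w1, b1, w2, b2 = model_params
    h = _act(x @ w1 + b1, activation)
    out = _act(h @ w2 + b2, "sigmoid")  # outputs live in [0, 1]
    return h, out


def train_autoencoder(vectors: np.ndarray | Sequence[Sequence[float]],
                      config: AEConfig,
                      hand_ids: Sequence[str] | None = None) -> AnomalyModel:
    """Train on healthy feature vectors only.

    ``vectors`` is (n_train, input_dim).  Weights start from a seeded Glorot
    uniform draw; optimization is Adam on the mean squared reconstruction
    error over all components.  Raises :class:`DivergenceError` (naming the
    epoch) if the loss goes non-finite.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[1] != config.input_dim:
        raise ValueError(
            f"training matrix shape {x.shape} incompatible with input_dim "
            f"{config.input_dim}"
        )
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    hand_ids = list(hand_ids) if hand_ids is not None else []

    rng = np.random.default_rng(config.seed)
    d, h = config.input_dim, config.hidden_dim

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    params = [glorot(d, h), np.zeros(h), glorot(h, d), np.zeros(d)]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    n = x.shape[0]

    losses = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        if config.batch_size is None or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, int(np.ceil(n / config.batch_size)))
        for idx in batches:
            xb = x[idx]
            hid, out = _forward(params, xb, config.activation)
            err = out - xb  # (b, d)
            scale = 2.0 / err.size
            # backprop through sigmoid output and hidden activation
            delta_out = scale * err * _act_grad(out, "sigmoid")
            grads = [None] * 4
            grads[2] = hid.T @ delta_out
            grads[3] = delta_out.sum(axis=0)
            delta_hid = (delta_out @ params[2].T) * _act_grad(hid, config.activation)
            grads[0] = xb.T @ delta_hid
            grads[1] = delta_hid.sum(axis=0)
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1 ** (epoch + 1))
                vhat = v[i] / (1 - beta2 ** (epoch + 1))
                params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)
        _, out = _forward(params, x, config.activation)
        loss = float(np.mean((out - x) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        losses.append(loss)
        if loss < best - config.min_improvement:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    return AnomalyModel(params[0], params[1], params[2], params[3],
                        config, np.array(losses), hand_ids)


def reconstruct(model: AnomalyModel, vector: np.ndarray) -> np.ndarray:
    """The autoencoder's reconstruction of one feature vector."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (model.config.input_dim,):
        raise ValueError(
            f"vector length {v.shape} != model input_dim {model.config.input_dim}"
        )
    _, out = _forward((model.w_enc, model.b_enc, model.w_dec, model.b_dec),
                      v[None, :], model.config.activation)
    return out[0]


def reconstruction_error(model: AnomalyModel, vector: np.ndarray) -> float:
    """Anomaly score: mean squared error between input and reconstruction."""
    v = np.asarray(vector, dtype=float)
    out = reconstruct(model, v)
    return float(np.mean((v - out) ** 2))


def score_cohort(model: AnomalyModel, features: pd.DataFrame,
                 include_trained: bool = False) -> pd.DataFrame:
    """Score every hand in a feature table (as built by
    :func:`opposcreen.encoding.encode_cohort`).

    Hands the model was trained on are excluded unless ``include_trained``
    (diagnostics only); an empty validation set after exclusion is an error.
    Returns columns hand_id, group, mse.
    """
    value_cols = [c for c in features.columns if c.startswith("v")]
    rows = []
    for rec in features.itertuples():
        if not include_trained and rec.hand_id in model.trained_on:
            continue
        vec = np.array([getattr(rec, c) for c in value_cols], dtype=float)
        rows.append((rec.hand_id, rec.group, reconstruction_error(model, vec)))
    if not rows:
        raise ValueError("validation set is empty after excluding training hands")
    return pd.DataFrame(rows, columns=["hand_id", "group", "mse"])


# ---------------------------------------------------------------------------
# Portable model serialization: versioned JSON with layer sizes and
# row-major weight lists.
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: AnomalyModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format": "opposcreen-autoencoder",
        "version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "layers": {
            "w_enc": model.w_enc.tolist(),
            "b_enc": model.b_enc.tolist(),
            "w_dec": model.w_dec.tolist(),
            "b_dec": model.b_dec.tolist(),
        },
        "loss_trace": model.loss_trace.tolist(),
        "trained_on": model.trained_on,
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> AnomalyModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "opposcreen-autoencoder":
        raise ValueError(f"{path}: not an opposcreen autoencoder file")
    if payload.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    cfg = AEConfig(**payload["config"])
    layers = payload["layers"]
    return AnomalyModel(np.array(layers["w_enc"]), np.array(layers["b_enc"]),
                        np.array(layers["w_dec"]), np.array(layers["b_dec"]),
                        cfg, np.array(payload["loss_trace"]),
                        list(payload["trained_on"]))
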