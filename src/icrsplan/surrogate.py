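"""Feedforward surrogate of the segment implant's morphological effect.

A fully-connected network maps (preoperative 8 mm Zernike elevation vector,
encoding of one or two ring segments) to the predicted postoperative
elevation vector on the same aperture.  Training is plain full-batch
backpropagation of the mean squared error with a momentum update

    Δw_t = −η ∇E(w) + α Δw_{t−1},

implemented here directly (the learning rule is the point, not a library
call).  Only cases passing the clinical success filter may be used for
training.  All randomness flows from one explicit seed, so identical
seed + data + hyperparameters reproduce identical weights bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .clinical import CaseRecord, success_filter
from .segments import (
    DEFAULT_THICKNESSES_UM,
    SEGMENT_ARCS,
    SEGMENT_CATALOG,
    SEGMENT_MODELS,
    SegmentSpec,
)
from .zernike import ZernikeCoefficients, n_terms

__all__ = [
    "SegmentSpec",
    "SEGMENT_CATALOG",
    "DEFAULT_THICKNESSES_UM",
    "SurrogateModel",
    "SurrogateEnsemble",
    "TrainingDataError",
    "DivergenceError",
    "encode_features",
    "feature_names",
    "train",
    "predict_postop",
    "predict_postop_batch",
    "save_model",
    "load_model",
]

N_ZERNIKE = n_terms(7)          # 36
_SLOT_WIDTH = 10                # per-segment feature block
N_FEATURES = N_ZERNIKE + 2 * _SLOT_WIDTH

DEFAULT_LAYER_SIZES = (N_FEATURES, 40, N_ZERNIKE)
DEFAULT_LEARNING_RATE = 0.01
DEFAULT_MOMENTUM = 0.9
DEFAULT_EPOCHS = 2000


class TrainingDataError(ValueError):
    """Raised when the training set violates the success-only contract."""


class DivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

def _slot_features(seg: SegmentSpec) -> list[float]:
    model_onehot = [1.0 if seg.model == m else 0.0 for m in SEGMENT_MODELS]
    arcs = SEGMENT_ARCS[seg.model]
    arc_onehot = [1.0 if seg.arc_deg == a else 0.0 for a in arcs]
    a = np.deg2rad(seg.bisecting_line_deg)
    return model_onehot + arc_onehot + [
        seg.thickness_um / 100.0,
        float(np.sin(a)),
        float(np.cos(a)),
        1.0,                    # presence flag
    ]


def encode_features(
    preop: ZernikeCoefficients, segments: Sequence[SegmentSpec]
) -> np.ndarray:
    """Fixed-order feature vector: 36 Zernike values + two segment slots.

    Each slot holds model one-hot (2), arc one-hot within the family (4),
    thickness (per 100 μm), the bisecting line as (sin a, cos a), and a
    presence flag; an absent second segment is all zeros.  Segments are
    canonically sorted so the encoding does not depend on input order.
    """
    if preop.max_order != 7:
        raise ValueError("surrogate features require a 7th-order expansion")
    if abs(preop.pupil_diameter_mm - 8.0) > 1e-6:
        raise ValueError(
            f"surrogate features require coefficients on an 8 mm aperture, "
            f"got {preop.pupil_diameter_mm} mm"
        )
    segs = list(segments)
    if not (1 <= len(segs) <= 2):
        raise ValueError(f"expected 1 or 2 segments, got {len(segs)}")
    segs.sort(key=SegmentSpec.sort_key)
    feats = list(preop.values)
    for slot in range(2):
        if slot < len(segs):
            feats.extend(_slot_features(segs[slot]))
        else:
            feats.extend([0.0] * _SLOT_WIDTH)
    return np.asarray(feats, dtype=float)


def feature_names() -> list[str]:
    names = [f"z{j}" for j in range(N_ZERNIKE)]
    for slot in (1, 2):
        names += [f"s{slot}_{t}" for t in (
            "is_si5", "is_si6", "arc0", "arc1", "arc2", "arc3",
            "thickness", "axis_sin", "axis_cos", "present",
        )]
    return names


# ---------------------------------------------------------------------------
# network core
# ---------------------------------------------------------------------------

def _init_params(layer_sizes: Sequence[int], seed: int):
    """Seeded uniform weights scaled by 1/sqrt(fan_in); zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(
            rng.uniform(-1.0, 1.0, size=(fan_out, fan_in)) / np.sqrt(fan_in)
        )
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(weights, biases, X):
    """Forward pass; tanh hidden layers, linear output.  Returns
    activations per layer (input first)."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W.T + b
        a = z if i == last else np.tanh(z)
        acts.append(a)
    return acts


def _loss_and_grads(weights, biases, X, Y):
    """MSE over all output entries and its gradients by backpropagation."""
    # overflow on a diverging run is reported as DivergenceError, not warned
    with np.errstate(over="ignore", invalid="ignore"):
        acts = _forward(weights, biases, X)
        pred = acts[-1]
        diff = pred - Y
        loss = float(np.mean(diff**2))
        n_entries = diff.size
        delta = 2.0 * diff / n_entries      # dL/d(pre-activation), output linear
        gw = [None] * len(weights)
        gb = [None] * len(biases)
        for i in range(len(weights) - 1, -1, -1):
            gw[i] = delta.T @ acts[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ weights[i]) * (1.0 - acts[i] ** 2)
    return loss, gw, gb


def _standardize(A: np.ndarray):
    mean = A.mean(axis=0)
    std = A.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


@dataclass
class SurrogateModel:
    """Trained network weights with the normalization baked alongside.

    With ``residual_output`` (the default) the network predicts the
    implant-induced coefficient *change* and the preoperative vector is
    added back on output — the identity part of the mapping is carried
    exactly instead of being re-learned from 75 cases.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    activation: str = "tanh"
    residual_output: bool = True
    metadata: dict = field(default_factory=dict)
    loss_history: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.x_mean) / self.x_std
        out = _forward(self.weights, self.biases, Xn)[-1]
        out = out * self.y_std + self.y_mean
        if self.residual_output:
            out = out + X[:, :N_ZERNIKE]
        return out


class SurrogateEnsemble:
    """Committee of independently seeded training runs.

    Averaging the predictions of a few networks trained on the same data
    with different seeds reduces the variance of the learned implant
    response — useful when the planner's argmax must discriminate between
    closely ranked candidates.
    """

    def __init__(self, models: Sequence[SurrogateModel]):
        if not models:
            raise ValueError("ensemble needs at least one model")
        self.models = list(models)

    def predict_postop(
        self, preop: ZernikeCoefficients, segments: Sequence[SegmentSpec]
    ) -> ZernikeCoefficients:
        vals = np.mean(
            [predict_postop(m, preop, segments).values for m in self.models],
            axis=0,
        )
        return ZernikeCoefficients(vals, pupil_diameter_mm=8.0, max_order=7)

    def predict_batch(self, preop, segment_lists) -> np.ndarray:
        return np.mean(
            [predict_postop_batch(m, preop, segment_lists)
             for m in self.models],
            axis=0,
        )


def _fit_network(
    X: np.ndarray,
    Y: np.ndarray,
    layer_sizes: Sequence[int],
    learning_rate: float,
    momentum: float,
    epochs: int,
    seed: int,
) -> tuple[list, list, np.ndarray]:
    """Gradient descent with momentum on standardized data."""
    weights, biases = _init_params(layer_sizes, seed)
    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    history = np.empty(epochs)
    for epoch in range(epochs):
        loss, gw, gb = _loss_and_grads(weights, biases, X, Y)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"training loss became non-finite at epoch {epoch} "
                f"(learning_rate={learning_rate}); reduce the learning rate"
            )
        history[epoch] = loss
        for i in range(len(weights)):
            vel_w[i] = momentum * vel_w[i] - learning_rate * gw[i]
            vel_b[i] = momentum * vel_b[i] - learning_rate * gb[i]
            weights[i] = weights[i] + vel_w[i]
            biases[i] = biases[i] + vel_b[i]
    return weights, biases, history


def train(
    cases: Sequence[CaseRecord],
    layer_sizes: Sequence[int] | None = None,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    momentum: float = DEFAULT_MOMENTUM,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    min_cases: int = 10,
    residual_output: bool = True,
) -> SurrogateModel:
    """Train the surrogate on success-filtered cases.

    Every case must pass :func:`icrsplan.clinical.success_filter` — the
    network learns only from surgeries that worked.  Inputs and targets are
    standardized per feature from the training data; the statistics are
    stored in the model.  Deterministic given the seed.
    """
    cases = list(cases)
    if len(cases) < min_cases:
        raise TrainingDataError(
            f"need at least {min_cases} training cases, got {len(cases)}"
        )
    for i, case in enumerate(cases):
        if not success_filter(case).is_success:
            raise TrainingDataError(
                f"case {i} does not pass the success filter; only successful "
                "cases may train the surrogate"
            )
    X = np.stack([encode_features(c.preop_coeffs, c.implant) for c in cases])
    Y = np.stack([c.postop_coeffs.values for c in cases])
    if residual_output:
        Y = Y - X[:, :N_ZERNIKE]
    if layer_sizes is None:
        layer_sizes = (X.shape[1], 40, Y.shape[1])
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if layer_sizes[0] != X.shape[1] or layer_sizes[-1] != Y.shape[1]:
        raise ValueError(
            f"layer_sizes {layer_sizes} incompatible with features "
            f"{X.shape[1]} and targets {Y.shape[1]}"
        )
    x_mean, x_std = _standardize(X)
    y_mean, y_std = _standardize(Y)
    Xn = (X - x_mean) / x_std
    Yn = (Y - y_mean) / y_std
    weights, biases, history = _fit_network(
        Xn, Yn, layer_sizes, learning_rate, momentum, epochs, seed
    )
    return SurrogateModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        residual_output=residual_output,
        metadata={
            "learning_rate": learning_rate,
            "momentum": momentum,
            "epochs": epochs,
            "seed": seed,
            "n_cases": len(cases),
            "final_mse": float(history[-1]) if epochs else None,
        },
        loss_history=history,
    )


def predict_postop(
    model: SurrogateModel,
    preop: ZernikeCoefficients,
    segments: Sequence[SegmentSpec],
) -> ZernikeCoefficients:
    """Predicted postoperative elevation coefficients (μm, 8 mm, order 7)."""
    x = encode_features(preop, segments)
    if x.size != model.layer_sizes[0]:
        raise ValueError(
            f"feature vector length {x.size} does not match model input "
            f"size {model.layer_sizes[0]}"
        )
    y = model.forward(x[None, :])[0]
    return ZernikeCoefficients(y, pupil_diameter_mm=8.0, max_order=7)


def predict_postop_batch(
    model: SurrogateModel,
    preop: ZernikeCoefficients,
    segment_lists: Sequence[Sequence[SegmentSpec]],
) -> np.ndarray:
    """Vectorized prediction for many candidate segment sets (planner)."""
    X = np.stack([encode_features(preop, segs) for segs in segment_lists])
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError("feature-count mismatch with model")
    return model.forward(X)


# ---------------------------------------------------------------------------
# persistence (versioned structured-text container)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Serialize to a versioned JSON container (deterministic bytes)."""
    doc = {
        "format": "icrsplan-surrogate",
        "version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "activation": model.activation,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "y_mean": model.y_mean.tolist(),
        "y_std": model.y_std.tolist(),
        "residual_output": model.residual_output,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path: str | Path) -> SurrogateModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "icrsplan-surrogate":
        raise ValueError(f"{path}: not a surrogate model file")
    if doc.get("version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    return SurrogateModel(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[np.asarray(W, dtype=float) for W in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        x_std=np.asarray(doc["x_std"], dtype=float),
        y_mean=np.asarray(doc["y_mean"], dtype=float),
        y_std=np.asarray(doc["y_std"], dtype=float),
        activation=doc.get("activation", "tanh"),
        residual_output=doc.get("residual_output", True),
        metadata=doc.get("metadata", {}),
    )
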