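"""Single-hidden-layer sigmoid network with min-max feature coding.

The model is deliberately tiny: ``m`` coded inputs, one hidden layer of
``h`` sigmoid nodes (no hidden bias), and one sigmoid output node with a
fixed +1 bias input.  All weights live in a flat vector of length
``P = m*h + h + 1`` whose layout is input-major across hidden nodes:
hidden node ``j`` receives input ``i`` through weight index
``(i-1)*h + j``, output weights occupy ``m*h + 1 .. m*h + h`` and the bias
weight is the last entry.  This layout is what ties each weight to one
column of the orthogonal training plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "FeatureScale",
    "encode",
    "decode",
    "sigmoid",
    "forward",
    "risk_score",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture bookkeeping: m inputs, h hidden nodes, P weights."""

    n_inputs: int
    n_hidden: int

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("n_inputs and n_hidden must be >= 1")

    @property
    def n_weights(self) -> int:
        m, h = self.n_inputs, self.n_hidden
        return m * h + h + 1

    def hidden_weight_index(self, i: int, j: int) -> int:
        """1-based flat index of the weight from input i to hidden node j."""
        if not (1 <= i <= self.n_inputs and 1 <= j <= self.n_hidden):
            raise ValueError("input/hidden index out of range")
        return (i - 1) * self.n_hidden + j

    def output_weight_index(self, j: int) -> int:
        """1-based flat index of the weight from hidden node j to the output."""
        if not 1 <= j <= self.n_hidden:
            raise ValueError("hidden index out of range")
        return self.n_inputs * self.n_hidden + j

    @property
    def bias_index(self) -> int:
        return self.n_weights


@dataclass(frozen=True)
class FeatureScale:
    """Min-max coding range of one raw feature."""

    name: str
    x_min: float
    x_max: float

    def __post_init__(self):
        if not self.x_max > self.x_min:
            raise ValueError(f"constant feature {self.name!r}: x_max must exceed x_min")


def encode(x, scale: FeatureScale):
    """Min-max code a raw value into [0, 1], clipping out-of-range values.

    ``(x - x_min) / (x_max - x_min)``; the coded scale makes features with
    different units commensurable before they enter the network.
    """
    y = (np.asarray(x, dtype=float) - scale.x_min) / (scale.x_max - scale.x_min)
    return np.clip(y, 0.0, 1.0)


def decode(y, scale: FeatureScale):
    """Inverse of :func:`encode`: ``x_min + y * (x_max - x_min)``."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("coded value outside [0, 1]")
    return scale.x_min + y * (scale.x_max - scale.x_min)


def sigmoid(z):
    """Logistic function 1 / (1 + exp(-z)), stable for large |z|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def _split_weights(spec: NetworkSpec, w: np.ndarray):
    m, h = spec.n_inputs, spec.n_hidden
    W_hidden = w[: m * h].reshape(m, h)  # row i: input i+1 -> each hidden node
    W_out = w[m * h : m * h + h]
    bias = w[-1]
    return W_hidden, W_out, bias


def forward(spec: NetworkSpec, weights, x):
    """Forward pass on coded inputs.

    Parameters
    ----------
    spec : NetworkSpec
    weights : array-like of length ``spec.n_weights``
    x : array-like, shape (m,) or (n, m)
        Coded feature vectors in [0, 1].

    Returns
    -------
    float or ndarray
        Output in (0, 1), one value per row of ``x``.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (spec.n_weights,):
        raise ValueError(
            f"shape error: expected {spec.n_weights} weights, got {w.shape}"
        )
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != spec.n_inputs:
        raise ValueError(
            f"shape error: expected {spec.n_inputs} inputs, got {X.shape[1]}"
        )
    W_hidden, W_out, bias = _split_weights(spec, w)
    Y = sigmoid(X @ W_hidden)          # (n, h) hidden activations
    out = sigmoid(Y @ W_out + bias)    # fixed +1 bias input on the output node
    return float(out[0]) if single else out


def risk_score(outputs) -> float:
    """Cohort-level risk: arithmetic mean of per-subject network outputs."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.size == 0:
        raise ValueError("no subjects")
    return float(outputs.mean())


def save_model(path, spec: NetworkSpec, weights, scales) -> None:
    """Serialize a trained model (architecture, weights, feature scales) to JSON."""
    doc = {
        "spec": {"m": spec.n_inputs, "h": spec.n_hidden},
        "weights": [float(v) for v in np.asarray(weights, dtype=float)],
        "scales": [
            {"name": s.name, "xmin": s.x_min, "xmax": s.x_max} for s in scales
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_model(path):
    """Inverse of :func:`save_model`; returns (spec, weights, scales)."""
    with open(path) as fh:
        doc = json.load(fh)
    spec = NetworkSpec(doc["spec"]["m"], doc["spec"]["h"])
    weights = np.asarray(doc["weights"], dtype=float)
    if weights.shape != (spec.n_weights,):
        raise ValueError("shape error: weight count does not match architecture")
    scales = [FeatureScale(s["name"], s["xmin"], s["xmax"]) for s in doc["scales"]]
    return spec, weights, scales
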