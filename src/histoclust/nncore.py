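"""Layer mathematics as standalone, testable primitives.

Activation functions, shape contracts for same-padded convolution and 2x2
pooling, closed-form trainable-parameter counts for dense and LSTM layers,
the softmax cross-entropy decision loss, and the soft-margin linear SVM
objective.  The layer engine in :mod:`histoclust.layers` uses these same
definitions; the network builders assert their analytic parameter counts
against brute-force enumeration of the built tensors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "tanh",
    "relu",
    "leaky_relu",
    "activation",
    "conv_output_shape",
    "pool_output_shape",
    "lstm_param_count",
    "dense_param_count",
    "softmax",
    "softmax_and_loss",
    "svm_objective",
]


# ---------------------------------------------------------------------------
# activations (total functions of a real array)

def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def tanh(x):
    return np.tanh(np.asarray(x, dtype=np.float64))


def relu(x):
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def leaky_relu(x, beta: float = 0.01):
    """x for x > 0, beta*x otherwise, with slope beta in (0, 1)."""
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, beta * x)


_ACTIVATIONS = {
    "sigmoid": sigmoid,
    "tanh": tanh,
    "relu": relu,
    "leaky_relu": leaky_relu,
}


def activation(kind: str, x, beta: float = 0.01):
    """Dispatch by name: sigmoid, tanh, relu or leaky_relu."""
    if kind not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {kind!r}")
    if kind == "leaky_relu":
        return leaky_relu(x, beta)
    return _ACTIVATIONS[kind](x)


# ---------------------------------------------------------------------------
# shape contracts

def conv_output_shape(in_shape: tuple[int, int], kernel: tuple[int, int] = (3, 3),
                      padding: str = "same", stride: int = 1) -> tuple[int, int]:
    """Spatial output shape of a convolution.

    Only the configuration used by the models is supported: odd kernels,
    stride 1, 'same' zero padding — which preserves H x W exactly.
    """
    h, w = in_shape
    kh, kw = kernel
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel must be odd-sized")
    if stride != 1 or padding != "same":
        raise ValueError("only stride-1 'same' convolutions are supported")
    if h < 1 or w < 1:
        raise ValueError("input shape must be positive")
    return (h, w)


def pool_output_shape(in_shape: tuple[int, int], kernel: tuple[int, int] = (2, 2)) -> tuple[int, int]:
    """2x2 non-overlapping pooling halves each spatial dimension."""
    h, w = in_shape
    kh, kw = kernel
    if (kh, kw) != (2, 2):
        raise ValueError("only 2x2 pooling is used by these models")
    if h % 2 or w % 2:
        raise ValueError(f"pooling needs even dimensions, got {h}x{w}")
    return (h // 2, w // 2)


# ---------------------------------------------------------------------------
# parameter-count formulas

def lstm_param_count(input_dim: int, hidden: int) -> int:
    """Trainable parameters of one LSTM layer: 4·(h·(d + h) + h).

    Four gate blocks (input gate, forget gate, candidate, output gate),
    each with an input projection (h·d), a recurrent projection (h·h) and a
    bias (h).
    """
    if input_dim < 1 or hidden < 1:
        raise ValueError("input_dim and hidden must be >= 1")
    return 4 * (hidden * (input_dim + hidden) + hidden)


def dense_param_count(in_units: int, out_units: int) -> int:
    """Fully connected layer: in·out weights plus out biases."""
    if in_units < 1 or out_units < 1:
        raise ValueError("unit counts must be >= 1")
    return in_units * out_units + out_units


def conv_param_count(in_maps: int, out_maps: int, kernel: tuple[int, int] = (3, 3)) -> int:
    """Convolution layer: k1·k2·in·out weights plus one bias per map."""
    kh, kw = kernel
    if min(in_maps, out_maps, kh, kw) < 1:
        raise ValueError("all counts must be >= 1")
    return kh * kw * in_maps * out_maps + out_maps


# ---------------------------------------------------------------------------
# decision-layer losses

def softmax(scores):
    """Row-wise softmax, log-sum-exp stabilized."""
    s = np.asarray(scores, dtype=np.float64)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_and_loss(end_scores, true_class: int) -> tuple[np.ndarray, float]:
    """Class probabilities and cross-entropy loss for one score vector.

    ``true_class`` is 1-based (1 = benign, 2 = malignant).  Returns
    (probabilities summing to 1, −ln of the true-class probability).
    """
    scores = np.asarray(end_scores, dtype=np.float64).ravel()
    if not (1 <= true_class <= scores.size):
        raise ValueError(f"true_class must be in 1..{scores.size}")
    shifted = scores - scores.max()
    log_probs = shifted - np.log(np.exp(shifted).sum())
    probs = np.exp(log_probs)
    loss = float(-log_probs[true_class - 1])
    return probs, loss


def svm_objective(w, x, y, c: float) -> float:
    """Soft-margin linear SVM objective ½‖W‖² + C·Σ max(0, 1 − yᵢ⟨W, xᵢ⟩).

    ``y`` takes values in {−1, +1} (malignant = +1).
    """
    if c <= 0:
        raise ValueError("C must be positive")
    w = np.asarray(w, dtype=np.float64).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape[1] != w.size:
        raise ValueError(f"dimension mismatch: W has {w.size}, data has {x.shape[1]}")
    if x.shape[0] != y.size:
        raise ValueError("x and y differ in length")
    margins = y * (x @ w)
    slack = np.maximum(0.0, 1.0 - margins)
    return float(0.5 * w @ w + c * slack.sum())
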