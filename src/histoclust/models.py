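"""Builders for the three tile-classifier architectures.

* Model 1 — a compact CNN: five 3x3 same-padded ReLU convolutions with
  three interleaved 2x2 poolings, shrinking 32x32 maps to 4x4; the final
  16 maps flatten to 256 features ahead of dropout and the decision layer.
* Model 2 — a stacked LSTM over the flattened pixel sequence: the 3072
  pixel values are reshaped into TS time steps of ID features (TS·ID must
  equal 3072), pass a 42-unit sequence-returning LSTM (L-1) and a second
  recurrent block producing 42 outputs (L-2), then dropout, a 22-unit
  dense layer and the decision layer.
* Model 3 — a CNN-LSTM hybrid: three 32-map convolutions and one pooling,
  a 512-unit dense bottleneck reshaped into TS×ID (TS·ID = 512), an LSTM
  block, a 65-unit dense layer, dropout and the decision layer.

The L-2 block of Model 2 is realized by default as a bidirectional 42-unit
LSTM with summed directions, which contributes exactly the parameters of
two 42-unit layers; a plain two-extra-stacked-layers realization with the
identical count is selectable (``l2="stacked"``).  docs/methods.md walks
through the parameter-count reconciliation that pins this choice.

All builders are deterministic given a seed, and every analytic parameter
count is re-derivable with :mod:`histoclust.nncore` formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nncore
from .layers import (
    AvgPool2D,
    Bidirectional,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    MaxPool2D,
    Network,
    SequenceReshape,
)

__all__ = [
    "ModelSpec",
    "MODEL2_FLAT_LENGTH",
    "MODEL3_BOTTLENECK",
    "reshape_to_sequence",
    "build_model1",
    "build_model2",
    "build_model3",
    "build_model",
    "count_parameters",
    "model2_parameter_count",
]

INPUT_SHAPE = (32, 32, 3)
MODEL2_FLAT_LENGTH = 32 * 32 * 3  # 3072
MODEL3_BOTTLENECK = 512
N_CLASSES = 2


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture configuration."""

    model_id: int
    ts: int | None = None
    id_dim: int | None = None
    conv_maps: tuple[int, ...] | None = None
    dropout_p: float = 0.25
    lstm_hidden: int = 42
    l2: str = "bidirectional"  # or "stacked"
    pooling: str = "max"  # or "avg"
    decision: str = "softmax"  # or "svm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.decision not in ("softmax", "svm"):
            raise ValueError("decision must be 'softmax' or 'svm'")
        if self.pooling not in ("max", "avg"):
            raise ValueError("pooling must be 'max' or 'avg'")


def reshape_to_sequence(vector_length: int, ts: int, id_dim: int) -> tuple[int, int]:
    """Validate and return the (time steps, input dimension) factorization.

    The flattened feature vector is read row-major into ``ts`` steps of
    ``id_dim`` features each; ``ts * id_dim`` must equal the vector length.
    """
    if ts < 1 or id_dim < 1:
        raise ValueError("ts and id_dim must be >= 1")
    if ts * id_dim != vector_length:
        raise ValueError(
            f"ts={ts} x id_dim={id_dim} = {ts * id_dim} does not factor the "
            f"{vector_length}-element feature vector"
        )
    return (ts, id_dim)


def _pool(kind: str, name: str):
    layer = MaxPool2D() if kind == "max" else AvgPool2D()
    layer.name = name
    return layer


def build_model1(
    conv_maps: tuple[int, ...] = (16, 16, 16, 16, 16),
    dropout_p: float = 0.25,
    pooling: str = "max",
    seed: int = 0,
) -> Network:
    """The CNN (Model 1): C1-C2-P1-C3-P2-C4-P3-C5, flatten, dropout, head.

    Spatial sizes run 32,32,16,16,8,8,4,4; with the default 16 maps in C5
    the flattened layer holds 16·4·4 = 256 features.
    """
    if len(conv_maps) != 5:
        raise ValueError(f"model 1 has five convolutions, got {len(conv_maps)} map counts")
    m = conv_maps
    layers = [
        Conv2D(3, m[0], name="C-1"),
        Conv2D(m[0], m[1], name="C-2"),
        _pool(pooling, "P-1"),
        Conv2D(m[1], m[2], name="C-3"),
        _pool(pooling, "P-2"),
        Conv2D(m[2], m[3], name="C-4"),
        _pool(pooling, "P-3"),
        Conv2D(m[3], m[4], name="C-5"),
        Flatten(),
        Dropout(dropout_p, name="dropout"),
        Dense(m[4] * 4 * 4, N_CLASSES, activation="linear", name="decision"),
    ]
    return Network(layers, INPUT_SHAPE, seed=seed, name="model1")


def _l2_block(hidden: int, realization: str) -> list:
    """The second recurrent block of Model 2.

    Both realizations contribute the parameters of two ``hidden``-unit
    LSTM layers operating on ``hidden``-dimensional input and emit
    ``hidden`` output neurons.
    """
    if realization == "bidirectional":
        return [Bidirectional(LSTM(hidden, hidden, return_sequences=False, name="L-2"),
                              name="L-2 (bi)")]
    if realization == "stacked":
        return [
            LSTM(hidden, hidden, return_sequences=True, name="L-2a"),
            LSTM(hidden, hidden, return_sequences=False, name="L-2b"),
        ]
    raise ValueError(f"unknown L-2 realization {realization!r}")


def build_model2(
    ts: int,
    id_dim: int,
    hidden: int = 42,
    dense_units: int = 22,
    dropout_p: float = 0.25,
    l2: str = "bidirectional",
    seed: int = 0,
) -> Network:
    """The stacked LSTM (Model 2) over the flattened 3072-pixel sequence."""
    reshape_to_sequence(MODEL2_FLAT_LENGTH, ts, id_dim)
    layers = [
        Flatten(),
        SequenceReshape(ts, id_dim, name="to-sequence"),
        LSTM(id_dim, hidden, return_sequences=True, name="L-1"),
        *_l2_block(hidden, l2),
        Dropout(dropout_p, name="dropout"),
        Dense(hidden, dense_units, activation="relu", name="dense-22"),
        Dense(dense_units, N_CLASSES, activation="linear", name="decision"),
    ]
    return Network(layers, INPUT_SHAPE, seed=seed, name="model2")


def build_model3(
    ts: int,
    id_dim: int,
    conv_maps: tuple[int, ...] = (32, 32, 32),
    bottleneck: int = MODEL3_BOTTLENECK,
    hidden: int = 42,
    post_dense: int = 65,
    dropout_p: float = 0.25,
    pooling: str = "max",
    seed: int = 0,
) -> Network:
    """The CNN-LSTM hybrid (Model 3)."""
    if len(conv_maps) != 3:
        raise ValueError(f"model 3 has three convolutions, got {len(conv_maps)} map counts")
    reshape_to_sequence(bottleneck, ts, id_dim)
    m = conv_maps
    layers = [
        Conv2D(3, m[0], name="C-1"),
        Conv2D(m[0], m[1], name="C-2"),
        Conv2D(m[1], m[2], name="C-3"),
        _pool(pooling, "P-1"),
        Flatten(),
        Dense(m[2] * 16 * 16, bottleneck, activation="relu", name="dense-512"),
        SequenceReshape(ts, id_dim, name="to-sequence"),
        LSTM(id_dim, hidden, return_sequences=False, name="LSTM"),
        Dense(hidden, post_dense, activation="relu", name="dense-65"),
        Dropout(dropout_p, name="dropout"),
        Dense(post_dense, N_CLASSES, activation="linear", name="decision"),
    ]
    return Network(layers, INPUT_SHAPE, seed=seed, name="model3")


def build_model(spec: ModelSpec) -> Network:
    """Build a network from a :class:`ModelSpec`."""
    if spec.model_id == 1:
        return build_model1(
            conv_maps=spec.conv_maps or (16,) * 5,
            dropout_p=spec.dropout_p,
            pooling=spec.pooling,
            seed=spec.seed,
        )
    if spec.model_id == 2:
        if spec.ts is None or spec.id_dim is None:
            raise ValueError("model 2 needs explicit ts and id_dim (ts * id_dim = 3072)")
        return build_model2(
            spec.ts, spec.id_dim, hidden=spec.lstm_hidden,
            dropout_p=spec.dropout_p, l2=spec.l2, seed=spec.seed,
        )
    if spec.ts is None or spec.id_dim is None:
        raise ValueError("model 3 needs explicit ts and id_dim (ts * id_dim = 512)")
    return build_model3(
        spec.ts, spec.id_dim, conv_maps=spec.conv_maps or (32,) * 3,
        hidden=spec.lstm_hidden, dropout_p=spec.dropout_p,
        pooling=spec.pooling, seed=spec.seed,
    )


def count_parameters(net: Network) -> int:
    """Total trainable parameters: brute-force sum over parameter tensors."""
    return net.count_parameters()


def model2_parameter_count(ts: int, id_dim: int, hidden: int = 42,
                           dense_units: int = 22) -> int:
    """Analytic Model-2 parameter total from the closed-form layer counts.

    L-1 consumes ``id_dim`` features; the L-2 block costs two
    ``hidden``-unit LSTM layers on ``hidden``-dimensional input; then the
    two dense layers.  Only ``id_dim`` (not ``ts``) enters the total, so
    consecutive sweep configurations differ by 4·hidden·ΔID.
    """
    reshape_to_sequence(MODEL2_FLAT_LENGTH, ts, id_dim)
    return (
        nncore.lstm_param_count(id_dim, hidden)
        + 2 * nncore.lstm_param_count(hidden, hidden)
        + nncore.dense_param_count(hidden, dense_units)
        + nncore.dense_param_count(dense_units, N_CLASSES)
    )
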