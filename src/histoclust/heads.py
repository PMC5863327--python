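"""Decision-layer training regimes: softmax cross-entropy and the SVM head.

Two regimes are supported.  The default trains the whole network under the
softmax cross-entropy loss; the SVM regime then replaces the decision
layer by a soft-margin linear SVM fitted on the penultimate-layer feature
vectors of the trained network (features first, margin second).  An
end-to-end hinge-loss mode is also available for training the network
directly under the margin objective.

Ties are broken toward benign: equal softmax scores, or an SVM margin of
exactly zero, predict the "no disease" label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import BENIGN, MALIGNANT, LabeledDataset
from .layers import Adam, Network
from .metrics import confusion, mcc_score
from .nncore import softmax

__all__ = [
    "TrainConfig",
    "EpochHistory",
    "SvmHead",
    "train_softmax",
    "train_hinge",
    "fit_linear_svm",
    "fit_svm_head",
    "predict",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for network training."""

    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_kind: str = "adam"
    seed: int = 0
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer_kind != "adam":
            raise ValueError("only the adam optimizer is implemented")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")


@dataclass
class EpochHistory:
    """Per-epoch train/test accuracy, loss and MCC curves."""

    epoch: list[int] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    train_mcc: list[float] = field(default_factory=list)
    test_mcc: list[float] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        for key, value in kwargs.items():
            getattr(self, key).append(value)

    def __len__(self) -> int:
        return len(self.epoch)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_acc": self.train_acc,
                "test_acc": self.test_acc,
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
                "train_mcc": self.train_mcc,
                "test_mcc": self.test_mcc,
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def plot(self, path) -> Path:
        """Three-panel figure: accuracy, loss and MCC over epochs."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        panels = [
            ("Accuracy (%)", self.train_acc, self.test_acc),
            ("Loss", self.train_loss, self.test_loss),
            ("MCC", self.train_mcc, self.test_mcc),
        ]
        for ax, (title, train, test) in zip(axes, panels):
            ax.plot(self.epoch, train, label="Train")
            ax.plot(self.epoch, test, label="Test")
            ax.set_xlabel("epoch")
            ax.set_title(title)
            ax.legend()
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def _softmax_loss_and_grad(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the score matrix."""
    n = scores.shape[0]
    shifted = scores - scores.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_probs = shifted - log_z[:, None]
    loss = float(-log_probs[np.arange(n), y].mean())
    dscores = np.exp(log_probs)
    dscores[np.arange(n), y] -= 1.0
    return loss, dscores / n


def _hinge_loss_and_grad(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary hinge loss on the score margin s = F_mal − F_ben."""
    n = scores.shape[0]
    sign = np.where(y == MALIGNANT, 1.0, -1.0)
    margin = scores[:, 1] - scores[:, 0]
    slack = 1.0 - sign * margin
    loss = float(np.maximum(0.0, slack).mean())
    active = (slack > 0).astype(float) * sign / n
    dscores = np.zeros_like(scores)
    dscores[:, 1] = -active
    dscores[:, 0] = active
    return loss, dscores


def _scores_to_labels(scores: np.ndarray) -> np.ndarray:
    """Argmax with the documented tie rule: equal scores predict benign."""
    return np.where(scores[:, MALIGNANT] > scores[:, BENIGN], MALIGNANT, BENIGN)


def _eval_split(net: Network, ds: LabeledDataset, loss_fn) -> tuple[float, float, float]:
    scores = net.forward(ds.images, train=False)
    loss, _ = loss_fn(scores, ds.labels)
    preds = _scores_to_labels(softmax(scores))
    acc = 100.0 * float(np.mean(preds == ds.labels))
    mcc = mcc_score(confusion(ds.labels, preds))
    return acc, loss, mcc


def _train(net, train_ds, test_ds, cfg, loss_fn) -> tuple[Network, EpochHistory]:
    if len(train_ds) == 0 or len(test_ds) == 0:
        raise ValueError("training and test datasets must be non-empty")
    history = EpochHistory()
    if cfg.epochs == 0:
        return net, history

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(net, lr=cfg.learning_rate)
    x_train, y_train = train_ds.images, train_ds.labels
    n = len(train_ds)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            net.zero_grad()
            scores = net.forward(x_train[idx], train=True, rng=rng)
            loss, dscores = loss_fn(scores, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            net.backward(dscores)
            optimizer.step()
        tr_acc, tr_loss, tr_mcc = _eval_split(net, train_ds, loss_fn)
        te_acc, te_loss, te_mcc = _eval_split(net, test_ds, loss_fn)
        history.append(
            epoch=epoch,
            train_acc=tr_acc, test_acc=te_acc,
            train_loss=tr_loss, test_loss=te_loss,
            train_mcc=tr_mcc, test_mcc=te_mcc,
        )
    return net, history


def train_softmax(net: Network, train_ds: LabeledDataset, test_ds: LabeledDataset,
                  cfg: TrainConfig) -> tuple[Network, EpochHistory]:
    """Train under mean softmax cross-entropy by mini-batch Adam.

    Seeded and reproducible: the config seed drives batch shuffling and
    dropout masks, so identical calls give identical histories.
    """
    return _train(net, train_ds, test_ds, cfg, _softmax_loss_and_grad)


def train_hinge(net: Network, train_ds: LabeledDataset, test_ds: LabeledDataset,
                cfg: TrainConfig) -> tuple[Network, EpochHistory]:
    """End-to-end margin training: hinge loss on the decision-score margin."""
    return _train(net, train_ds, test_ds, cfg, _hinge_loss_and_grad)


@dataclass(frozen=True)
class SvmHead:
    """A fitted soft-margin linear SVM over penultimate-layer features."""

    w: np.ndarray
    b: float
    c: float

    def margin(self, features: np.ndarray) -> np.ndarray:
        return features @ self.w + self.b

    def predict(self, features: np.ndarray) -> np.ndarray:
        # margin exactly 0 falls to benign (tie rule)
        return np.where(self.margin(features) > 0, MALIGNANT, BENIGN)


def fit_linear_svm(features: np.ndarray, labels: np.ndarray, c: float = 1.0,
                   fit_intercept: bool = False) -> SvmHead:
    """Minimize the hinge objective ½‖W‖² + C·Σξ over a feature matrix.

    ``labels`` are 0/1 class labels; internally mapped to ±1 with
    malignant = +1.  By default no intercept is fitted, matching the
    plain-margin objective; ``fit_intercept=True`` adds one.
    """
    if c <= 0:
        raise ValueError("C must be positive")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("SVM head needs both classes in the training data")
    from sklearn.svm import LinearSVC

    y = np.where(labels == MALIGNANT, 1, -1)
    svc = LinearSVC(C=c, loss="hinge", fit_intercept=fit_intercept, max_iter=20000)
    svc.fit(np.asarray(features, dtype=np.float64), y)
    b = float(svc.intercept_[0]) if fit_intercept else 0.0
    return SvmHead(w=svc.coef_.ravel().copy(), b=b, c=c)


def fit_svm_head(net: Network, train_ds: LabeledDataset, c: float = 1.0,
                 fit_intercept: bool = False) -> SvmHead:
    """Fit the SVM decision head on the trained network's features.

    Extracts the penultimate-layer activation vector per training image and
    fits the soft-margin linear SVM on them (features first, margin
    second).
    """
    feats = net.penultimate_features(train_ds.images)
    return fit_linear_svm(feats, train_ds.labels, c=c, fit_intercept=fit_intercept)


def predict(net: Network, images: np.ndarray, head="softmax") -> np.ndarray:
    """Predict 0/1 labels with either decision head.

    ``head`` is the string ``"softmax"`` or a fitted :class:`SvmHead`.
    """
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if head == "softmax":
        scores = net.forward(images, train=False)
        return _scores_to_labels(softmax(scores))
    if isinstance(head, SvmHead):
        return head.predict(net.penultimate_features(images))
    raise ValueError(f"unknown decision head {head!r}")


def evaluate(net: Network, ds: LabeledDataset, head="softmax"):
    """Confusion counts and metric report for one dataset."""
    from .metrics import report

    preds = predict(net, ds.images, head=head)
    counts = confusion(ds.labels, preds)
    return counts, report(counts)
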