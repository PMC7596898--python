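"""Metrics, the shuffle/held-out split protocol, and the pipeline comparison.

Accuracy is the percentage (TP+TN)/(TP+TN+FP+FN)*100 with class 1 as the
positive class; loss is categorical cross-entropy over predicted class
probabilities.  The evaluation protocol shuffles all trials once under a
seed and holds out the last ``n_test`` (default 100 of 280) as the test
set.  ``compare_pipelines`` runs both classifiers on one epoch set:
band-pass -> CSP features -> redundant dictionary -> (a) SRC by minimum
residual, (b) sparse codes fed to the FCRes-CNN, and reports accuracy and
loss for each plus the network's per-epoch curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn
from .csp import FeatureVector, feature_matrix, fit_csp
from .io import EpochSet, bandpass
from .sparse import build_dictionary, classify_src, sparse_features

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "cross_entropy",
    "shuffle_split",
    "softmin_probabilities",
    "PipelineConfig",
    "compare_pipelines",
]


@dataclass
class ConfusionCounts:
    """Two-class confusion counts; class 1 is the positive class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 2) & (y_pred == 2))),
        FP=int(np.sum((y_true == 2) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 2))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Classification accuracy as a percentage."""
    if c.total == 0:
        raise ValueError("no samples")
    return 100.0 * (c.TP + c.TN) / c.total


def cross_entropy(y_hat: np.ndarray, y_true: np.ndarray, eps: float = 1e-12) -> float:
    """Categorical cross-entropy -(1/n) sum_ij y_ij ln(yhat_ij)."""
    y_hat = np.asarray(y_hat, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_hat.shape != y_true.shape:
        raise ValueError(f"shape mismatch {y_hat.shape} vs {y_true.shape}")
    return float(-(y_true * np.log(np.clip(y_hat, eps, 1.0))).sum() / y_hat.shape[0])


class SplitResult(NamedTuple):
    train_indices: np.ndarray
    test_indices: np.ndarray
    class_proportions: dict


def shuffle_split(n_samples: int, labels, n_test: int, seed: int) -> SplitResult:
    """Shuffle all samples under ``seed``; the last ``n_test`` become the test set.

    Class proportions of the resulting test set are reported but not
    enforced (the shuffle is unstratified, matching the protocol).
    """
    labels = np.asarray(labels, dtype=int)
    if n_test >= n_samples:
        raise ValueError(f"n_test={n_test} must be < n_samples={n_samples}")
    perm = np.random.default_rng(seed).permutation(n_samples)
    train_idx = perm[: n_samples - n_test]
    test_idx = perm[n_samples - n_test :]
    props = {}
    if n_test:
        test_labels = labels[test_idx]
        for c in np.unique(labels):
            props[int(c)] = float(np.mean(test_labels == c))
    return SplitResult(train_idx, test_idx, props)


def softmin_probabilities(residuals: np.ndarray, temperature: float = 0.1) -> np.ndarray:
    """Map per-class residuals to pseudo-probabilities via softmin.

    Gives the residual classifier a probability output so the same
    cross-entropy loss applies to both pipelines.  Smaller residual ->
    larger probability; temperature controls sharpness.
    """
    r = np.asarray(residuals, dtype=float)
    z = -r / temperature
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    out = np.zeros((labels.size, classes.size))
    for j, c in enumerate(classes):
        out[labels == c, j] = 1.0
    return out


def _atom_columns(train_labels: np.ndarray) -> list[int]:
    """Dictionary column index of each training sample (class-grouped order)."""
    train_labels = np.asarray(train_labels, dtype=int)
    cols = np.empty(train_labels.size, dtype=int)
    offset = 0
    for c in np.unique(train_labels):
        members = np.flatnonzero(train_labels == c)
        cols[members] = offset + np.arange(members.size)
        offset += members.size
    return cols.tolist()


@dataclass
class PipelineConfig:
    """Settings for the SRC vs SRC+FCRes-CNN comparison run."""

    band: tuple = (8.0, 15.0)
    n_csp_filters: int = 32
    epsilon: float | None = None  # None -> 0.01 * ||y||
    n_test: int = 100
    seed: int = 0
    leave_one_out: bool = True  # code training atoms without their own column
    src_temperature: float = 0.1
    val_fraction: float = 0.0
    cnn: dict = field(default_factory=dict)  # NetworkConfig overrides


def compare_pipelines(dataset: EpochSet, cfg: PipelineConfig | None = None) -> dict:
    """Run the SRC baseline and the SRC+FCRes-CNN pipeline on one dataset.

    Returns ``{"src": {"acc", "loss"}, "fcres": {"acc", "loss"}, "curves"}``
    where curves carries the network's per-epoch history and the (flat)
    baseline reference lines.
    """
    cfg = cfg or PipelineConfig()
    labels = dataset.labels
    if np.unique(labels).size != 2:
        raise ValueError("comparison requires a two-class dataset")

    es = bandpass(dataset, *cfg.band)
    split = shuffle_split(len(es), labels, cfg.n_test, cfg.seed)
    train_es = es.subset(split.train_indices)
    test_es = es.subset(split.test_indices)

    model = fit_csp(train_es, cfg.n_csp_filters)
    Xtr, ytr = feature_matrix(model, train_es)
    Xte, yte = feature_matrix(model, test_es)
    train_feats = [FeatureVector(v, int(l)) for v, l in zip(Xtr, ytr)]
    test_feats = [FeatureVector(v, int(l)) for v, l in zip(Xte, yte)]

    d = build_dictionary(train_feats)

    # (a) SRC baseline: minimum class residual
    src_out = classify_src(d, test_feats, epsilon=cfg.epsilon)
    src_pred = np.array([p for p, _ in src_out])
    src_resid = np.stack([r for _, r in src_out])
    src_acc = accuracy(confusion_counts(yte, src_pred))
    probs_src = softmin_probabilities(src_resid, cfg.src_temperature)
    src_loss = cross_entropy(probs_src, _one_hot(yte, d.classes))

    # (b) sparse codes -> FCRes-CNN
    exclude = _atom_columns(ytr) if cfg.leave_one_out else None
    codes_tr = sparse_features(d, train_feats, epsilon=cfg.epsilon, exclude_columns=exclude)
    codes_te = sparse_features(d, test_feats, epsilon=cfg.epsilon)

    net_cfg = nn.NetworkConfig(
        input_length=d.N, n_classes=d.k, seed=cfg.seed, **cfg.cnn
    )
    net = nn.build_network(net_cfg)
    nn.train(net, codes_tr, ytr, val_fraction=cfg.val_fraction)
    probs_te, pred_te = nn.predict(net, codes_te)
    fcres_acc = accuracy(confusion_counts(yte, pred_te))
    fcres_loss = cross_entropy(probs_te, _one_hot(yte, d.classes))

    history = net.history
    return {
        "src": {"acc": src_acc, "loss": src_loss},
        "fcres": {"acc": fcres_acc, "loss": fcres_loss},
        "curves": {
            "epoch": [h["epoch"] for h in history],
            "fcres_train_loss": [h["train_loss"] for h in history],
            "fcres_train_acc": [h["train_acc"] for h in history],
            "fcres_val_loss": [h["val_loss"] for h in history],
            "fcres_val_acc": [h["val_acc"] for h in history],
            "src_acc": [src_acc] * len(history),
            "src_loss": [src_loss] * len(history),
        },
    }


def plot_curves(report: dict, path) -> None:
    """Two-panel accuracy/loss figure comparing the network against the
    residual baseline, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = report["curves"]
    epochs = curves["epoch"]
    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_acc.plot(epochs, [100.0 * a for a in curves["fcres_train_acc"]],
                label="SRC+FCRes-CNN (train)")
    ax_acc.plot(epochs, curves["src_acc"], "--", label="SRC (held-out)")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("accuracy (%)")
    ax_acc.legend()
    ax_loss.plot(epochs, curves["fcres_train_loss"], label="SRC+FCRes-CNN (train)")
    ax_loss.plot(epochs, curves["src_loss"], "--", label="SRC (held-out)")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("cross-entropy loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
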