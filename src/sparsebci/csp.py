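"""Common spatial patterns for two-class motor-imagery EEG.

CSP finds spatial filters w maximizing the variance ratio between two
classes: with trace-normalized average class covariances C1 and C2, the
filters are the generalized eigenvectors of (C1, C1 + C2).  The eigenvalue
lambda_j in [0, 1] is the fraction of filtered variance carried by class 1;
filters from both ends of the spectrum are the discriminative ones.  The
per-epoch feature is the log of the normalized variance of each filtered
signal ("log band-power"), giving an m-dimensional vector per trial.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.linalg

from .io import Epoch, EpochSet

__all__ = ["CSPModel", "FeatureVector", "fit_csp", "csp_features", "save_csp", "load_csp"]


@dataclass
class FeatureVector:
    """m-dimensional CSP feature vector with an optional class label."""

    values: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    @property
    def m(self) -> int:
        return self.values.size


@dataclass
class CSPModel:
    """Fitted spatial filter bank.

    Attributes
    ----------
    filters : ndarray, shape (n_filters, n_channels)
        Spatial filter rows, sorted by descending class-1 eigenvalue.
    eigenvalues : ndarray, shape (n_filters,)
        Class-1 variance fraction lambda_j per filter, in [0, 1].
    log : bool
        Whether features are log-normalized variances (default) or raw
        normalized variance ratios.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    fitted_channels: int
    log: bool = True
    composite_cov: np.ndarray | None = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def patterns(self) -> np.ndarray:
        """Spatial patterns (mixing directions), one column per filter.

        With filters normalized so W Cc W' = I (Cc the composite class
        covariance), the mixing direction of filter j is column j of Cc W';
        this holds for reduced filter sets where the pseudo-inverse does not.
        """
        if self.composite_cov is not None:
            return self.composite_cov @ self.filters.T
        return np.linalg.pinv(self.filters)


def _trial_covariance(data: np.ndarray) -> np.ndarray:
    C = data @ data.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate epoch: zero total variance")
    return C / tr


def _class_covariances(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    covs: dict[int, list[np.ndarray]] = {1: [], 2: []}
    for e in es.epochs:
        covs[e.label].append(_trial_covariance(e.data))
    if not covs[1] or not covs[2]:
        raise ValueError("CSP requires two classes")
    return np.mean(covs[1], axis=0), np.mean(covs[2], axis=0)


def fit_csp(
    es: EpochSet,
    n_filters: int = 32,
    *,
    log: bool = True,
    shrinkage: float = 1e-6,
) -> CSPModel:
    """Fit CSP filters on a two-class epoch set.

    If the channel count is below ``n_filters``, all available filters are
    kept and the actual count is recorded on the model.  A small shrinkage
    ``C <- (1-g)C + g (tr(C)/ch) I`` is applied to the composite covariance
    when it is near-singular (common with many channels and few trials).
    """
    if n_filters < 2 or n_filters % 2:
        raise ValueError("n_filters must be an even integer >= 2")
    C1, C2 = _class_covariances(es)
    ch = C1.shape[0]
    Cc = C1 + C2
    if np.linalg.cond(Cc) > 1e10:
        warnings.warn(
            "composite covariance near-singular; applying shrinkage regularization",
            stacklevel=2,
        )
        mu = np.trace(Cc) / ch
        Cc = (1.0 - shrinkage) * Cc + shrinkage * mu * np.eye(ch)
        C1 = (1.0 - shrinkage) * C1 + 0.5 * shrinkage * mu * np.eye(ch)

    # eigh normalizes eigenvectors so w' Cc w = 1, i.e. w C1 w' + w C2 w' = 1
    eigvals, eigvecs = scipy.linalg.eigh(C1, Cc)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_keep = min(n_filters, ch)
    half = n_keep // 2
    idx = np.r_[np.arange(half), np.arange(ch - (n_keep - half), ch)]
    W = eigvecs[:, idx].T
    lam = np.clip(eigvals[idx], 0.0, 1.0)

    # deterministic sign: largest-magnitude coefficient of each filter positive
    for j in range(W.shape[0]):
        k = np.argmax(np.abs(W[j]))
        if W[j, k] < 0:
            W[j] = -W[j]
    return CSPModel(W, lam, fitted_channels=ch, log=log, composite_cov=Cc)


def csp_features(model: CSPModel, epoch: Epoch) -> FeatureVector:
    """Extract the normalized-variance (default: log) feature vector of one epoch."""
    if epoch.data.shape[0] != model.fitted_channels:
        raise ValueError(
            f"epoch has {epoch.data.shape[0]} channels, model fitted on "
            f"{model.fitted_channels}"
        )
    z = model.filters @ epoch.data
    v = z.var(axis=1)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate epoch: zero variance under all filters")
    p = v / total
    values = np.log(np.maximum(p, 1e-300)) if model.log else p
    return FeatureVector(values, label=epoch.label)


def feature_matrix(model: CSPModel, es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Features of every epoch as (n_epochs, m) matrix plus label vector."""
    feats = [csp_features(model, e) for e in es.epochs]
    X = np.stack([f.values for f in feats]) if feats else np.empty((0, model.n_filters))
    return X, es.labels


def save_csp(model: CSPModel, path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps(
                {
                    "filters": model.filters.tolist(),
                    "eigenvalues": model.eigenvalues.tolist(),
                    "fitted_channels": model.fitted_channels,
                    "log": model.log,
                }
            )
        )
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("filters", data=model.filters)
            f.create_dataset("eigenvalues", data=model.eigenvalues)
            f.create_dataset("fitted_channels", data=model.fitted_channels)
            f.create_dataset("log", data=int(model.log))
            if model.composite_cov is not None:
                f.create_dataset("composite_cov", data=model.composite_cov)
    return path


def load_csp(path) -> CSPModel:
    path = Path(path)
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        return CSPModel(
            np.asarray(d["filters"], dtype=float),
            np.asarray(d["eigenvalues"], dtype=float),
            int(d["fitted_channels"]),
            bool(d["log"]),
        )
    with h5py.File(path, "r") as f:
        return CSPModel(
            np.asarray(f["filters"]),
            np.asarray(f["eigenvalues"]),
            int(np.asarray(f["fitted_channels"])),
            bool(int(np.asarray(f["log"]))),
            np.asarray(f["composite_cov"]) if "composite_cov" in f else None,
        )
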