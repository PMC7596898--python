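"""Sparse-representation coding and classification (SRC).

A redundant dictionary A (m x N, m < N in the intended regime) is built by
stacking unit-normalized training feature vectors column-wise, grouped by
class.  A test feature y is coded by basis pursuit: minimize ||x||_1
subject to ||A x - y||_2 <= eps (the equality constraint relaxed by eps to
absorb noise).  Per-class residuals r_i(y) = ||y - A d_i(x)||_2, where d_i
keeps only the coefficients of class i, decide the class by minimum
residual; the full coefficient vector doubles as the input representation
for the downstream network.

The solver is FISTA (accelerated proximal gradient) on the Lagrangian form
with a per-sample penalty sweep to meet the eps constraint, followed by a
least-squares polish on the detected support.  All samples are coded in one
vectorized batch; a per-sample exclusion mask supports leave-one-column-out
coding of training samples (the proximal step of L1 plus a coordinate-zero
constraint is separable, so masking the iterate is exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .csp import FeatureVector

__all__ = [
    "Dictionary",
    "SparseCode",
    "build_dictionary",
    "solve_l1",
    "classify_src",
    "sparse_features",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class Dictionary:
    """Column-stacked training feature vectors with class provenance.

    Columns are grouped in ascending class order and L2-normalized.
    """

    A: np.ndarray
    column_classes: np.ndarray
    classes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.column_classes = np.asarray(self.column_classes, dtype=int)
        if self.A.shape[1] != self.column_classes.size:
            raise ValueError("one class id per dictionary column required")
        if self.classes is None:
            self.classes = np.unique(self.column_classes)

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[1]

    @property
    def k(self) -> int:
        return self.classes.size


@dataclass
class SparseCode:
    """Recovered coefficient vector with per-class residuals and prediction."""

    x_hat: np.ndarray
    residuals: np.ndarray  # aligned with Dictionary.classes
    predicted_class: int
    l1_norm: float
    fit_residual: float
    converged: bool = True


def build_dictionary(train_features: list[FeatureVector]) -> Dictionary:
    """Stack labeled training features into a class-grouped, unit-norm dictionary."""
    if not train_features:
        raise ValueError("no training features supplied")
    labels = np.array([f.label for f in train_features])
    if any(l is None for l in labels):
        raise ValueError("all training features must carry a class label")
    classes = np.unique(labels)
    cols, col_classes = [], []
    for c in classes:
        members = [f.values for f in train_features if f.label == c]
        if not members:
            raise ValueError(f"class {c} has zero training samples")
        cols.extend(members)
        col_classes.extend([c] * len(members))
    A = np.stack(cols, axis=1).astype(float)
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("dictionary column with zero norm")
    return Dictionary(A / norms, np.array(col_classes), classes)


# ---------------------------------------------------------------------------
# batched FISTA with penalty sweep
# ---------------------------------------------------------------------------


def _shrink(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(X) * np.maximum(np.abs(X) - t, 0.0)


def _fista(A, Y, lam, X0, max_iter, tol, mask):
    """Minimize 0.5||A x - y||^2 + lam_s ||x||_1 per column s, warm-started."""
    L = np.linalg.norm(A, 2) ** 2
    t_step = 1.0 / max(L, 1e-30)
    X = X0.copy()
    Z = X.copy()
    tk = 1.0
    AtA = A.T @ A
    AtY = A.T @ Y
    thresh = t_step * lam[None, :]
    for _ in range(max_iter):
        G = AtA @ Z - AtY
        X_new = _shrink(Z - t_step * G, thresh)
        if mask is not None:
            X_new[mask] = 0.0
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Z = X_new + ((tk - 1.0) / tk_new) * (X_new - X)
        if mask is not None:
            Z[mask] = 0.0
        delta = np.abs(X_new - X).max()
        scale = max(1.0, np.abs(X_new).max())
        X = X_new
        tk = tk_new
        if delta <= tol * scale:
            break
    return X


def _polish(A, Y, X, eps, mask):
    """Nested-support least-squares refits of each column's solution.

    Atoms are ranked by |coefficient|; for each prefix support the
    least-squares refit is a candidate.  Among feasible candidates
    (including the raw iterate) the one with the smallest L1 norm wins;
    with no feasible candidate, the smallest residual wins.  This removes
    the soft-thresholding bias near the constraint boundary.
    """
    m, S = Y.shape
    Xp = X.copy()
    for s in range(S):
        x = X[:, s]
        amax = np.abs(x).max()
        if amax == 0:
            continue
        order = np.argsort(-np.abs(x))
        order = order[np.abs(x[order]) > max(1e-10, 1e-8 * amax)]
        if mask is not None:
            order = order[~mask[order, s]]
        best = x
        best_res = np.linalg.norm(A @ x - Y[:, s])
        best_l1 = np.abs(x).sum()
        best_feasible = best_res <= eps[s]
        for j in range(1, min(order.size, m) + 1):
            support = order[:j]
            sol, *_ = np.linalg.lstsq(A[:, support], Y[:, s], rcond=None)
            cand_res = np.linalg.norm(A[:, support] @ sol - Y[:, s])
            cand_l1 = np.abs(sol).sum()
            cand_feasible = cand_res <= eps[s]
            better = (
                (cand_feasible and not best_feasible)
                or (cand_feasible and best_feasible and cand_l1 < best_l1)
                or (not cand_feasible and not best_feasible and cand_res < best_res)
            )
            if better:
                best = np.zeros_like(x)
                best[support] = sol
                best_res, best_l1, best_feasible = cand_res, cand_l1, cand_feasible
        Xp[:, s] = best
    return Xp


def _solve_batch(
    A: np.ndarray,
    Y: np.ndarray,
    eps: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-8,
    mask: np.ndarray | None = None,
    n_sweeps: int = 20,
):
    """Solve min ||x||_1 s.t. ||A x - y|| <= eps for every column of Y.

    Returns (X, converged) where converged flags per-column feasibility.
    """
    m, S = Y.shape
    N = A.shape[1]
    X = np.zeros((N, S))
    corr = np.abs(A.T @ Y)
    if mask is not None:
        corr = np.where(mask, 0.0, corr)
    lam_max = corr.max(axis=0) if N else np.zeros(S)
    lam = 0.5 * lam_max
    lam_floor = 1e-12 * np.maximum(lam_max, 1e-30)
    active = lam_max > 0
    for _ in range(n_sweeps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        sub_mask = mask[:, idx] if mask is not None else None
        X[:, idx] = _fista(A, Y[:, idx], lam[idx], X[:, idx], max_iter, tol, sub_mask)
        res = np.linalg.norm(A @ X[:, idx] - Y[:, idx], axis=0)
        feasible = res <= eps[idx]
        exhausted = lam[idx] <= lam_floor[idx]
        done = feasible | exhausted
        active[idx[done]] = False
        lam[idx[~done]] *= 0.2
    X = _polish(A, Y, X, eps, mask)
    final_res = np.linalg.norm(A @ X - Y, axis=0)
    converged = final_res <= eps + 1e-12
    return X, converged


def _default_eps(y: np.ndarray, epsilon: float | None) -> float:
    return 0.01 * np.linalg.norm(y) if epsilon is None else float(epsilon)


def _residuals(d: Dictionary, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    r = np.empty(d.k)
    for i, c in enumerate(d.classes):
        xi = np.where(d.column_classes == c, x, 0.0)
        r[i] = np.linalg.norm(y - d.A @ xi)
    return r


def solve_l1(
    d: Dictionary,
    y: FeatureVector | np.ndarray,
    epsilon: float | None = None,
    max_iter: int = 5000,
) -> SparseCode:
    """Code one feature vector against the dictionary and classify by residual.

    ``epsilon`` defaults to 0.01 * ||y||_2; epsilon = 0 is treated as an
    exact-representation request (solved to numerical tolerance).
    """
    yv = y.values if isinstance(y, FeatureVector) else np.asarray(y, dtype=float)
    if yv.size != d.m:
        raise ValueError(f"feature dimension {yv.size} != dictionary rows {d.m}")
    eps = _default_eps(yv, epsilon)
    X, conv = _solve_batch(d.A, yv[:, None], np.array([eps]), max_iter=max_iter)
    x = X[:, 0]
    if not conv[0]:
        warnings.warn("L1 solver did not reach the requested residual", stacklevel=2)
    r = _residuals(d, yv, x)
    pred = int(d.classes[int(np.argmin(r))])  # argmin ties -> lowest class index
    return SparseCode(
        x_hat=x,
        residuals=r,
        predicted_class=pred,
        l1_norm=float(np.abs(x).sum()),
        fit_residual=float(np.linalg.norm(d.A @ x - yv)),
        converged=bool(conv[0]),
    )


def _normalize_rows(Y: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Y, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return Y / safe


def classify_src(
    d: Dictionary,
    test_features: list[FeatureVector],
    epsilon: float | None = None,
    max_iter: int = 5000,
    normalize: bool = True,
) -> list[tuple[int, np.ndarray]]:
    """Classify each test feature by minimum class residual (one batch solve).

    Test vectors are unit-normalized by default, matching the dictionary
    column convention, so residuals are scale-fair across samples.
    """
    if not test_features:
        return []
    Y = np.stack([f.values for f in test_features], axis=1).astype(float)
    if Y.shape[0] != d.m:
        raise ValueError(f"feature dimension {Y.shape[0]} != dictionary rows {d.m}")
    if normalize:
        Y = _normalize_rows(Y)
    eps = np.array([_default_eps(Y[:, s], epsilon) for s in range(Y.shape[1])])
    X, _ = _solve_batch(d.A, Y, eps, max_iter=max_iter)
    out = []
    for s in range(Y.shape[1]):
        r = _residuals(d, Y[:, s], X[:, s])
        out.append((int(d.classes[int(np.argmin(r))]), r))
    return out


def sparse_features(
    d: Dictionary,
    features: list[FeatureVector],
    epsilon: float | None = None,
    max_iter: int = 5000,
    exclude_columns: list[int | None] | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Sparse codes of many features as an (n_samples, N) matrix.

    ``exclude_columns[s]`` (optional) names one dictionary column forced to
    zero while coding sample s — leave-one-column-out coding for training
    samples that are themselves dictionary atoms, so no sample is coded
    against its own perfect copy.
    """
    if not features:
        return np.empty((0, d.N))
    Y = np.stack([f.values for f in features], axis=1).astype(float)
    if Y.shape[0] != d.m:
        raise ValueError(f"feature dimension {Y.shape[0]} != dictionary rows {d.m}")
    if normalize:
        Y = _normalize_rows(Y)
    S = Y.shape[1]
    eps = np.array([_default_eps(Y[:, s], epsilon) for s in range(S)])
    mask = None
    if exclude_columns is not None:
        if len(exclude_columns) != S:
            raise ValueError("exclude_columns must have one entry per sample")
        mask = np.zeros((d.N, S), dtype=bool)
        for s, col in enumerate(exclude_columns):
            if col is not None:
                mask[col, s] = True
    X, _ = _solve_batch(d.A, Y, eps, max_iter=max_iter, mask=mask)
    return X.T


def save_dictionary(d: Dictionary, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=d.A)
        f.create_dataset("column_classes", data=d.column_classes)
    return path


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        return Dictionary(np.asarray(f["A"]), np.asarray(f["column_classes"], dtype=int))
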