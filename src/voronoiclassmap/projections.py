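"""Minimal 2-D projections (PCA, PLS-DA) and the two clustering routines used
in the clustering-failure demonstration.

PCA is a plain SVD of the (optionally autoscaled) column-centered matrix.
PLS-DA is iterative PLS2 (NIPALS) on autoscaled features against a centered
one-hot class indicator, with regression deflation. Both fix component signs
so that the largest-magnitude loading entry of each component is positive,
making score plots reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

__all__ = [
    "ProjectionResult",
    "pca_scores",
    "plsda_scores",
    "cluster_kmeans",
    "cluster_single_linkage",
]

_NIPALS_TOL = 1e-9
_NIPALS_MAX_ITER = 500


@dataclass
class ProjectionResult:
    scores: np.ndarray  # (n, 2)
    loadings: np.ndarray  # (p, 2)
    method: str  # 'pca' | 'plsda' | 'none'
    axis_names: tuple
    explained: tuple | None = None


def _as_matrix(X, min_rows: int = 1, min_cols: int = 1):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"V{j + 1}" for j in range(M.shape[1])] if M.ndim == 2 else None
    if M.ndim != 2:
        raise ValueError("feature table must be two-dimensional")
    if np.isnan(M).any():
        raise ValueError("feature table contains missing values")
    n, p = M.shape
    if n < min_rows or p < min_cols:
        raise ValueError(f"need at least {min_rows} rows and {min_cols} columns, got {n}x{p}")
    return M, names


def _autoscale(M: np.ndarray, names) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s) under autoscaling: {[names[j] for j in zero]}")
    return (M - M.mean(axis=0)) / sd


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Flip each component so its largest-|loading| entry is positive."""
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def pca_scores(X, autoscale: bool = False) -> ProjectionResult:
    """First two principal-component scores of a feature table."""
    M, names = _as_matrix(X, min_rows=3, min_cols=2)
    if autoscale:
        Mc = _autoscale(M, names)
    else:
        Mc = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    scores = U[:, :2] * s[:2]
    loadings = Vt[:2].T.copy()
    loadings, scores = _fix_signs(loadings, scores)
    total = float(np.sum(s**2))
    explained = tuple(float(s[k] ** 2) / total for k in range(2)) if total > 0 else (0.0, 0.0)
    axis_names = tuple(f"PC{k + 1} ({100 * explained[k]:.1f}%)" for k in range(2))
    return ProjectionResult(scores, loadings, "pca", axis_names, explained)


def plsda_scores(X, labels, n_comp: int = 2) -> ProjectionResult:
    """PLS-DA score plot coordinates: PLS2/NIPALS X-scores against one-hot classes.

    Features are autoscaled, the one-hot indicator is column-centered; each
    component iterates to a 1e-9 relative tolerance (max 500 iterations).
    When the class information is exhausted before ``n_comp`` components, the
    remaining directions are driven by the dominant residual feature
    structure; a fully deflated feature matrix yields zero components with a
    warning.
    """
    M, names = _as_matrix(X, min_rows=3, min_cols=1)
    y = np.asarray(labels, dtype=object)
    if len(y) != M.shape[0]:
        raise ValueError("labels length does not match number of rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("PLS-DA requires at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"each class needs at least 2 members; too small: {small}")

    Xr = _autoscale(M, names)
    total_var = float(np.sum(Xr**2))
    Y = (y[:, None] == classes[None, :]).astype(float)
    Yr = Y - Y.mean(axis=0)

    n = M.shape[0]
    T = np.zeros((n, n_comp))
    P = np.zeros((M.shape[1], n_comp))
    for a in range(n_comp):
        if float(np.sum(Xr**2)) <= 1e-12 * max(total_var, 1.0):
            warnings.warn(f"feature matrix exhausted before component {a + 1}; zero scores")
            break
        # start from the Y-residual column with the largest sum of squares
        # (deterministic); fall back to the dominant X column if Y is exhausted
        ssy = np.sum(Yr**2, axis=0)
        if ssy.max() > 1e-12:
            u = Yr[:, int(np.argmax(ssy))].copy()
        else:
            u = Xr[:, int(np.argmax(np.sum(Xr**2, axis=0)))].copy()
        t = None
        for _ in range(_NIPALS_MAX_ITER):
            w = Xr.T @ u
            nw = float(np.linalg.norm(w))
            if nw < 1e-15:
                t = np.zeros(n)
                break
            w /= nw
            t_new = Xr @ w
            q = Yr.T @ t_new / float(t_new @ t_new)
            qq = float(q @ q)
            if qq < 1e-24:
                t = t_new  # supervision exhausted; direction fixed by X alone
                break
            u = Yr @ q / qq
            if t is not None and np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        tt = float(t @ t)
        if tt <= 0:
            continue
        p_load = Xr.T @ t / tt
        q = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)
        T[:, a] = t
        P[:, a] = p_load

    T2 = T[:, :2].copy()
    P2 = P[:, :2].copy()
    P2, T2 = _fix_signs(P2, T2)
    explained = tuple(
        float(np.sum(T2[:, k] ** 2)) / total_var if total_var > 0 else 0.0 for k in range(2)
    )
    axis_names = ("Component 1", "Component 2")
    return ProjectionResult(T2, P2, "plsda", axis_names, explained)


def _check_k(X, k: int) -> np.ndarray:
    M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("X must be two-dimensional")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > M.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of points n = {M.shape[0]}")
    return M


def cluster_kmeans(X, k: int, n_restarts: int = 100, seed: int = 0) -> np.ndarray:
    """Best-inertia Lloyd k-means assignment over ``n_restarts`` seeded restarts."""
    M = _check_k(X, k)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    return km.fit_predict(M)


def cluster_single_linkage(X, k: int) -> np.ndarray:
    """Agglomerative clustering with single (minimum-distance) linkage, cut at k clusters."""
    M = _check_k(X, k)
    if k == M.shape[0]:
        return np.arange(M.shape[0])
    model = AgglomerativeClustering(n_clusters=k, linkage="single")
    return model.fit_predict(M)
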