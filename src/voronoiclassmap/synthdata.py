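"""Synthetic benchmark generators: the two-class and three-class nine-variable
tables, the label-switch and permuted variants, and an Lsun-style
three-cluster 2-D set (two bricks + one spherical cluster).

All generators are fully reproducible: the same seed yields a bit-identical
dataset. Feature columns are named A, B, C, D, E, G, H, I plus a pure-noise
column J completing the nine variables.

Construction summary (two-class, n = 80 with classes 40/40):

* A ~ N(mu_i, sigma_i^2) with (mu_1, mu_2) = (4, 8), (sigma_1, sigma_2) = (1, 1)
  — the strongest class separator.
* B ~ N(0.3 mu_1, 0.9 sigma_1^2) for class 1 and N(0.5 mu_2, 0.9 sigma_2^2)
  for class 2 — an inverse relationship between classes.
* E, G ~ Uniform(mu_i - 1 + u, mu_i + 1 + u) with a per-class jitter
  u ~ Uniform(-0.25, 0.25) — class-separated uniforms.
* C, D — weighted sampling from the integers 1..10 with weights
  proportional to position^(class index), plus N(0, 0.1) jitter — moderate
  variability with partial class overlap.
* H ~ Uniform(0, 10) for all classes; I = 0.8 H + 1 + N(0, 0.3) — a jittered
  linear transform of H; J ~ N(0, 1) — no class information in H, I, J.

The three-class variant (n = 75, classes 20/40/15) uses
(mu) = (4, 6, 8), (sigma) = (2, 4, 3) and B with means 0.5 mu_i and
variances 0.9 sigma_i^2, analogously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticDataset",
    "gen_two_class",
    "flip_labels",
    "gen_three_class",
    "permute_to_nonsignificance",
    "gen_lsun",
    "kruskal_wallis_screen",
    "write_csv",
]

FEATURE_NAMES = ["A", "B", "C", "D", "E", "G", "H", "I", "J"]


@dataclass
class SyntheticDataset:
    X: pd.DataFrame
    y: np.ndarray
    variant: str
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.X)

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _class_uniform(rng, mu, sizes):
    """Class-separated uniform: bounds mu_i +/- 1 shifted by a per-class jitter."""
    out = []
    for m, k in zip(mu, sizes):
        u = rng.uniform(-0.25, 0.25)
        out.append(rng.uniform(m - 1.0 + u, m + 1.0 + u, size=k))
    return np.concatenate(out)


def _weighted_sequential(rng, sizes):
    """Weighted draws from 1..10 with weights ~ position^(class index), jittered."""
    vals = np.arange(1, 11, dtype=float)
    out = []
    for ci, k in enumerate(sizes, start=1):
        w = vals**ci
        w = w / w.sum()
        draw = rng.choice(vals, size=k, p=w)
        out.append(draw + rng.normal(0.0, 0.1, size=k))
    return np.concatenate(out)


def _common_tail(rng, n):
    """H, I, J: no class information by construction."""
    H = rng.uniform(0.0, 10.0, size=n)
    I = 0.8 * H + 1.0 + rng.normal(0.0, 0.3, size=n)
    J = rng.normal(0.0, 1.0, size=n)
    return H, I, J


def _assemble(seed, variant, sizes, mu, sigma, b_means, b_sds):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    y = np.concatenate(
        [np.repeat(f"C{i + 1}", k) for i, k in enumerate(sizes)]
    ).astype(object)
    A = np.concatenate([rng.normal(m, s, size=k) for m, s, k in zip(mu, sigma, sizes)])
    B = np.concatenate([rng.normal(m, s, size=k) for m, s, k in zip(b_means, b_sds, sizes)])
    C = _weighted_sequential(rng, sizes)
    D = _weighted_sequential(rng, sizes)
    E = _class_uniform(rng, mu, sizes)
    G = _class_uniform(rng, mu, sizes)
    H, I, J = _common_tail(rng, n)
    X = pd.DataFrame(
        dict(zip(FEATURE_NAMES, [A, B, C, D, E, G, H, I, J]))
    )
    return SyntheticDataset(X=X, y=y, variant=variant, seed=seed, meta={"y_true": y.copy()})


def gen_two_class(seed: int = 0) -> SyntheticDataset:
    """Two-class benchmark: n = 80 cases (40/40), nine variables."""
    mu = (4.0, 8.0)
    sigma = (1.0, 1.0)
    b_means = (0.3 * mu[0], 0.5 * mu[1])
    b_sds = (np.sqrt(0.9) * sigma[0], np.sqrt(0.9) * sigma[1])
    return _assemble(seed, "two_class", (40, 40), mu, sigma, b_means, b_sds)


def gen_three_class(seed: int = 0) -> SyntheticDataset:
    """Three-class benchmark: n = 75 cases (20/40/15), nine variables."""
    mu = (4.0, 6.0, 8.0)
    sigma = (2.0, 4.0, 3.0)
    # B uses scaled versions of A's parameters: both the mean and the spread
    # are halved (with the same 0.9 variance shrink as the two-class set), so
    # B stays a reliable, if weaker, class separator.
    b_means = tuple(0.5 * m for m in mu)
    b_sds = tuple(0.5 * np.sqrt(0.9) * s for s in sigma)
    return _assemble(seed, "three_class", (20, 40, 15), mu, sigma, b_means, b_sds)


def flip_labels(ds: SyntheticDataset, k_per_class: int = 3, seed: int = 0) -> SyntheticDataset:
    """Reassign ``k_per_class`` uniformly chosen cases per class to the opposite class.

    Selection is made on the generator's original class structure (kept in
    metadata), so flipping twice with the same seed restores the original
    labels exactly. Features are untouched; the indices whose current label
    differs from the original are recorded in ``meta['flipped_indices']``.
    """
    y_true = np.asarray(ds.meta.get("y_true", ds.y), dtype=object)
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("flip_labels requires a two-class dataset")
    min_size = min(int(np.sum(y_true == c)) for c in classes)
    if k_per_class < 0 or k_per_class > min_size:
        raise ValueError(f"k_per_class must be in [0, {min_size}], got {k_per_class}")

    rng = np.random.default_rng(seed)
    other = {classes[0]: classes[1], classes[1]: classes[0]}
    y_new = ds.y.copy()
    chosen = []
    for c in classes:
        members = np.flatnonzero(y_true == c)
        pick = rng.choice(members, size=k_per_class, replace=False)
        chosen.extend(int(i) for i in pick)
    for i in chosen:
        y_new[i] = other[y_new[i]]

    meta = dict(ds.meta)
    meta["y_true"] = y_true.copy()
    meta["flipped_indices"] = sorted(int(i) for i in np.flatnonzero(y_new != y_true))
    return SyntheticDataset(
        X=ds.X.copy(), y=y_new, variant=f"{ds.variant}_switched", seed=seed, meta=meta
    )


def kruskal_wallis_screen(data, labels=None) -> pd.DataFrame:
    """Tie-corrected Kruskal–Wallis statistic and chi-squared p-value per column.

    Accepts a SyntheticDataset or a (feature table, labels) pair. A constant
    column yields p = 1 with a warning.
    """
    if isinstance(data, SyntheticDataset):
        X, y = data.X, data.y
    else:
        X, y = data, np.asarray(labels, dtype=object)
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 classes")
    rows = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        groups = [v[y == c] for c in classes]
        if np.all(v == v[0]):
            warnings.warn(f"column {col!r} is constant; p set to 1")
            rows[col] = (0.0, 1.0)
            continue
        h, p = stats.kruskal(*groups)
        rows[col] = (float(h), float(p))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["statistic", "pvalue"])


def permute_to_nonsignificance(
    ds: SyntheticDataset, alpha: float = 0.05, max_iter: int = 100, seed: int = 0
) -> SyntheticDataset:
    """Independently permute each variable until no column is class-associated.

    Each column is re-permuted until its Kruskal–Wallis p-value exceeds
    ``alpha`` (rejection resampling), so the output is guaranteed to have all
    per-variable p-values above the threshold while every column keeps its
    original multiset of values and the class vector is unchanged.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(ds.y)
    X_new = ds.X.copy()
    for col in ds.X.columns:
        v = ds.X[col].to_numpy(dtype=float)
        ok = False
        for _ in range(max_iter):
            perm = rng.permutation(v)
            groups = [perm[ds.y == c] for c in classes]
            _, p = stats.kruskal(*groups)
            if p > alpha:
                X_new[col] = perm
                ok = True
                break
        if not ok:
            raise RuntimeError(f"column {col!r}: no permutation with p > {alpha} in {max_iter} tries")
    meta = dict(ds.meta)
    meta["alpha"] = alpha
    return SyntheticDataset(
        X=X_new, y=ds.y.copy(), variant=f"{ds.variant}_permuted", seed=seed, meta=meta
    )


def gen_lsun(seed: int = 0) -> SyntheticDataset:
    """Lsun-style 2-D set: 400 points in three well-separated classes.

    Two axis-aligned uniform rectangles of different sizes form an "L"
    (150 points each) and a truncated isotropic Gaussian forms a spherical
    cluster (100 points). Inter-class gaps are at least half the smallest
    rectangle side, so single-linkage clustering recovers the classes while
    the elongated bricks defeat k-means' spherical-cluster assumption.
    """
    rng = np.random.default_rng(seed)
    n1, n2, n3 = 150, 150, 100
    # vertical brick: 1 x 4
    r1 = np.column_stack([rng.uniform(0.0, 1.0, n1), rng.uniform(0.0, 4.0, n1)])
    # horizontal brick: 3 x 1, separated from the vertical brick by a 0.5 gap
    r2 = np.column_stack([rng.uniform(0.0, 3.0, n2), rng.uniform(-1.5, -0.5, n2)])
    # spherical cluster: isotropic Gaussian truncated at radius 1
    center = np.array([2.8, 2.5])
    pts = []
    while len(pts) < n3:
        cand = rng.normal(0.0, 0.35, size=(n3, 2))
        keep = cand[np.hypot(cand[:, 0], cand[:, 1]) <= 1.0]
        pts.extend(keep.tolist())
    r3 = center + np.asarray(pts[:n3])
    X = pd.DataFrame(np.vstack([r1, r2, r3]), columns=["x", "y"])
    y = np.concatenate(
        [np.repeat("C1", n1), np.repeat("C2", n2), np.repeat("C3", n3)]
    ).astype(object)
    return SyntheticDataset(X=X, y=y, variant="lsun", seed=seed, meta={"y_true": y.copy()})


def write_csv(ds: SyntheticDataset, path) -> None:
    """Write the dataset as CSV with a 'class' column appended."""
    out = ds.X.copy()
    out["class"] = ds.y
    out.to_csv(path, index=False)
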