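"""Per-group bivariate confidence ellipses.

The ellipse for a group with mean mu and covariance Sigma is the set
{x : (x - mu)' Sigma^{-1} (x - mu) <= c}, with c the chi-squared (df = 2)
quantile at the chosen confidence level. By default this is a *data*
ellipse (sample covariance, region for observations); a mean-confidence
variant (Sigma / n) is available via ``kind='mean'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EllipseSpec", "chi2_threshold", "fit_ellipse", "in_ellipse", "ellipse_polygon"]

_REL_TOL = 1e-9


def chi2_threshold(level: float) -> float:
    """Chi-squared (df = 2) quantile; equals -2 ln(1 - level)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(stats.chi2.ppf(level, df=2))


@dataclass
class EllipseSpec:
    group: object
    mean: np.ndarray
    cov: np.ndarray
    level: float
    threshold: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths sqrt(c * lambda_k), descending."""
        lam = np.linalg.eigvalsh(self.cov)[::-1]
        return np.sqrt(self.threshold * lam)

    @property
    def axes_directions(self) -> np.ndarray:
        """Unit eigenvectors (columns), matching ``semi_axes`` order."""
        lam, vec = np.linalg.eigh(self.cov)
        return vec[:, ::-1]


def fit_ellipse(points, level: float = 0.95, group=None, kind: str = "data") -> EllipseSpec | None:
    """Fit a group's confidence ellipse from its 2-D points.

    Returns None (with a warning) for groups with fewer than 3 points or a
    singular covariance, so a plot can proceed without the ellipse.
    ``kind='data'`` covers observations; ``kind='mean'`` divides the
    covariance by n to cover the group mean instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        warnings.warn(f"group {group!r}: fewer than 3 points, ellipse omitted")
        return None
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(cov)
    if lam.min() <= 1e-12 * max(lam.max(), 1.0):
        warnings.warn(f"group {group!r}: singular covariance (collinear points), ellipse omitted")
        return None
    if kind == "mean":
        cov = cov / n
    elif kind != "data":
        raise ValueError("kind must be 'data' or 'mean'")
    return EllipseSpec(group=group, mean=mean, cov=cov, level=level, threshold=chi2_threshold(level))


def in_ellipse(spec: EllipseSpec, x) -> bool:
    """True iff the squared Mahalanobis distance of x from the mean is <= c (closed region)."""
    x = np.asarray(x, dtype=float).reshape(2)
    diff = x - spec.mean
    m2 = float(diff @ np.linalg.solve(spec.cov, diff))
    return m2 <= spec.threshold * (1.0 + _REL_TOL) + _REL_TOL


def ellipse_polygon(spec: EllipseSpec, n_vertices: int = 100) -> np.ndarray:
    """Closed ring of boundary points mu + sqrt(c) * Sigma^{1/2} (cos t, sin t)."""
    if n_vertices < 4:
        raise ValueError("n_vertices must be >= 4")
    lam, vec = np.linalg.eigh(spec.cov)
    sqrt_cov = vec @ np.diag(np.sqrt(lam)) @ vec.T  # symmetric matrix square root
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return spec.mean + np.sqrt(spec.threshold) * circle @ sqrt_cov.T
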