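"""Reproducible benchmark pipelines composed from the library modules.

These are the end-to-end experiments the synthetic generators exist for:
the label-switch island experiment (flip a few labels in a well-separated
two-class set, project with PLS-DA, count Voronoi islands) and the
Lsun-style clustering contrast (single linkage succeeds where k-means'
spherical-cluster assumption fails).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .geometry import PointSet2D, neighbor_graph, tessellate
from .islands import find_islands
from .projections import cluster_kmeans, cluster_single_linkage, plsda_scores
from .synthdata import flip_labels, gen_lsun, gen_two_class

__all__ = ["label_switch_island_trial", "lsun_clustering_trial", "derive_seed"]

_MOD = 2**31


def derive_seed(base: int, stream: int, index: int = 0) -> int:
    """Deterministic child seed below 2**31 for replicate ``index`` of ``stream``."""
    return (base * 1_000_003 + stream * 7_919 + index) % _MOD


def label_switch_island_trial(seed: int, k_per_class: int = 3) -> dict:
    """One replicate of the label-switch island experiment.

    Generates the two-class benchmark, flips ``k_per_class`` labels per
    class, computes two-component PLS-DA scores using the modified labels,
    tessellates the score plane and detects Voronoi islands under the same
    modified labels.
    """
    ds = gen_two_class(derive_seed(seed, 1))
    flipped = flip_labels(ds, k_per_class=k_per_class, seed=derive_seed(seed, 2))
    proj = plsda_scores(flipped.X, flipped.y)
    points = PointSet2D(proj.scores)
    tess = tessellate(points)
    graph = neighbor_graph(points, tess)
    report = find_islands(graph, flipped.y)
    flipped_set = set(flipped.meta["flipped_indices"])
    return {
        "count": report.count,
        "rate": report.rate,
        "islands": list(report.islands),
        "flipped": sorted(flipped_set),
        "islands_subset_of_flipped": set(report.islands) <= flipped_set,
    }


def lsun_clustering_trial(seed: int, n_restarts: int = 100) -> dict:
    """One replicate of the clustering contrast on the Lsun-style dataset."""
    ds = gen_lsun(derive_seed(seed, 3))
    X = ds.X.to_numpy()
    km = cluster_kmeans(X, k=3, n_restarts=n_restarts, seed=derive_seed(seed, 4))
    sl = cluster_single_linkage(X, k=3)
    return {
        "ari_kmeans": float(adjusted_rand_score(ds.y, km)),
        "ari_single": float(adjusted_rand_score(ds.y, sl)),
    }
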