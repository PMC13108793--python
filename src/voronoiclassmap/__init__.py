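"""Voronoi class maps for 2-D projections of biomedical data.

Tessellates the projection plane into per-case Voronoi cells colored by
class ("political map" view), detects *Voronoi islands* — cases whose every
Voronoi neighbor belongs to another class — as a visualization-intrinsic
discordance metric, and draws the classic confidence-ellipse scatter plots
alongside. Ships minimal PCA / PLS-DA projections, k-means and
single-linkage clustering wrappers, and fully seeded synthetic benchmark
generators so every demonstration runs without external data.
"""

from .ellipses import EllipseSpec, chi2_threshold, ellipse_polygon, fit_ellipse, in_ellipse
from .geometry import (
    NeighborGraph,
    PointSet2D,
    Tessellation,
    Window,
    compute_window,
    locate,
    neighbor_graph,
    tessellate,
)
from .islands import ClassLabels, IslandReport, find_islands, island_rate_percent, subtitle_text
from .projections import (
    ProjectionResult,
    cluster_kmeans,
    cluster_single_linkage,
    pca_scores,
    plsda_scores,
)
from .synthdata import (
    SyntheticDataset,
    flip_labels,
    gen_lsun,
    gen_three_class,
    gen_two_class,
    kruskal_wallis_screen,
    permute_to_nonsignificance,
    write_csv,
)
from .viz import (
    OKABE_ITO,
    PlotBundle,
    PlotParams,
    create_tessellation_plots,
    create_voronoi_plot,
    place_labels,
    resolve_palette,
    save_figure,
)

__version__ = "0.1.0"

__all__ = [
    "PointSet2D",
    "Window",
    "Tessellation",
    "NeighborGraph",
    "compute_window",
    "tessellate",
    "neighbor_graph",
    "locate",
    "ClassLabels",
    "IslandReport",
    "find_islands",
    "island_rate_percent",
    "subtitle_text",
    "EllipseSpec",
    "chi2_threshold",
    "fit_ellipse",
    "in_ellipse",
    "ellipse_polygon",
    "ProjectionResult",
    "pca_scores",
    "plsda_scores",
    "cluster_kmeans",
    "cluster_single_linkage",
    "SyntheticDataset",
    "gen_two_class",
    "gen_three_class",
    "gen_lsun",
    "flip_labels",
    "permute_to_nonsignificance",
    "kruskal_wallis_screen",
    "write_csv",
    "PlotParams",
    "PlotBundle",
    "OKABE_ITO",
    "resolve_palette",
    "place_labels",
    "create_voronoi_plot",
    "create_tessellation_plots",
    "save_figure",
    "__version__",
]
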