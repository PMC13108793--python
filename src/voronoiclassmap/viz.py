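"""Class-map plotting: confidence-ellipse scatter, Voronoi tessellation, and
the combined view, with dual class coloring and the island subtitle.

The Voronoi panel works like a political map: each case's clipped cell is
filled by its class color (``fill_voronoi`` classification) with the points
overlaid, optionally colored by a different classification
(``color_points``) — e.g. prior classes as points over clustering results as
cells. When ``show_island_count`` is on, the island count/rate subtitle is
computed on the SAME classification that fills the cells, so the metric
describes the tessellation the viewer sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection
from matplotlib.colors import to_rgb
from matplotlib.lines import Line2D

from .ellipses import ellipse_polygon, fit_ellipse
from .geometry import PointSet2D, compute_window, neighbor_graph, tessellate
from .islands import ClassLabels, find_islands, subtitle_text

__all__ = [
    "PlotParams",
    "PlotBundle",
    "OKABE_ITO",
    "resolve_palette",
    "place_labels",
    "create_voronoi_plot",
    "create_tessellation_plots",
    "save_figure",
]

# Colorblind-safe default cycle (Okabe-Ito), in this fixed documented order.
OKABE_ITO = [
    "#E69F00",  # orange
    "#56B4E9",  # sky blue
    "#009E73",  # bluish green
    "#F0E442",  # yellow
    "#0072B2",  # blue
    "#D55E00",  # vermillion
    "#CC79A7",  # reddish purple
    "#999999",  # grey
]

_TAGS = ("primary", "alternative")
_SHAPE_TAGS = ("primary", "alternative", "none")
_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*"]


@dataclass
class PlotParams:
    """Plot options mirroring the class-map function-call parameters."""

    show_labels: bool = False
    voronoi_alpha: float = 0.3
    ellipse_alpha: float = 0.1
    point_size: float = 2.0
    legend_position: str = "bottom"
    color_points: str = "primary"
    fill_voronoi: str = "primary"
    point_shape: str = "none"
    label_fontface: str = "plain"
    label_size: float = 3.88
    show_island_count: bool = False
    label_islands_only: bool = False
    coord_names: tuple = ("Dim1", "Dim2")
    title: str | None = None
    add_grid_lines: bool = False
    color_palette: list | None = None
    margin_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("voronoi_alpha", "ellipse_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.color_points not in _TAGS:
            raise ValueError(f"color_points must be one of {_TAGS}")
        if self.fill_voronoi not in _TAGS:
            raise ValueError(f"fill_voronoi must be one of {_TAGS}")
        if self.point_shape not in _SHAPE_TAGS:
            raise ValueError(f"point_shape must be one of {_SHAPE_TAGS}")
        if self.label_islands_only and not self.show_island_count:
            raise ValueError("label_islands_only requires show_island_count")
        if len(self.coord_names) != 2:
            raise ValueError("coord_names must hold exactly 2 axis names")


@dataclass
class PlotBundle:
    scatter_plot: plt.Figure
    voronoi_plot: plt.Figure
    combined_plot: plt.Figure
    island_report: object = None
    figures: dict = field(default_factory=dict)


def _lighten(color: str, blend: float) -> str:
    r, g, b = to_rgb(color)
    r, g, b = (v + (1.0 - v) * blend for v in (r, g, b))
    return matplotlib.colors.to_hex((r, g, b))


def resolve_palette(n_classes: int, custom=None) -> list:
    """First n colors of the fixed colorblind-safe cycle, or a custom palette.

    Beyond 8 classes the cycle recycles deterministically with each full
    cycle lightened toward white by an additional 30% (capped at 80%).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if custom is not None:
        custom = list(custom)
        if len(custom) < n_classes:
            raise ValueError(
                f"custom palette has {len(custom)} colors but {n_classes} classes are displayed"
            )
        return custom[:n_classes]
    out = []
    for i in range(n_classes):
        cycle = i // len(OKABE_ITO)
        base = OKABE_ITO[i % len(OKABE_ITO)]
        out.append(base if cycle == 0 else _lighten(base, min(0.3 * cycle, 0.8)))
    return out


def _classes_in_order(labels: np.ndarray) -> list:
    """Distinct labels ordered by first appearance."""
    seen, out = set(), []
    for v in labels:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def place_labels(points, case_ids, which: str = "all", island_report=None, texts=None):
    """Greedy label placement with radial offsetting.

    Returns a list of (x, y, text) triples. Empty-string labels are
    suppressed; ``which='islands_only'`` keeps labels only for the island
    cases of ``island_report``.
    """
    coords = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(coords)
    if texts is None:
        texts = [str(c) for c in case_ids]
    if which == "islands_only":
        if island_report is None:
            raise ValueError("islands_only labelling requires an island report")
        keep = set(island_report.islands)
    elif which == "all":
        keep = set(range(n))
    else:
        raise ValueError("which must be 'all' or 'islands_only'")

    span = coords.max(axis=0) - coords.min(axis=0) if n > 1 else np.ones(2)
    scale = float(max(span.max(), 1e-12))
    base_r = 0.02 * scale
    min_sep = 0.04 * scale
    placed: list[tuple[float, float, str]] = []
    angles = np.deg2rad([45, 135, 225, 315, 0, 90, 180, 270])
    for i in range(n):
        if i not in keep or texts[i] == "":
            continue
        pos = None
        for ring in range(1, 6):
            r = base_r * ring
            for ang in angles:
                cand = coords[i] + r * np.array([np.cos(ang), np.sin(ang)])
                if all(np.hypot(cand[0] - x, cand[1] - y) >= min_sep for x, y, _ in placed):
                    pos = cand
                    break
            if pos is not None:
                break
        if pos is None:  # crowded: accept overlap rather than drop the label
            pos = coords[i] + base_r
        placed.append((float(pos[0]), float(pos[1]), texts[i]))
    return placed


def _normalize_inputs(points, labels):
    if not isinstance(points, PointSet2D):
        points = PointSet2D(points)
    if labels is None:
        labels = ClassLabels(primary=np.repeat("all", points.n))
        implicit = True
    else:
        if not isinstance(labels, ClassLabels):
            labels = ClassLabels(primary=labels)
        implicit = False
    if labels.n != points.n:
        raise ValueError("labels length does not match number of points")
    return points, labels, implicit


def _color_map(labels_vec, palette):
    classes = _classes_in_order(labels_vec)
    colors = resolve_palette(len(classes), palette)
    return classes, dict(zip(classes, colors))


def _legend(ax, classes, cmap, position, title=None):
    handles = [
        Line2D([], [], marker="o", linestyle="", color=cmap[c], label=str(c)) for c in classes
    ]
    loc = {
        "bottom": ("upper center", (0.5, -0.12), len(classes)),
        "top": ("lower center", (0.5, 1.12), len(classes)),
        "right": ("center left", (1.02, 0.5), 1),
        "left": ("center right", (-0.02, 0.5), 1),
    }.get(position, ("upper center", (0.5, -0.12), len(classes)))
    ax.legend(
        handles=handles,
        loc=loc[0],
        bbox_to_anchor=loc[1],
        ncols=loc[2],
        frameon=False,
        title=title,
    )


def _scatter_points(ax, points, labels, params, implicit):
    vec = labels.get(params.color_points) if not implicit else labels.primary
    classes, cmap = _color_map(vec, params.color_palette)
    s = (params.point_size * 3.0) ** 2  # ggplot-like mm size -> matplotlib pt^2 area
    if params.point_shape != "none" and not implicit:
        shape_vec = labels.get(params.point_shape)
        shape_classes = _classes_in_order(shape_vec)
        markers = {c: _MARKERS[i % len(_MARKERS)] for i, c in enumerate(shape_classes)}
    else:
        shape_vec = None
    for c in classes:
        idx = np.flatnonzero(vec == c)
        if shape_vec is None:
            ax.scatter(
                points.coords[idx, 0], points.coords[idx, 1], s=s, color=cmap[c],
                edgecolors="white", linewidths=0.4, zorder=3,
            )
        else:
            for i in idx:
                ax.scatter(
                    points.coords[i, 0], points.coords[i, 1], s=s, color=cmap[c],
                    marker=markers[shape_vec[i]], edgecolors="white", linewidths=0.4, zorder=3,
                )
    return classes, cmap


def _draw_ellipses(ax, points, labels, params, implicit):
    vec = labels.get(params.color_points) if not implicit else labels.primary
    classes, cmap = _color_map(vec, params.color_palette)
    for c in classes:
        pts = points.coords[vec == c]
        spec = fit_ellipse(pts, level=0.95, group=c)
        if spec is None:
            continue
        ring = ellipse_polygon(spec, n_vertices=200)
        ax.fill(ring[:, 0], ring[:, 1], color=cmap[c], alpha=params.ellipse_alpha, zorder=1)
        ax.plot(
            np.append(ring[:, 0], ring[0, 0]), np.append(ring[:, 1], ring[0, 1]),
            color=cmap[c], linewidth=1.0, zorder=2,
        )


def _style_axes(ax, window, params):
    ax.set_xlim(window.xmin, window.xmax)
    ax.set_ylim(window.ymin, window.ymax)
    ax.set_xlabel(params.coord_names[0])
    ax.set_ylabel(params.coord_names[1])
    if params.add_grid_lines:
        ax.axhline(0.0, color="grey", linewidth=0.6, zorder=0)
        ax.axvline(0.0, color="grey", linewidth=0.6, zorder=0)


def _fontface(face):
    weight = "bold" if "bold" in face else "normal"
    style = "italic" if "italic" in face else "normal"
    return weight, style


def _add_labels(ax, points, params, island_report):
    which = "islands_only" if params.label_islands_only else "all"
    if which == "all" and not params.show_labels:
        return
    placements = place_labels(
        points.coords, points.case_ids, which=which, island_report=island_report
    )
    weight, style = _fontface(params.label_fontface)
    for x, y, text in placements:
        ax.annotate(
            text, (x, y), fontsize=params.label_size * 2.2,
            fontweight=weight, fontstyle=style, zorder=5,
        )


def _voronoi_layer(ax, points, labels, params, implicit, tess):
    vec = labels.get(params.fill_voronoi) if not implicit else labels.primary
    classes, cmap = _color_map(vec, params.color_palette)
    face = [cmap[vec[i]] for i in range(points.n)]
    coll = PolyCollection(
        [c for c in tess.cells if len(c) >= 3],
        facecolors=face,
        alpha=params.voronoi_alpha,
        edgecolors="#666666",
        linewidths=0.5,
        zorder=1,
    )
    ax.add_collection(coll)
    return classes, cmap


def _island_report(points, labels, params, tess):
    graph = neighbor_graph(points, tess)
    return find_islands(graph, labels, which=params.fill_voronoi, case_ids=points.case_ids)


def _new_fig(params, subtitle=None):
    fig, ax = plt.subplots(figsize=(6.5, 6.0), constrained_layout=True)
    if params.title:
        fig.suptitle(params.title)
    if subtitle:
        ax.set_title(subtitle, fontsize=10, loc="left")
    return fig, ax


def create_voronoi_plot(points, labels=None, params: PlotParams | None = None):
    """The colored Voronoi-cell class map (single figure)."""
    params = params or PlotParams()
    points, labels, implicit = _normalize_inputs(points, labels)
    window = compute_window(points, params.margin_frac)
    tess = tessellate(points, window)

    report = None
    subtitle = None
    if params.show_island_count and not implicit:
        report = _island_report(points, labels, params, tess)
        subtitle = subtitle_text(report)

    fig, ax = _new_fig(params, subtitle)
    fill_classes, fill_cmap = _voronoi_layer(ax, points, labels, params, implicit, tess)
    _scatter_points(ax, points, labels, params, implicit)
    _style_axes(ax, window, params)
    if not implicit:
        _legend(ax, fill_classes, fill_cmap, params.legend_position)
    _add_labels(ax, points, params, report)
    fig._island_report = report
    return fig


def create_tessellation_plots(points, labels=None, params: PlotParams | None = None) -> PlotBundle:
    """The three class-map views: ellipse scatter, Voronoi map, and combined.

    All three figures share the window, axis names, palette and legend
    content; the island subtitle (when requested) appears on the panels that
    show the tessellation and is computed with the ``fill_voronoi``
    classification.
    """
    params = params or PlotParams()
    points, labels, implicit = _normalize_inputs(points, labels)
    window = compute_window(points, params.margin_frac)
    tess = tessellate(points, window)

    report = None
    subtitle = None
    if params.show_island_count and not implicit:
        report = _island_report(points, labels, params, tess)
        subtitle = subtitle_text(report)

    # scatter + ellipses
    fig_s, ax = _new_fig(params)
    _draw_ellipses(ax, points, labels, params, implicit)
    classes, cmap = _scatter_points(ax, points, labels, params, implicit)
    _style_axes(ax, window, params)
    if not implicit:
        _legend(ax, classes, cmap, params.legend_position)
    if params.show_labels and not params.label_islands_only:
        _add_labels(ax, points, params, report)

    # voronoi
    fig_v, ax = _new_fig(params, subtitle)
    fill_classes, fill_cmap = _voronoi_layer(ax, points, labels, params, implicit, tess)
    _scatter_points(ax, points, labels, params, implicit)
    _style_axes(ax, window, params)
    if not implicit:
        _legend(ax, fill_classes, fill_cmap, params.legend_position)
    _add_labels(ax, points, params, report)

    # combined
    fig_c, ax = _new_fig(params, subtitle)
    _voronoi_layer(ax, points, labels, params, implicit, tess)
    _draw_ellipses(ax, points, labels, params, implicit)
    _scatter_points(ax, points, labels, params, implicit)
    _style_axes(ax, window, params)
    if not implicit:
        _legend(ax, fill_classes, fill_cmap, params.legend_position)
    _add_labels(ax, points, params, report)

    return PlotBundle(
        scatter_plot=fig_s,
        voronoi_plot=fig_v,
        combined_plot=fig_c,
        island_report=report,
        figures={"scatter": fig_s, "voronoi": fig_v, "combined": fig_c},
    )


def save_figure(fig, path, width: float = 6.5, height: float = 6.0, dpi: int = 150):
    """Export a figure as PNG, SVG or PDF depending on the path's extension."""
    fig.set_size_inches(width, height)
    fig.savefig(path, dpi=dpi)
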