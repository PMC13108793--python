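"""Voronoi islands: the visualization-intrinsic class-discordance metric.

A point is a *Voronoi island* when it has at least one Voronoi neighbor and
every one of its neighbors carries a class label different from its own —
the strongest local signal of class discordance visible in the tessellation.
The metric is summarized as an island count and an island rate (islands / n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .geometry import NeighborGraph

__all__ = [
    "ClassLabels",
    "IslandReport",
    "find_islands",
    "island_rate_percent",
    "subtitle_text",
]


def _as_label_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} labels must be one-dimensional")
    missing = [
        i + 1
        for i, v in enumerate(arr)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == ""
    ]
    if missing:
        raise ValueError(f"missing {name} class labels in rows {missing}")
    return arr


@dataclass
class ClassLabels:
    """Primary (and optionally alternative) categorical labels for n points."""

    primary: np.ndarray
    alternative: np.ndarray | None = None

    def __post_init__(self):
        self.primary = _as_label_array(self.primary, "primary")
        if self.alternative is not None:
            self.alternative = _as_label_array(self.alternative, "alternative")
            if len(self.alternative) != len(self.primary):
                raise ValueError("primary and alternative label lengths differ")

    @property
    def n(self) -> int:
        return len(self.primary)

    def get(self, which: str) -> np.ndarray:
        if which == "primary":
            return self.primary
        if which == "alternative":
            if self.alternative is None:
                raise ValueError("alternative labels requested but none provided")
            return self.alternative
        raise ValueError(f"unknown label selector {which!r} (use 'primary' or 'alternative')")


@dataclass
class IslandReport:
    islands: list  # point indices, sorted
    count: int
    rate: float
    labels_used: str
    n: int
    island_case_ids: list

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "labels_used": self.labels_used,
            "islands": list(self.island_case_ids),
            "count": self.count,
            "rate": self.rate,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def find_islands(
    graph: NeighborGraph,
    labels: ClassLabels | np.ndarray,
    which: str = "primary",
    case_ids=None,
) -> IslandReport:
    """Detect Voronoi islands on a neighbor graph under the chosen classification.

    ``which`` must mirror the classification that fills the Voronoi cells in
    the plot, so the reported metric describes the tessellation the viewer
    actually sees.
    """
    if not isinstance(labels, ClassLabels):
        labels = ClassLabels(primary=labels)
    lab = labels.get(which)
    n = graph.n
    if len(lab) != n:
        raise ValueError(f"labels length {len(lab)} does not match graph size {n}")
    if case_ids is None:
        case_ids = list(range(1, n + 1))

    islands = []
    for i in range(n):
        nbrs = graph.neighbors(i)
        if nbrs and all(lab[j] != lab[i] for j in nbrs):
            islands.append(i)
    count = len(islands)
    rate = count / n if n else 0.0
    return IslandReport(
        islands=islands,
        count=count,
        rate=rate,
        labels_used=which,
        n=n,
        island_case_ids=[case_ids[i] for i in islands],
    )


def _percent_half_up(count: int, n: int) -> str:
    """count/n as a percentage, rounded half-up to one decimal place."""
    if n == 0:
        return "0.0"
    pct = (Decimal(count) * 100 / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return str(pct)


def island_rate_percent(report: IslandReport) -> str:
    """Island rate as text, e.g. '5.0%' for 4 islands among 80 cells."""
    return f"{_percent_half_up(report.count, report.n)}%"


def subtitle_text(report: IslandReport) -> str:
    """Plot subtitle: 'Voronoi islands: {count} ({rate%})'."""
    return f"Voronoi islands: {report.count} ({island_rate_percent(report)})"
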