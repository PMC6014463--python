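"""Per-cell signal extraction: spots -> clusters -> counts and fusions.

Spots of one cell are joined into clusters by single-linkage: two spots are
connected when their distance is at most ``fusion_radius`` (closed ball, so
ties at exactly the radius merge — deterministic on exact-coordinate
fixtures), and clusters are the connected components of that graph.
Same-color spots inside one cluster count as a single signal (this is what
re-absorbs split signals); a cluster containing two or more distinct colors
is one fusion (juxtaposition) event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .panel import Color

__all__ = ["SpotCluster", "CellPattern", "extract_cell_pattern", "extract_patterns"]


@dataclass(frozen=True)
class SpotCluster:
    colors: tuple[Color, ...]  # distinct colors, sorted by name
    centroid: tuple[float, float]
    n_spots: int

    @property
    def is_fusion(self) -> bool:
        return len(self.colors) >= 2


@dataclass
class CellPattern:
    """One cell's extracted signal multiset."""

    cell_id: int
    color_counts: dict[Color, int]
    fusions: Counter  # Counter[frozenset[Color]]
    clusters: list[SpotCluster] = field(default_factory=list)

    def count(self, color: Color) -> int:
        return self.color_counts.get(color, 0)

    def has_fusion(self, pair: frozenset) -> bool:
        return any(pair <= colors for colors in self.fusions)


def extract_cell_pattern(spots, fusion_radius: float, cell_id: int = 0) -> CellPattern:
    """Cluster one cell's spots.

    ``spots`` is a sequence of ``(color, x, y)`` triples or a DataFrame with
    ``color``, ``x``, ``y`` columns.  An empty input yields an empty pattern.
    """
    if fusion_radius < 0:
        raise ValueError("fusion_radius must be non-negative")
    if isinstance(spots, pd.DataFrame):
        triples = [
            (Color(c), float(x), float(y))
            for c, x, y in zip(spots["color"], spots["x"], spots["y"])
        ]
    else:
        triples = [(Color(c), float(x), float(y)) for c, x, y in spots]

    if not triples:
        return CellPattern(cell_id=cell_id, color_counts={}, fusions=Counter())

    coords = np.array([(x, y) for _, x, y in triples])
    n = len(triples)
    if n == 1:
        labels = np.zeros(1, dtype=int)
        n_comp = 1
    else:
        adj = squareform(pdist(coords)) <= fusion_radius
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    clusters: list[SpotCluster] = []
    counts: dict[Color, int] = {}
    fusions: Counter = Counter()
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        colors = tuple(sorted({triples[i][0] for i in members}, key=lambda c: c.value))
        centroid = coords[members].mean(axis=0)
        clusters.append(
            SpotCluster(
                colors=colors,
                centroid=(float(centroid[0]), float(centroid[1])),
                n_spots=len(members),
            )
        )
        for color in colors:
            counts[color] = counts.get(color, 0) + 1
        if len(colors) >= 2:
            fusions[frozenset(colors)] += 1
    return CellPattern(
        cell_id=cell_id, color_counts=counts, fusions=fusions, clusters=clusters
    )


def extract_patterns(
    table: pd.DataFrame, fusion_radius: float, n_cells: int | None = None
) -> list[CellPattern]:
    """Extract every cell of one hybridization's spot table.

    ``n_cells`` fills in empty patterns for cells whose signals all dropped
    out (the table carries rows only for observed spots).
    """
    by_cell = {int(cid): grp for cid, grp in table.groupby("cell_id")}
    if n_cells is None:
        ids = sorted(by_cell)
    else:
        ids = list(range(1, n_cells + 1))
    out = []
    for cid in ids:
        grp = by_cell.get(cid)
        if grp is None:
            out.append(CellPattern(cell_id=cid, color_counts={}, fusions=Counter()))
        else:
            out.append(extract_cell_pattern(grp, fusion_radius, cell_id=cid))
    return out


def patterns_to_frame(patterns: list[CellPattern]) -> pd.DataFrame:
    """Serializable per-cell summary (one row per color count plus fusion rows)."""
    rows = []
    for p in patterns:
        for color, n in sorted(p.color_counts.items(), key=lambda kv: kv[0].value):
            rows.append((p.cell_id, color.value, n, ""))
        for pair, n in sorted(p.fusions.items(), key=lambda kv: sorted(c.value for c in kv[0])):
            rows.append((p.cell_id, "+".join(sorted(c.value for c in pair)), n, "fusion"))
    return pd.DataFrame(rows, columns=["cell_id", "color", "count", "kind"])
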