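"""Voronoi-tessellation cell adjacency and cell-to-cell interaction tallies.

Each cell's centroid seeds a Voronoi polygon; two cells are *adjacent* (and
considered interacting) when their polygons share a border of positive
length.  For every adjacency, the Cartesian product of the two cells'
positive-marker sets is tallied into a symmetric interaction matrix: entry
(A, B) counts the times a cell positive for A was adjacent to a cell
positive for B.  Homotypic interactions (both cells positive for the same
marker) land on the diagonal.

Because Voronoi polygons border only immediate neighbors, a cell's sphere
of influence is restricted to its nearest surrounding cells — no fixed
interaction radius is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import QhullError, Voronoi

from .coexpression import PairCountMatrix, flatten_features
from .io import DataError
from .panel import MarkerPanel, PanelError
from .quant import CellRecord, ExtractedCell

#: Finite Voronoi ridges shorter than this are treated as point contacts
#: (cocircular degeneracies), i.e. NOT adjacency.
RIDGE_LENGTH_TOL = 1e-9

SUBSET_MODES = (
    "all_functional",
    "lineage_only",
    "immunoregulatory",
    "single_marker_ablation",
    "homotypic_diagonal",
)


@dataclass
class AdjacencyGraph:
    """Undirected cell adjacency graph: nodes are cell ids."""

    nodes: tuple[int, ...]
    edges: frozenset[frozenset[int]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise DataError("self-edge or malformed edge in adjacency graph")
            if not e <= node_set:
                raise DataError("edge references unknown node")

    def degree(self) -> dict[int, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            for n in e:
                d[n] += 1
        return d

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.edge_list(), columns=["cell_a", "cell_b"]).to_csv(path, index=False)


def centroids(cells: Sequence[ExtractedCell]) -> dict[int, tuple[float, float]]:
    """Unweighted pixel-mean centroid per cell, 0-based (row, col)."""
    out = {}
    for c in cells:
        if len(c.pixels) < 1:
            raise DataError(f"cell {c.cell_id} has no pixels")
        m = c.pixels.mean(axis=0)
        out[c.cell_id] = (float(m[0]), float(m[1]))
    return out


def _collinear_chain(ids: list[int], pts: np.ndarray) -> AdjacencyGraph:
    # Degenerate geometry: order points along their principal direction and
    # connect consecutive neighbors.
    if len(ids) == 1:
        return AdjacencyGraph(nodes=tuple(ids), edges=frozenset())
    d = pts - pts.mean(axis=0)
    direction = d[np.argmax(np.linalg.norm(d, axis=1))]
    if np.linalg.norm(direction) == 0:
        direction = np.array([1.0, 0.0])
    order = np.argsort(d @ direction, kind="stable")
    edges = frozenset(
        frozenset((ids[order[i]], ids[order[i + 1]])) for i in range(len(ids) - 1)
    )
    return AdjacencyGraph(nodes=tuple(ids), edges=edges)


def voronoi_adjacency(cents: Mapping[int, tuple[float, float]]) -> AdjacencyGraph:
    """Adjacency graph from the Voronoi diagram of cell centroids.

    Two cells are adjacent iff their Voronoi regions share a ridge of
    positive length; unbounded ridges count as positive.  Zero-length
    ridges (four or more cocircular centroids meeting at a point) are NOT
    adjacency — a point contact is not a shared border.  Fewer than three
    cells, or all-collinear centroids, degrade to nearest-neighbor chain
    adjacency along the line.
    """
    ids = sorted(cents)
    pts = np.array([cents[i] for i in ids], dtype=float)
    if len(ids) == 0:
        return AdjacencyGraph(nodes=(), edges=frozenset())
    if not np.all(np.isfinite(pts)):
        raise DataError("non-finite centroid")
    # duplicate detection
    _, inv, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        dup_groups = [
            [ids[k] for k in np.nonzero(inv == g)[0]] for g in np.nonzero(counts > 1)[0]
        ]
        raise DataError(f"duplicate centroids for cells {dup_groups}")
    if len(ids) < 3:
        return _collinear_chain(ids, pts)
    try:
        vor = Voronoi(pts)
    except QhullError:
        return _collinear_chain(ids, pts)
    edges = set()
    for (p, q), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:
            positive = True  # unbounded ridge
        else:
            v = vor.vertices[ridge]
            positive = np.linalg.norm(v[0] - v[1]) > RIDGE_LENGTH_TOL
        if positive:
            edges.add(frozenset((ids[p], ids[q])))
    return AdjacencyGraph(nodes=tuple(ids), edges=frozenset(edges))


def radius_adjacency(
    cents: Mapping[int, tuple[float, float]], radius: float
) -> AdjacencyGraph:
    """Fixed-distance adjacency (for comparison experiments only).

    Prior work used a set physical distance to define neighboring cells;
    the Voronoi construction above is this package's default and the fixed
    radius is retained only to enable side-by-side comparisons.
    """
    ids = sorted(cents)
    pts = np.array([cents[i] for i in ids], dtype=float)
    edges = set()
    for a in range(len(ids)):
        d = np.linalg.norm(pts[a + 1 :] - pts[a], axis=1)
        for off in np.nonzero(d <= radius)[0]:
            edges.add(frozenset((ids[a], ids[a + 1 + off])))
    return AdjacencyGraph(nodes=tuple(ids), edges=frozenset(edges))


def interaction_matrix(
    graph: AdjacencyGraph,
    records: Sequence[CellRecord],
    marker_subset: Sequence[str],
) -> PairCountMatrix:
    """Tally marker pairs over all cell adjacencies.

    Each unordered edge (u, v) is visited once; every (a, b) in
    positive(u) × positive(v) adds one count to the unordered pair {a, b}
    (the diagonal when a = b).  Reading the symmetric matrix at (A, B)
    gives the number of times a cell positive for A was adjacent to a cell
    positive for B.
    """
    if not marker_subset:
        raise PanelError("empty marker subset")
    markers = tuple(marker_subset)
    index = {m: i for i, m in enumerate(markers)}
    by_id = {r.cell_id: r for r in records}
    missing = set(graph.nodes) - set(by_id)
    if missing:
        raise DataError(f"graph nodes without cell records: {sorted(missing)}")
    P = len(markers)
    counts = np.zeros((P, P), dtype=np.int64)
    for e in graph.edges:
        u, v = tuple(e)
        pos_u = [index[m] for m in by_id[u].positive_markers if m in index]
        pos_v = [index[m] for m in by_id[v].positive_markers if m in index]
        for a in pos_u:
            for b in pos_v:
                counts[a, b] += 1
                if a != b:
                    counts[b, a] += 1
                else:
                    # homotypic: one adjacency, one diagonal count — but the
                    # matrix must stay symmetric, so the diagonal absorbs it
                    pass
    return PairCountMatrix(markers=markers, counts=counts, flavor="interaction")


def subset_features(
    matrix: PairCountMatrix,
    mode: str,
    panel: MarkerPanel | None = None,
    target: str | None = None,
    include_diagonal: bool = True,
) -> pd.Series:
    """Feature vectors from sub-blocks of an interaction matrix.

    Modes: ``all_functional`` / ``lineage_only`` / ``immunoregulatory``
    flatten the corresponding sub-matrix (panel categories required);
    ``single_marker_ablation`` keeps only the entries involving ``target``
    (its row, diagonal included); ``homotypic_diagonal`` keeps the full
    diagonal.
    """
    if mode not in SUBSET_MODES:
        raise ValueError(f"unknown subset mode {mode!r}")
    if mode == "homotypic_diagonal":
        return pd.Series(
            np.diag(matrix.counts).astype(float),
            index=[f"{m}+{m}" for m in matrix.markers],
        )
    if mode == "single_marker_ablation":
        if target is None or target not in matrix.markers:
            raise PanelError(f"ablation target {target!r} not in matrix markers")
        i = matrix.markers.index(target)
        names = [
            "+".join(sorted((target, m))) for m in matrix.markers
        ]
        return pd.Series(matrix.counts[i, :].astype(float), index=names)
    if panel is None:
        raise PanelError(f"mode {mode!r} requires the marker panel")
    wanted = {
        "all_functional": panel.functional_names,
        "lineage_only": panel.lineage_names,
        "immunoregulatory": panel.immunoregulatory_names,
    }[mode]
    keep = [m for m in matrix.markers if m in set(wanted)]
    if not keep:
        raise PanelError(f"no markers of mode {mode!r} present in matrix")
    return flatten_features(matrix.submatrix(keep), include_diagonal=include_diagonal)
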