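"""Labeled neighborhood graphs built from per-cell spatial tables.

Cells become graph nodes carrying 2D/3D coordinates and an integer cell-type
label; edges connect spatially adjacent cells.  One graph is built per tissue
section (or animal ID), because sections are physically disjoint and controls
must be shuffled within a section.

Label codes are contiguous integers ``1..L``; code ``0`` is reserved for
"erased" nodes, which motif discovery uses to mask out the sites of motifs it
has already reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree


class DegenerateGeometryError(ValueError):
    """Raised when a section's points cannot be triangulated (collinear/coplanar)."""


@dataclass
class CellMap:
    """Per-cell table for one or more tissue sections.

    Attributes
    ----------
    positions : (n, d) float array, d in {2, 3}, microns.
    cell_types : (n,) int array with codes in 1..L (0 = erased).
    sections : (n,) array of section identifiers.
    cell_ids : (n,) array of opaque per-cell identifiers, unique per section.
    type_names : mapping code -> human-readable cell-type name.
    expression : optional (n, G) non-negative matrix, counts.
    gene_names : optional length-G list.
    """

    positions: np.ndarray
    cell_types: np.ndarray
    sections: np.ndarray
    cell_ids: np.ndarray | None = None
    type_names: dict[int, str] = field(default_factory=dict)
    expression: np.ndarray | None = None
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cell_types = np.asarray(self.cell_types, dtype=np.int32)
        self.sections = np.asarray(self.sections)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        n = len(self.positions)
        if len(self.cell_types) != n or len(self.sections) != n:
            raise ValueError("positions, cell_types and sections must have equal length")
        if self.cell_types.min(initial=1) < 0:
            raise ValueError("cell-type codes must be >= 0")
        if self.cell_ids is None:
            self.cell_ids = np.arange(n)
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            for sec in np.unique(self.sections):
                ids = self.cell_ids[self.sections == sec]
                if len(np.unique(ids)) != len(ids):
                    raise ValueError(f"duplicate cell_id within section {sec!r}")
        if not self.type_names:
            self.type_names = {int(c): str(c) for c in np.unique(self.cell_types) if c > 0}

    @property
    def n_types(self) -> int:
        return int(max(self.type_names, default=int(self.cell_types.max(initial=0))))


@dataclass
class NeighborhoodGraph:
    """Undirected labeled graph for one section.

    Nodes are indexed ``0..n-1``.  Adjacency is stored in CSR form
    (``indptr``/``indices``) for fast vectorized traversal; ``edges`` gives
    the canonical (u < v) undirected pair list.
    """

    coords: np.ndarray
    labels: np.ndarray
    edges: np.ndarray
    section_id: object = 0

    indptr: np.ndarray = field(init=False, repr=False)
    indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        if len(edges) and (edges[:, 0] == edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")
        edges = np.unique(edges, axis=0) if len(edges) else edges
        self.edges = edges
        n = self.n_nodes
        if len(edges) and edges.max() >= n:
            raise ValueError("edge endpoint out of range")
        # symmetric CSR adjacency, neighbor lists sorted
        both = np.concatenate([edges, edges[:, ::-1]]) if len(edges) else edges
        order = np.lexsort((both[:, 1], both[:, 0])) if len(both) else np.array([], dtype=int)
        both = both[order]
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.indptr, both[:, 0] + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.indices = np.ascontiguousarray(both[:, 1]) if len(both) else np.array([], dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int) -> np.ndarray:
        if not 0 <= v < self.n_nodes:
            raise KeyError(f"vertex {v} not in graph")
        return self.indices[self.indptr[v]: self.indptr[v + 1]]

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def with_labels(self, labels: np.ndarray) -> "NeighborhoodGraph":
        """Same topology, different label assignment (used by null models)."""
        g = NeighborhoodGraph(self.coords, labels, self.edges, self.section_id)
        return g


def forward_neighborhood(G: NeighborhoodGraph, v: int, excluded=()) -> set[int]:
    """Neighbors of ``v`` that are not in the excluded vertex set.

    This is the forward neighborhood N_frw(v, V0) used by the path-enumeration
    tree: candidate extensions of a growing path exclude vertices already on it.
    """
    excluded = set(excluded)
    return {int(u) for u in G.neighbors(v) if u not in excluded}


def _check_duplicates(pts: np.ndarray, section, jitter: bool, seed: int) -> np.ndarray:
    uniq = np.unique(pts, axis=0)
    if len(uniq) == len(pts):
        return pts
    if not jitter:
        raise ValueError(
            f"section {section!r} contains duplicate coordinates; "
            "pass jitter_duplicates=True to apply a seeded deterministic jitter"
        )
    bbox = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
    rng = np.random.default_rng(seed)
    return pts + rng.normal(scale=1e-6 * max(bbox, 1.0), size=pts.shape)


def _delaunay_edges(pts: np.ndarray, section) -> np.ndarray:
    d = pts.shape[1]
    if len(pts) < d + 1:
        raise DegenerateGeometryError(
            f"section {section!r}: need at least {d + 1} points for Delaunay in {d}D"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"section {section!r}: degenerate (collinear/coplanar) input for Delaunay"
        ) from exc
    simplices = tri.simplices
    m = simplices.shape[1]
    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            pairs.append(simplices[:, [i, j]])
    edges = np.concatenate(pairs)
    return np.unique(np.sort(edges, axis=1), axis=0)


def _knn_edges(pts: np.ndarray, k: int) -> np.ndarray:
    if k < 1:
        raise ValueError("knn requires param K >= 1")
    k_eff = min(k, len(pts) - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_eff + 1)
    src = np.repeat(np.arange(len(pts)), k_eff)
    dst = idx[:, 1:].ravel()
    return np.column_stack([src, dst])


def _epsilon_edges(pts: np.ndarray, radius: float) -> np.ndarray:
    if radius is None or radius <= 0:
        raise ValueError("epsilon graph requires param radius > 0")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    return pairs.reshape(-1, 2)


def build_graph(
    cells: CellMap,
    method: str = "delaunay",
    param: float | None = None,
    *,
    max_edge_length: float | None = None,
    jitter_duplicates: bool = False,
    seed: int = 0,
) -> dict[object, NeighborhoodGraph]:
    """Build one :class:`NeighborhoodGraph` per section.

    Parameters
    ----------
    method : {"delaunay", "knn", "epsilon"}
        ``delaunay``: edge iff the pair shares a Delaunay simplex edge;
        ``knn``: undirected union of each vertex's K nearest neighbors
        (``param`` = K); ``epsilon``: edge iff Euclidean distance <= radius
        (``param`` = radius).
    max_edge_length : optional
        Drop edges longer than this (off by default; long boundary edges are
        kept as-is otherwise).
    jitter_duplicates : bool
        Exact duplicate coordinates raise by default; opt in to a seeded
        deterministic jitter of magnitude 1e-6 x bounding-box diagonal.

    Returns
    -------
    dict mapping section id -> NeighborhoodGraph (insertion order = sorted
    section ids).  Node order within a section preserves input row order.
    """
    if method not in ("delaunay", "knn", "epsilon"):
        raise ValueError(f"unknown graph construction method: {method!r}")
    out: dict[object, NeighborhoodGraph] = {}
    for sec in sorted(np.unique(cells.sections), key=str):
        mask = cells.sections == sec
        pts = _check_duplicates(cells.positions[mask], sec, jitter_duplicates, seed)
        if method == "delaunay":
            edges = _delaunay_edges(pts, sec)
        elif method == "knn":
            edges = _knn_edges(pts, int(param))
        else:
            edges = _epsilon_edges(pts, param)
        if max_edge_length is not None and len(edges):
            lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
            edges = edges[lengths <= max_edge_length]
        out[sec] = NeighborhoodGraph(pts, cells.cell_types[mask], edges, section_id=sec)
    return out


def write_graph(graphs: dict, edge_path, node_path) -> None:
    """Write edge-list and node-table TSVs (0-based node indices, per section)."""
    erows, nrows = [], []
    for sec, g in graphs.items():
        for u, v in g.edges:
            erows.append((sec, int(u), int(v)))
        for i in range(g.n_nodes):
            nrows.append((sec, i, *g.coords[i], int(g.labels[i])))
    pd.DataFrame(erows, columns=["section", "v1", "v2"]).to_csv(edge_path, sep="\t", index=False)
    d = next(iter(graphs.values())).coords.shape[1]
    cols = ["section", "index", "x", "y"] + (["z"] if d == 3 else []) + ["label"]
    pd.DataFrame(nrows, columns=cols).to_csv(node_path, sep="\t", index=False)
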