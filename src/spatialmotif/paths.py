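"""Enumeration and uniform sampling of simple paths in neighborhood graphs.

The Path ENumeration algorithm (PEN) is an ESU-style tree traversal: a path
grows only through neighbors of its most recently added vertex that are not
already on the path, and — to report each undirected path once — the index of
the final vertex must exceed the index of the root.  Uniform Random Path
ENumeration (URPEN) prunes this tree stochastically: the extension at depth
``d`` is taken with probability ``p_d``, so every leaf (path) survives with
identical probability ``prod(p_d)`` and the output is an unbiased sample.

Paths can be constrained to be *radial*: physical distance must increase
monotonically along the node sequence, so that path order reflects spatial
order.  We use the symmetric two-endpoint criterion (distance from the first
node strictly increases forward AND distance from the last node strictly
increases backward), which makes a path radial iff its reverse is — required
for reverse augmentation to be consistent.  The forward half is checked while
the tree is extended (a candidate that breaks it is never recursed into); the
backward half is a deterministic filter on the leaves, which leaves the
per-leaf inclusion probability untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .graph import NeighborhoodGraph


class PathSample(NamedTuple):
    nodes: tuple
    word: tuple
    section_id: object


@dataclass(frozen=True)
class SamplingPlan:
    """Per-depth inclusion probabilities for URPEN.

    ``p[0]`` applies to root-vertex inclusion, ``p[d-1]`` to the extension
    reaching depth ``d``.  The overall per-path inclusion probability is
    ``prod(p)``.
    """

    k: int
    p: tuple
    radial: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("path length k must be >= 2")
        if len(self.p) != self.k:
            raise ValueError("p must have one probability per depth (length k)")
        if any(not (0.0 <= q <= 1.0) for q in self.p):
            raise ValueError("all p_d must be in [0, 1]")

    @classmethod
    def from_level(cls, k: int, level: float, radial: bool = True, seed: int = 0):
        """Scalar sampling level q -> p = (1, ..., 1, q), the standard usage."""
        return cls(k=k, p=(1.0,) * (k - 1) + (float(level),), radial=radial, seed=seed)

    @property
    def inclusion_probability(self) -> float:
        return float(np.prod(self.p))


@dataclass
class PathSet:
    """A batch of same-length paths from one graph.

    ``nodes`` is an (m, k) integer array; row order is the deterministic
    PEN traversal order.  ``words`` resolves labels lazily so the same node
    tuples can be re-labeled by null models.
    """

    nodes: np.ndarray
    graph: NeighborhoodGraph

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        if self.nodes.ndim != 2:
            raise ValueError("nodes must be a 2D (m, k) array")

    @property
    def k(self) -> int:
        return self.nodes.shape[1]

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def words(self) -> np.ndarray:
        return self.graph.labels[self.nodes]

    def to_samples(self) -> Iterator[PathSample]:
        words = self.words
        sec = self.graph.section_id
        for row, w in zip(self.nodes, words):
            yield PathSample(tuple(int(x) for x in row), tuple(int(x) for x in w), sec)


def is_radial(nodes: Sequence[int], coords: np.ndarray, mode: str = "both") -> bool:
    """True iff the path's node sequence is radial.

    mode="both" (default): distance from the first node strictly increases
    along the sequence and distance from the last node strictly increases
    along the reversed sequence.  mode="start": forward condition only.
    Ties (exactly equal distances) fail.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    if len(nodes) < 2:
        raise ValueError("a path needs at least 2 nodes")
    pts = np.asarray(coords, dtype=float)[nodes]
    if not np.isfinite(pts).all():
        raise ValueError("missing or non-finite coordinates")
    d_first = np.linalg.norm(pts - pts[0], axis=1)
    ok = bool(np.all(np.diff(d_first) > 0))
    if mode == "start":
        return ok
    if mode != "both":
        raise ValueError(f"unknown radial mode {mode!r}")
    d_last = np.linalg.norm(pts - pts[-1], axis=1)
    return ok and bool(np.all(np.diff(d_last[::-1]) > 0))


def _traverse(G: NeighborhoodGraph, k: int, p=None, rng=None, radial=False) -> np.ndarray:
    """Level-wise PEN/URPEN traversal; returns (m, k) canonical path rows."""
    n = G.n_nodes
    if k < 2:
        raise ValueError("path length k must be >= 2")
    if k > n:
        return np.empty((0, k), dtype=np.int64)
    indptr, indices, coords = G.indptr, G.indices, G.coords

    cur = np.arange(n, dtype=np.int64)[:, None]
    if p is not None and p[0] < 1.0:
        cur = cur[rng.random(len(cur)) < p[0]]
    d_last = np.zeros(len(cur))  # distance from root to current last vertex

    for depth in range(2, k + 1):
        if len(cur) == 0:
            return np.empty((0, k), dtype=np.int64)
        last = cur[:, -1]
        counts = (indptr[last + 1] - indptr[last]).astype(np.int64)
        total = int(counts.sum())
        rowrep = np.repeat(np.arange(len(cur)), counts)
        cum = np.zeros(len(cur), dtype=np.int64)
        np.cumsum(counts[:-1], out=cum[1:])
        cand = indices[np.repeat(indptr[last], counts) + (np.arange(total) - cum[rowrep])]

        keep = np.ones(total, dtype=bool)
        for j in range(depth - 1):  # simple-path: candidate not already on path
            keep &= cand != cur[rowrep, j]
        if radial:  # forward half of the radial criterion, checked while extending
            d_cand = np.linalg.norm(coords[cand] - coords[cur[rowrep, 0]], axis=1)
            keep &= d_cand > d_last[rowrep]
        if depth == k:  # canonical orientation: final index exceeds root index
            keep &= cand > cur[rowrep, 0]
        if p is not None and p[depth - 1] < 1.0:
            keep &= rng.random(total) < p[depth - 1]

        rowrep, cand = rowrep[keep], cand[keep]
        cur = np.column_stack([cur[rowrep], cand])
        if radial:
            d_last = np.linalg.norm(coords[cand] - coords[cur[:, 0]], axis=1)

    if radial and k > 2:  # backward half, applied at the leaves
        end = coords[cur[:, -1]]
        d_end = np.linalg.norm(coords[cur] - end[:, None, :], axis=2)  # (m, k)
        ok = np.ones(len(cur), dtype=bool)
        for j in range(k - 2):
            ok &= d_end[:, j] > d_end[:, j + 1]
        cur = cur[ok]
    return cur


def enumerate_paths(G: NeighborhoodGraph, k: int, radial: bool = False) -> PathSet:
    """All simple k-node paths of G, each once, in canonical orientation."""
    return PathSet(_traverse(G, k, radial=radial), G)


def sample_paths(G: NeighborhoodGraph, plan: SamplingPlan) -> PathSet:
    """URPEN: include each (radial) k-node path with probability prod(p_d)."""
    rng = np.random.default_rng(plan.seed)
    if all(q == 1.0 for q in plan.p):
        return enumerate_paths(G, plan.k, radial=plan.radial)
    return PathSet(_traverse(G, plan.k, p=plan.p, rng=rng, radial=plan.radial), G)


def add_reverses(paths: PathSet) -> PathSet:
    """Each path plus its reversal (nodes and word reversed).

    Endpoints of a simple path are distinct, so the output always has exactly
    twice as many rows as the input.
    """
    if len(paths) == 0:
        return paths
    return PathSet(np.concatenate([paths.nodes, paths.nodes[:, ::-1]]), paths.graph)


def write_paths(paths: PathSet, path) -> None:
    """TSV with section, node_1..node_k, label word."""
    import pandas as pd

    k = paths.k
    df = pd.DataFrame(paths.nodes, columns=[f"node_{i + 1}" for i in range(k)])
    df.insert(0, "section", paths.graph.section_id)
    df["label_word"] = ["".join(map(str, w)) if max(w, default=0) < 10 else "-".join(map(str, w))
                        for w in paths.words]
    df.to_csv(path, sep="\t", index=False)
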