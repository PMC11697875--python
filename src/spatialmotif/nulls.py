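"""Control label configurations: global and kernel-local label shuffling.

Controls preserve the per-section multiset of cell-type labels exactly.
Global shuffling permutes all non-fixed labels within a section; kernel
shuffling swaps each cell's label only with a cell within K graph hops,
preserving local cell-type composition (useful when a tissue is
compartmentalized and the interesting patterns live inside compartments).
Labels of *fixed* cell types are never moved, in either direction — they are
excluded both as swap initiators and as swap partners — which suppresses
motifs whose significance is driven entirely by those types.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import NeighborhoodGraph


@dataclass(frozen=True)
class ControlConfig:
    method: str = "shuffle"  # "shuffle" | "kernel"
    K: int = 1  # kernel radius in graph hops (kernel method only)
    fixed_types: frozenset = frozenset()
    n_train: int = 10
    n_score: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("shuffle", "kernel"):
            raise ValueError(f"unknown control method {self.method!r}")
        if self.method == "kernel" and self.K < 1:
            raise ValueError("kernel radius K must be >= 1")
        if self.n_train < 1 or self.n_score < 1:
            raise ValueError("n_train and n_score must be >= 1")


@dataclass
class ControlSet:
    """Per-section label assignments for a set of control replicates."""

    replicates: list  # list of dict: section -> (n,) label array
    role: str = "train"

    def __len__(self):
        return len(self.replicates)


def _movable_mask(labels: np.ndarray, fixed_types) -> np.ndarray:
    mask = np.ones(len(labels), dtype=bool)
    for t in fixed_types:
        mask &= labels != t
    mask &= labels != 0  # erased nodes stay erased
    return mask


def global_shuffle(G: NeighborhoodGraph, fixed_types=(), seed: int = 0) -> np.ndarray:
    """Uniform random permutation of the non-fixed labels of one section."""
    rng = np.random.default_rng(seed)
    labels = G.labels.copy()
    mov = np.flatnonzero(_movable_mask(labels, fixed_types))
    labels[mov] = labels[rng.permutation(mov)]
    return labels


def _khop(G: NeighborhoodGraph, v: int, K: int) -> list[int]:
    """All nodes within K graph hops of v, excluding v itself (BFS)."""
    seen = {v}
    out = []
    q = deque([(v, 0)])
    while q:
        u, d = q.popleft()
        if d == K:
            continue
        for w in G.neighbors(u):
            w = int(w)
            if w not in seen:
                seen.add(w)
                out.append(w)
                q.append((w, d + 1))
    return out


def kernel_shuffle(G: NeighborhoodGraph, K: int = 1, fixed_types=(), seed: int = 0) -> np.ndarray:
    """Local shuffle: every non-fixed node swaps labels with one uniformly
    chosen non-fixed node within graph distance <= K.

    One pass in a seeded random visit order; each node initiates exactly one
    swap (its partner may have swapped before), so the label multiset is
    conserved exactly and the degree of mixing is controlled by K.  The
    center cell belongs to its own kernel (graph distance 0), so a node may
    draw itself and keep its label — without these no-op draws the pass
    would always compose a fixed number of transpositions and entire
    permutation parities would be unreachable.
    """
    if K < 1:
        raise ValueError("kernel radius K must be >= 1")
    rng = np.random.default_rng(seed)
    labels = G.labels.copy()
    movable = _movable_mask(G.labels, fixed_types)
    order = rng.permutation(np.flatnonzero(movable))
    for v in order:
        partners = [int(v)] + [u for u in _khop(G, int(v), K) if movable[u]]
        u = partners[rng.integers(len(partners))]
        labels[v], labels[u] = labels[u], labels[v]
    return labels


def shuffle_labels(G: NeighborhoodGraph, config: ControlConfig, seed: int) -> np.ndarray:
    if config.method == "shuffle":
        return global_shuffle(G, config.fixed_types, seed)
    return kernel_shuffle(G, config.K, config.fixed_types, seed)


def build_controls(graphs: dict, config: ControlConfig) -> tuple[ControlSet, ControlSet]:
    """nTrain training and nScore scoring replicates, sections independent.

    Every (replicate, section) pair gets its own child seed spawned from the
    master seed, so replicates are mutually independent and section-parallel
    execution is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_train + config.n_score)

    def make(child_ss):
        per_sec = child_ss.spawn(len(graphs))
        return {
            sec: shuffle_labels(g, config, int(s.generate_state(1)[0] % (2**31)))
            for (sec, g), s in zip(graphs.items(), per_sec)
        }

    train = ControlSet([make(c) for c in children[: config.n_train]], role="train")
    score = ControlSet([make(c) for c in children[config.n_train:]], role="score")
    return train, score
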