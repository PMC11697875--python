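"""Ground-truth synthetic graphs and benchmark metrics.

The benchmark embeds a degenerate pattern — one variable position with two
equiprobable cell types, e.g. ``(A/B)CDE`` — onto node-disjoint radial paths
of a random Delaunay graph, labels the remaining nodes from a near-uniform
background, runs discovery, and scores recovery by the best shift-aligned
Pearson correlation between recovered and embedded PWMs, plus TPR/FPR and a
success rate combining correlation with statistical significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discovery import PWM
from .graph import NeighborhoodGraph, _delaunay_edges
from .paths import PathSet, enumerate_paths


def background_frequencies(L: int = 12) -> np.ndarray:
    """The benchmark's near-uniform background: b_F = [1, 1/2, ..., 1/L]^(1/4),
    normalized.  The max/min frequency ratio is L^(1/4) (< 2 for L = 12), so no
    cell type is common enough to create spurious repeat patterns."""
    b = (1.0 / np.arange(1, L + 1)) ** 0.25
    return b / b.sum()


@dataclass(frozen=True)
class EmbeddingSpec:
    """A degenerate pattern ``(A/B)CDE``-style and how densely to embed it.

    ``pattern`` is a tuple of positions; the variable position is a tuple of
    exactly two codes, fixed positions are single codes.  ``f`` is the
    fraction of graph nodes used for embedding, so the number of embedded
    paths is floor(f * n / W).
    """

    pattern: tuple
    f: float
    L: int = 12
    b_F: np.ndarray = None
    seed: int = 0
    methods_convention: bool = False  # f*n/W paths per variant instead of in total

    def __post_init__(self):
        variable = [p for p in self.pattern if isinstance(p, tuple)]
        if len(variable) != 1 or len(variable[0]) != 2:
            raise ValueError("pattern must have exactly one variable position with two types")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("embedding fraction f must be in [0, 1]")
        if self.b_F is None:
            object.__setattr__(self, "b_F", background_frequencies(self.L))

    @property
    def W(self) -> int:
        return len(self.pattern)

    def n_patterns(self, n_nodes: int) -> int:
        """Number of embedded paths: floor(f * n / W) pattern instances in
        total (doubled under the per-variant convention)."""
        n = int(np.floor(self.f * n_nodes / self.W))
        return 2 * n if self.methods_convention else n

    def ground_truth_pwm(self, rho: float = 0.01) -> PWM:
        """PWM of the embedded pattern: one-hot columns, (0.5, 0.5) at the
        variable position, softened by a uniform Dirichlet prior of weight
        rho (the prior is uniform over cell types here, by construction of
        the benchmark)."""
        M = np.zeros((self.L, self.W))
        for j, p in enumerate(self.pattern):
            if isinstance(p, tuple):
                M[p[0] - 1, j] = 0.5
                M[p[1] - 1, j] = 0.5
            else:
                M[p - 1, j] = 1.0
        M = (M + rho / self.L) / (1.0 + rho)
        M /= M.sum(axis=0, keepdims=True)
        return PWM(M, self.b_F, rho)


def parse_pattern(text: str) -> tuple:
    """Parse ``(A/B)CDE`` notation into a pattern tuple (A=1, B=2, ...)."""
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.index(")", i)
            alts = text[i + 1:j].split("/")
            if len(alts) != 2:
                raise ValueError("variable position must list exactly two types")
            out.append(tuple(ord(a.strip()) - ord("A") + 1 for a in alts))
            i = j + 1
        else:
            out.append(ord(ch) - ord("A") + 1)
            i += 1
    return tuple(out)


def generate_random_graph(n_points: int, seed: int = 0, dim: int = 2) -> NeighborhoodGraph:
    """Delaunay graph on uniform random points in the unit square (or cube)."""
    if n_points < dim + 2:
        raise ValueError("need at least dim + 2 points")
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, dim))
    edges = _delaunay_edges(pts, "synthetic")
    labels = np.zeros(n_points, dtype=np.int32)
    return NeighborhoodGraph(pts, labels, edges, section_id="synthetic")


def assign_background_labels(G: NeighborhoodGraph, b_F: np.ndarray, seed: int = 0) -> np.ndarray:
    """Draw a label for every node independently from the (normalized)
    background frequency vector."""
    b = np.asarray(b_F, dtype=float)
    if (b <= 0).any():
        raise ValueError("background frequencies must be positive")
    b = b / b.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(1, len(b) + 1), size=G.n_nodes, p=b).astype(np.int32)


def embed_patterns(
    G: NeighborhoodGraph,
    spec: EmbeddingSpec,
    radial_paths: PathSet | None = None,
) -> tuple[np.ndarray, list, PWM]:
    """Label a graph with background + embedded pattern occurrences.

    Selects floor(f * n / W) node-disjoint radial W-paths uniformly (seeded
    rejection sampling over the enumerated radial path set), writes the
    pattern onto them with the variable position split fairly between its two
    alternatives, and labels all remaining nodes from the background.

    Returns (labels, ground-truth occurrences as node tuples with their
    realized words, ground-truth PWM).
    """
    W = spec.W
    n_patterns = spec.n_patterns(G.n_nodes)
    rng = np.random.default_rng(spec.seed)
    labels = assign_background_labels(G, spec.b_F, seed=int(rng.integers(2**31)))

    if n_patterns > 0:
        if radial_paths is None:
            radial_paths = enumerate_paths(G, W, radial=True)
        pool = radial_paths.nodes
        if len(pool) == 0:
            raise ValueError("graph has no radial paths of the requested length")
        order = rng.permutation(len(pool))
        used = np.zeros(G.n_nodes, dtype=bool)
        chosen = []
        for idx in order:
            row = pool[idx]
            if not used[row].any():
                used[row] = True
                chosen.append(row)
                if len(chosen) == n_patterns:
                    break
        if len(chosen) < n_patterns:
            raise ValueError(
                f"only {len(chosen)} node-disjoint radial paths available, "
                f"{n_patterns} requested"
            )
    else:
        chosen = []

    var_pos = next(j for j, p in enumerate(spec.pattern) if isinstance(p, tuple))
    alts = spec.pattern[var_pos]
    # fair split of the variable position over the embedded paths
    half = len(chosen) // 2
    variant = np.array([alts[0]] * (len(chosen) - half) + [alts[1]] * half)
    rng.shuffle(variant)

    truth = []
    for row, v in zip(chosen, variant):
        word = [v if j == var_pos else spec.pattern[j] for j in range(W)]
        labels[row] = word
        truth.append((tuple(int(x) for x in row), tuple(int(x) for x in word)))
    return labels, truth, spec.ground_truth_pwm()


def best_pwm_correlation(query: PWM, target: PWM, min_overlap: int | None = None) -> float:
    """Best shift-aligned Pearson correlation between two PWMs.

    All offsets of the query against the target (and of the column-reversed
    query) with at least min(W_q, W_t) - 1 overlapping columns are scored by
    the Pearson correlation of the flattened overlapping submatrices; the
    maximum is returned.  A zero-variance overlap scores 0 with a warning.
    """
    Mq, Mt = query.matrix, target.matrix
    if Mq.shape[0] != Mt.shape[0]:
        raise ValueError("PWMs must share the same alphabet size")
    if min_overlap is None:
        min_overlap = min(Mq.shape[1], Mt.shape[1]) - 1
    best = -1.0
    for q in (Mq, Mq[:, ::-1]):
        Wq, Wt = q.shape[1], Mt.shape[1]
        for off in range(-Wq + 1, Wt):
            lo_q, hi_q = max(0, -off), min(Wq, Wt - off)
            if hi_q - lo_q < min_overlap:
                continue
            a = q[:, lo_q:hi_q].ravel()
            b = Mt[:, lo_q + off:hi_q + off].ravel()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn("zero-variance overlap in PWM comparison; scored 0")
                r = 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            best = max(best, r)
    return best


@dataclass
class BenchmarkResult:
    """Per-run record: each output motif's best PCC against the embedded PWM
    and its hold-out log p-value."""

    pcc: list = field(default_factory=list)
    log_p: list = field(default_factory=list)

    @property
    def best_pcc(self) -> float:
        return max(self.pcc) if self.pcc else float("nan")


def compute_tpr_fpr(
    results: list[BenchmarkResult], pcc_threshold: float = 0.95, logp_threshold: float = -10.0
) -> tuple[float | None, float | None]:
    """Confusion-matrix rates over all output motifs of all runs.

    TP: correlation above threshold and p below threshold; FN: correlation
    above but p above; FP: correlation below and p below; TN: both below
    threshold criteria unmet.  Undefined rates (zero denominator) are None.
    """
    tp = fn = fp = tn = 0
    for res in results:
        for r, lp in zip(res.pcc, res.log_p):
            if r >= pcc_threshold:
                if lp <= logp_threshold:
                    tp += 1
                else:
                    fn += 1
            else:
                if lp <= logp_threshold:
                    fp += 1
                else:
                    tn += 1
    tpr = tp / (tp + fn) if (tp + fn) else None
    fpr = fp / (fp + tn) if (fp + tn) else None
    return tpr, fpr


def success_rate(
    results: list[BenchmarkResult], pcc_threshold: float = 0.95, logp_threshold: float = -10.0
) -> float:
    """Fraction of runs with at least one output motif that is both accurate
    (PCC >= threshold) and significant (log p <= threshold)."""
    if not results:
        return 0.0
    ok = sum(
        any(r >= pcc_threshold and lp <= logp_threshold for r, lp in zip(res.pcc, res.log_p))
        for res in results
    )
    return ok / len(results)
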