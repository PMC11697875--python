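"""Motif discovery in cell-type label sequences sampled from neighborhood graphs.

The engine follows the STREME recipe adapted to graph-path input.  Sampled
(reverse-augmented) paths are cut into W-mers; each distinct label word is a
candidate *seed* counted under the Zero-Node-In-Common (ZNIC) model, which
admits only node-disjoint occurrences so overlapping instances cannot inflate
counts.  Seed significance compares the primary ZNIC count against counts in
label-shuffled control graphs through a gamma-Poisson (negative-binomial
predictive) upper-tail test.  The best seeds are refined by PWM enrichment:
words are ranked by likelihood-ratio score under the current PWM, incremental
ZNIC counts are accumulated down the ranking, and the score cutoff minimizing
the negative-binomial p-value defines the motif members, from which the next
PWM is estimated by weighted maximum likelihood.  Output motifs are scored on
held-out shuffles, their nodes are erased (label set to 0), and the process
repeats.

All ZNIC counting loops are compiled with numba; everything else is
vectorized numpy/scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import logsumexp
from scipy.stats import nbinom

from .graph import NeighborhoodGraph
from .nulls import ControlConfig, build_controls
from .paths import PathSet, SamplingPlan, add_reverses, sample_paths

LOG10 = math.log(10.0)


# ---------------------------------------------------------------------------
# negative-binomial enrichment test
# ---------------------------------------------------------------------------

def negbin_log_pvalue(y0, w0, y, w, alpha=None, beta=None, log_base: float = 10.0) -> float:
    """Upper-tail log p-value of the gamma-Poisson predictive count test.

    The seed count in each graph is modeled as y_i ~ Poisson(w_i * theta)
    with exposure w_i (total ZNIC seeds in that graph) and a Gamma(alpha,
    beta) prior on the rate.  The posterior predictive for the primary count
    is negative-binomial with shape ``alpha_n = alpha + sum(y)`` and success
    probability ``p_n = w0 / (beta + sum(w) + w0)``; the p-value is
    P(Y >= y0) under that distribution.  Defaults ``alpha = y0``,
    ``beta = w0``.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if y0 < 0 or (y < 0).any() or (w < 0).any():
        raise ValueError("counts must be non-negative")
    if w0 <= 0:
        raise ValueError("primary total seed count w0 must be positive")
    if alpha is None:
        alpha = y0
    if beta is None:
        beta = w0
    out = _negbin_logsf(
        np.array([float(y0)]), float(w0), np.array([float(y.sum())]),
        float(w.sum()), np.array([float(alpha)]), float(beta),
    )[0]
    return float(out / math.log(log_base))


def _negbin_logsf(y0, w0, ysum, wsum, alpha, beta):
    """Vectorized natural-log survival P(Y >= y0); y0 == 0 gives 0 exactly."""
    y0 = np.asarray(y0, dtype=float)
    alpha_n = np.broadcast_to(np.asarray(alpha + ysum, dtype=float), y0.shape)
    beta_n = np.asarray(beta + wsum, dtype=float)
    p_n = np.broadcast_to(w0 / (beta_n + w0), y0.shape)
    out = np.zeros_like(y0)
    pos = y0 > 0
    if pos.any():
        # scipy's nbinom puts its `p` on the shape exponent, i.e. p_scipy = 1 - p_n
        with np.errstate(divide="ignore"):
            out[pos] = nbinom.logsf(y0[pos] - 1, alpha_n[pos], 1.0 - p_n[pos])
        bad = pos & ~np.isfinite(out)
        for i in np.flatnonzero(bad):  # log-space tail sum when sf underflows
            ks = np.arange(y0[i], y0[i] + 20000)
            out[i] = logsumexp(nbinom.logpmf(ks, alpha_n[i], 1.0 - p_n[i]))
    return out


# ---------------------------------------------------------------------------
# PWM representation
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Column-stochastic L x W position weight matrix over cell types."""

    matrix: np.ndarray
    background: np.ndarray
    rho: float = 0.01

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def W(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> tuple:
        """Most probable cell-type code at each position (1-based codes)."""
        return tuple(int(i) + 1 for i in self.matrix.argmax(axis=0))


def initial_pwm(word, b, rho: float = 0.01) -> PWM:
    """PWM for a single seed word: near-one-hot columns softened by a
    background-weighted Dirichlet prior, then column-normalized."""
    if rho < 0:
        raise ValueError("Dirichlet prior weight rho must be >= 0")
    b = np.asarray(b, dtype=float)
    L = len(b)
    word = tuple(int(s) for s in word)
    if any(not 1 <= s <= L for s in word):
        raise ValueError("word symbols must be integer codes in 1..L")
    W = len(word)
    M = np.full((L, W), rho / (1.0 + rho))
    for j, s in enumerate(word):
        M[s - 1, j] = (1.0 + rho * b[s - 1]) / (1.0 + rho)
    M /= M.sum(axis=0, keepdims=True)
    return PWM(M, b, rho)


def lr_score(pwm: PWM, word) -> float:
    """Log likelihood-ratio of a word under the motif versus background.

    Positive iff the word is more likely under the PWM.  Words containing an
    erased symbol (0) never match: score is -inf.
    """
    word = np.asarray(word, dtype=np.int64)
    if len(word) != pwm.W:
        raise ValueError("word length must equal PWM width")
    if (word == 0).any():
        return float("-inf")
    idx = word - 1
    cols = np.arange(pwm.W)
    return float(np.sum(np.log(pwm.matrix[idx, cols]) - np.log(pwm.background[idx])))


@dataclass
class SeedMember:
    """One word contributing to a motif."""

    word: tuple
    Z: int  # incremental ZNIC count (sites disjoint from higher-ranked members)
    N: int  # total ZNIC count in the primary data
    P: float  # log p-value from the initial seed evaluation

    def indicator(self, L: int) -> np.ndarray:
        I = np.zeros((L, len(self.word)))
        for j, s in enumerate(self.word):
            I[s - 1, j] = 1.0
        return I


def update_pwm_mle(members: list[SeedMember], b, rho: float = 0.01) -> PWM:
    """Maximum-likelihood PWM from motif members.

    Each member's one-hot indicator is weighted by |P| * Z / N — more
    significant seeds and seeds whose sites are mostly novel weigh more —
    plus a background pseudocount rho * b, then columns are normalized.
    """
    if not members:
        raise ValueError("cannot estimate a PWM from zero members")
    b = np.asarray(b, dtype=float)
    L = len(b)
    W = len(members[0].word)
    M = np.zeros((L, W))
    for m in members:
        if m.N > 0:
            M += abs(m.P) * (m.Z / m.N) * m.indicator(L)
    if not M.any():
        raise ValueError("degenerate motif: all member weights are zero")
    M += rho * b[:, None]
    M /= M.sum(axis=0, keepdims=True)
    return PWM(M, b, rho)


@dataclass
class MotifResult:
    pwm: PWM
    members: list[SeedMember]
    score_threshold: float
    log_p_train: float
    log_p_score: float
    occupied_nodes: dict  # section -> sorted array of node indices
    rank: int
    n_sites: int  # accepted node-disjoint occurrence count in the primary data

    @property
    def consensus(self) -> tuple:
        return self.pwm.consensus


@dataclass
class DiscoveryConfig:
    W: int
    n_eval: int = 25
    n_ref: int = 4
    n_enrich: int = 20
    differential_p: bool = False
    max_motifs: int = 10
    log_base: float = 10.0
    stop_logp: float | None = -3.0  # stop when the hold-out score exceeds this
    background: np.ndarray | None = None  # known background frequencies, else estimated
    rho: float = 0.01
    # The Dirichlet prior inside the engine is uniform over cell types.  This
    # makes PWM scores of words at equal Hamming distance from a seed tie
    # exactly, so the documented tie-break (initial p-value) decides their
    # order — which is what lets degenerate variants such as (A/B)CDE merge
    # into one motif.  A background-shaped prior is available for export and
    # the public PWM helpers.
    uniform_prior: bool = True
    # The score-threshold search walks at most this many top-ranked words;
    # the minimizing cutoff sits within the first few words in practice and
    # counts only dilute beyond it.
    max_cutoff_candidates: int = 100

    def __post_init__(self):
        if self.W < 2:
            raise ValueError("motif width W must be >= 2")


# ---------------------------------------------------------------------------
# W-mer extraction and ZNIC seed tables
# ---------------------------------------------------------------------------

def extract_wmers(paths: PathSet, W: int) -> np.ndarray:
    """Node windows of all contiguous W-node stretches of each path.

    Input should already be reverse-augmented so that both orientations of
    every word are represented.  Returns an (m * (k - W + 1), W) node array.
    """
    k = paths.k
    if W > k:
        raise ValueError(f"W={W} exceeds path length k={k}")
    wins = [paths.nodes[:, j:j + W] for j in range(k - W + 1)]
    return np.concatenate(wins) if len(wins) > 1 else wins[0].copy()


@njit(cache=True)
def _table_kernel(occ, rows, codes, n_codes, n_nodes):  # pragma: no cover
    """Stable counting sort of occurrences by word code fused with the
    greedy per-word ZNIC pass.  Returns (sorted order, dense per-code ZNIC
    counts, selected mask aligned with the sorted order)."""
    M = len(rows)
    W = occ.shape[1]
    starts = np.zeros(n_codes + 1, dtype=np.int64)
    for i in range(M):
        starts[codes[i] + 1] += 1
    for c in range(n_codes):
        starts[c + 1] += starts[c]
    order = np.empty(M, dtype=np.int64)
    pos = starts[:-1].copy()
    for i in range(M):
        c = codes[i]
        order[pos[c]] = i
        pos[c] += 1
    stamp = np.full(n_nodes, -1, dtype=np.int64)
    zcnt = np.zeros(n_codes, dtype=np.int64)
    selected = np.zeros(M, dtype=np.bool_)
    for p in range(M):
        i = order[p]
        r = rows[i]
        c = codes[i]
        ok = True
        for j in range(W):
            if stamp[occ[r, j]] == c:
                ok = False
                break
        if ok:
            for j in range(W):
                stamp[occ[r, j]] = c
            zcnt[c] += 1
            selected[p] = True
    return order, zcnt, selected


@njit(cache=True)
def _full_table_kernel(occ, labels, powers, n_codes, n_nodes):  # pragma: no cover
    """Fused pass: label gather + word encoding + erased-window filtering +
    stable counting sort by code + greedy per-word ZNIC selection."""
    M, W = occ.shape
    codes = np.full(M, -1, dtype=np.int64)
    starts = np.zeros(n_codes + 1, dtype=np.int64)
    for i in range(M):
        c = 0
        ok = True
        for j in range(W):
            lab = labels[occ[i, j]]
            if lab == 0:
                ok = False
                break
            c += lab * powers[j]
        if ok:
            codes[i] = c
            starts[c + 1] += 1
    for c in range(n_codes):
        starts[c + 1] += starts[c]
    Mv = starts[n_codes]
    order = np.empty(Mv, dtype=np.int64)
    pos = starts[:-1].copy()
    for i in range(M):
        c = codes[i]
        if c >= 0:
            order[pos[c]] = i
            pos[c] += 1
    stamp = np.full(n_nodes, -1, dtype=np.int64)
    zcnt = np.zeros(n_codes, dtype=np.int64)
    selected = np.zeros(Mv, dtype=np.bool_)
    for p in range(Mv):
        i = order[p]
        c = codes[i]
        ok = True
        for j in range(W):
            if stamp[occ[i, j]] == c:
                ok = False
                break
        if ok:
            for j in range(W):
                stamp[occ[i, j]] = c
            zcnt[c] += 1
            selected[p] = True
    return order, codes, zcnt, selected


@njit(cache=True)
def _joint_znic(occ, rows, groups, n_groups, used):  # pragma: no cover
    counts = np.zeros(n_groups, dtype=np.int64)
    accepted = np.zeros(len(rows), dtype=np.bool_)
    W = occ.shape[1]
    for pos in range(len(rows)):
        row = rows[pos]
        ok = True
        for j in range(W):
            if used[occ[row, j]]:
                ok = False
                break
        if ok:
            for j in range(W):
                used[occ[row, j]] = True
            counts[groups[pos]] += 1
            accepted[pos] = True
    return counts, accepted


@dataclass
class SeedTable:
    """Per-word ZNIC statistics for one label assignment over a fixed
    occurrence set.

    ``codes`` are unique word codes in ascending (lexicographic-word) order;
    ``znic`` the greedy node-disjoint counts; ``total`` their sum (the
    exposure w of the graph); ``sel_rows`` indexes the ZNIC-selected
    occurrence rows of the shared occurrence array, grouped by word
    (``sel_group`` gives each row's word group).
    """

    codes: np.ndarray
    znic: np.ndarray
    total: int
    sel_rows: np.ndarray
    sel_group: np.ndarray

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """ZNIC count for each query code (0 when absent)."""
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.clip(idx, 0, max(len(self.codes) - 1, 0))
        out = np.zeros(len(codes), dtype=np.int64)
        if len(self.codes):
            hit = self.codes[idx_c] == codes
            out[hit] = self.znic[idx_c[hit]]
        return out

    def member_rows(self, member_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Selected occurrence rows of the given words, in the given word
        order; returns (rows, group index per row)."""
        gidx = np.searchsorted(self.codes, member_codes)
        rows_parts, grp_parts = [], []
        starts = np.searchsorted(self.sel_group, np.arange(len(self.codes) + 1))
        for rank, g in enumerate(gidx):
            if g >= len(self.codes) or self.codes[g] != member_codes[rank]:
                continue
            sl = slice(starts[g], starts[g + 1])
            rows_parts.append(self.sel_rows[sl])
            grp_parts.append(np.full(starts[g + 1] - starts[g], rank, dtype=np.int64))
        if not rows_parts:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(rows_parts), np.concatenate(grp_parts)


def encode_words(words: np.ndarray, L: int) -> np.ndarray:
    """Word -> integer code, first position most significant, so ascending
    code order equals lexicographic word order."""
    W = words.shape[1]
    powers = (L + 1) ** np.arange(W - 1, -1, -1, dtype=np.int64)
    return words.astype(np.int64) @ powers


def decode_words(codes: np.ndarray, L: int, W: int) -> np.ndarray:
    out = np.empty((len(codes), W), dtype=np.int64)
    rem = np.asarray(codes, dtype=np.int64).copy()
    for j in range(W - 1, -1, -1):
        out[:, j] = rem % (L + 1)
        rem //= (L + 1)
    return out


def build_seed_table(occ: np.ndarray, labels: np.ndarray, L: int, n_nodes: int) -> SeedTable:
    """Group occurrences by word under the given labels and count ZNIC sites.

    Occurrences whose window touches an erased node (label 0) are dropped.
    The greedy disjoint selection scans occurrences of each word in a
    deterministic order (word, then traversal order of the shared occurrence
    array), accepting any occurrence sharing no node with an already accepted
    occurrence of the same word; the result is maximal.
    """
    W = occ.shape[1]
    if len(occ) == 0:
        e = np.empty(0, dtype=np.int64)
        return SeedTable(e, e.copy(), 0, e.copy(), e.copy())
    n_codes = (L + 1) ** W
    # lexicographic code: first position most significant
    powers = (L + 1) ** np.arange(W - 1, -1, -1, dtype=np.int64)
    if n_codes > 50_000_000:  # very wide motifs: dense counting sort infeasible
        words = labels[occ]
        valid = (words > 0).all(axis=1)
        rows = np.flatnonzero(valid)
        if len(rows) == 0:
            e = np.empty(0, dtype=np.int64)
            return SeedTable(e, e.copy(), 0, e.copy(), e.copy())
        codes = encode_words(words[rows], L)
        uniq, remapped = np.unique(codes, return_inverse=True)
        order, zcnt, selected = _table_kernel(occ, rows, remapped.astype(np.int64),
                                              len(uniq), n_nodes)
        sel_codes = remapped[order][selected]
        return SeedTable(uniq, zcnt, int(zcnt.sum()), rows[order][selected], sel_codes)
    order, codes, zcnt, selected = _full_table_kernel(
        occ, labels.astype(np.int64), powers, n_codes, n_nodes
    )
    uniq = np.flatnonzero(zcnt > 0)
    gid = np.full(n_codes, -1, dtype=np.int64)
    gid[uniq] = np.arange(len(uniq))
    return SeedTable(
        codes=uniq.astype(np.int64),
        znic=zcnt[uniq],
        total=int(zcnt.sum()),
        sel_rows=order[selected],
        sel_group=gid[codes[order][selected]],
    )


def znic_count(occurrences) -> tuple[int, list]:
    """Greedy maximal node-disjoint subset of same-word occurrences.

    Convenience scalar form: ``occurrences`` is a sequence of node tuples
    (all carrying the same word).  Returns (count, selected subset).
    """
    used: set = set()
    chosen = []
    for occ in occurrences:
        if not used.intersection(occ):
            used.update(occ)
            chosen.append(tuple(occ))
    return len(chosen), chosen


# ---------------------------------------------------------------------------
# discovery pipeline
# ---------------------------------------------------------------------------

@dataclass
class _Pooled:
    """Sections pooled into one node-index space for counting."""

    graphs: dict
    offsets: dict
    n_nodes: int
    L: int
    occ: np.ndarray  # (M, W) global node ids, reverse-augmented W-mers
    labels: np.ndarray  # primary labels, mutated by erasure

    def globalize(self, per_section: dict) -> np.ndarray:
        out = np.empty(self.n_nodes, dtype=np.int32)
        for sec, g in self.graphs.items():
            off = self.offsets[sec]
            out[off: off + g.n_nodes] = per_section[sec]
        return out


def _pool(graphs: dict, paths_by_sec: dict, W: int) -> _Pooled:
    offsets, n = {}, 0
    for sec, g in graphs.items():
        offsets[sec] = n
        n += g.n_nodes
    L = int(max(int(g.labels.max(initial=0)) for g in graphs.values()))
    occ_parts = []
    for sec, ps in paths_by_sec.items():
        if len(ps) == 0:
            continue
        occ_parts.append(extract_wmers(add_reverses(ps), W) + offsets[sec])
    occ = np.concatenate(occ_parts) if occ_parts else np.empty((0, W), dtype=np.int64)
    labels = np.empty(n, dtype=np.int32)
    for sec, g in graphs.items():
        labels[offsets[sec]: offsets[sec] + g.n_nodes] = g.labels
    return _Pooled(graphs, offsets, n, L, occ, labels)


def evaluate_initial_seeds(
    primary: SeedTable, train_tables: list[SeedTable], config: DiscoveryConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Rank all primary words by the negative-binomial seed test.

    Returns (order, logp) where ``order`` indexes ``primary.codes`` from most
    to least significant (ties: larger primary count, then lexicographically
    smaller word) and ``logp`` is the per-word log p-value aligned with
    ``primary.codes``.
    """
    U = len(primary.codes)
    if U == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    ysum = np.zeros(U)
    wsum = 0.0
    for t in train_tables:
        ysum += t.lookup(primary.codes)
        wsum += t.total
    y0 = primary.znic.astype(float)
    logp = _negbin_logsf(y0, float(primary.total), ysum, wsum, y0, float(primary.total))
    logp = logp / math.log(config.log_base)
    order = np.lexsort((primary.codes, -primary.znic, logp))
    return order, logp


def _select_cutoff(logp: np.ndarray, differential: bool) -> int:
    """Score-threshold choice over the cumulative p-value series: the global
    minimum by default, or — in differential mode — the last cutoff of the
    initial strictly improving stretch (yields simpler motifs)."""
    if differential:
        cut = 0
        while cut + 1 < len(logp) and logp[cut + 1] < logp[cut]:
            cut += 1
        return cut
    return int(np.argmin(logp))


@dataclass
class _Enriched:
    members: list[SeedMember]
    member_codes: np.ndarray
    threshold: float
    logp: float
    accepted_rows: np.ndarray  # occurrence rows forming the motif's sites


def enrichment_iteration(
    pwm: PWM,
    pooled: _Pooled,
    primary: SeedTable,
    train_tables: list[SeedTable],
    init_logp: np.ndarray,
    config: DiscoveryConfig,
) -> _Enriched | None:
    """One enrichment pass: rank words by PWM score, accumulate incremental
    ZNIC counts, pick the score cutoff minimizing (or, in differential mode,
    the last strictly improving) negative-binomial p-value."""
    letters = decode_words(primary.codes, pooled.L, config.W)
    cols = np.arange(config.W)
    scores = np.sum(
        np.log(pwm.matrix[letters - 1, cols]) - np.log(pwm.background[letters - 1]),
        axis=1,
    )
    cand = np.flatnonzero(scores > 0)
    if len(cand) == 0:
        return None
    # scores rounded for ordering so that exact tie classes survive float
    # summation-order noise; ties fall through to the initial p-value
    order = cand[np.lexsort((primary.codes[cand], init_logp[cand], -np.round(scores[cand], 9)))]
    order = order[: config.max_cutoff_candidates]

    # incremental ZNIC down the ranking: sites disjoint from all sites of
    # higher-ranked words.  The same jointly-disjoint statistic is computed
    # in the primary data and in every control replicate, so overlap between
    # similar words (shared cores) is discounted on both sides alike.
    cand_codes = primary.codes[order]
    code_sorter = np.argsort(cand_codes)
    sorted_cand = cand_codes[code_sorter]

    def incremental(table: SeedTable):
        pos = np.searchsorted(sorted_cand, table.codes)
        pos_c = np.clip(pos, 0, len(sorted_cand) - 1)
        hit = sorted_cand[pos_c] == table.codes if len(sorted_cand) else np.zeros(0, bool)
        rank_of_code = np.full(len(table.codes), len(order), dtype=np.int64)
        rank_of_code[hit] = code_sorter[pos_c[hit]]
        grp_rank = rank_of_code[table.sel_group]
        keep = grp_rank < len(order)
        rows = table.sel_rows[keep]
        grp = grp_rank[keep]
        o2 = np.argsort(grp, kind="stable")
        rows, grp = rows[o2], grp[o2]
        used = np.zeros(pooled.n_nodes, dtype=np.bool_)
        counts, accepted = _joint_znic(pooled.occ, rows, grp, len(order), used)
        return counts, rows, grp, accepted

    Z, rows, grp_rank, accepted = incremental(primary)
    cumY = np.cumsum(Z).astype(float)
    ctrl = np.zeros(len(order))
    wsum = 0.0
    for t in train_tables:
        ctrl += incremental(t)[0]
        wsum += t.total
    cumC = np.cumsum(ctrl)
    logp = _negbin_logsf(cumY, float(primary.total), cumC, wsum, cumY, float(primary.total))
    logp = logp / math.log(config.log_base)

    cut = _select_cutoff(logp, config.differential_p)

    member_idx = order[: cut + 1]
    members = [
        SeedMember(
            word=tuple(int(x) for x in letters[u]),
            Z=int(Z[r]),
            N=int(primary.znic[u]),
            P=float(init_logp[u]),
        )
        for r, u in enumerate(member_idx)
    ]
    acc_rows = rows[accepted & (grp_rank <= cut)]
    return _Enriched(
        members=members,
        member_codes=primary.codes[member_idx],
        threshold=float(scores[order[cut]]),
        logp=float(logp[cut]),
        accepted_rows=acc_rows,
    )


def refine_and_enrich(
    seed_order: np.ndarray,
    pooled: _Pooled,
    primary: SeedTable,
    train_tables: list[SeedTable],
    init_logp: np.ndarray,
    config: DiscoveryConfig,
    b: np.ndarray,
) -> list[tuple[_Enriched, PWM]]:
    """Seed refinement and nested enrichment.

    Every candidate seed gets one enrichment iteration from its initial PWM;
    the top n_ref by resulting p-value continue for up to n_enrich further
    iterations each, stopping early when the p-value stops improving.
    Returns the refined finalists ordered by training p-value; the caller
    picks the winner by hold-out score, where the selection bias that
    inflates training p-values (seed, members and cutoff are all chosen to
    minimize it) does not carry over.
    """
    letters = decode_words(primary.codes, pooled.L, config.W)
    prior = np.full(pooled.L, 1.0 / pooled.L) if config.uniform_prior else b
    first_pass = []
    for u in seed_order[: config.n_eval]:
        pwm = initial_pwm(letters[u], prior, config.rho)
        res = enrichment_iteration(pwm, pooled, primary, train_tables, init_logp, config)
        if res is not None:
            first_pass.append((res.logp, len(first_pass), res, pwm))
    if not first_pass:
        return []
    first_pass.sort(key=lambda t: (t[0], t[1]))

    finalists = []
    for logp0, _, res, pwm in first_pass[: config.n_ref]:
        best = res
        cur_pwm = pwm
        for _ in range(config.n_enrich):
            try:
                cur_pwm = update_pwm_mle(best.members, prior, config.rho)
            except ValueError:
                break
            nxt = enrichment_iteration(cur_pwm, pooled, primary, train_tables, init_logp, config)
            if nxt is None or nxt.logp >= best.logp:
                break
            best = nxt
        finalists.append((best, cur_pwm))
    finalists.sort(key=lambda t: t[0].logp)
    return finalists


def score_motif(
    enriched: _Enriched,
    pooled: _Pooled,
    primary: SeedTable,
    score_tables: list[SeedTable],
    config: DiscoveryConfig,
) -> float:
    """Hold-out score: the 95th-percentile least significant p-value over the
    scoring replicates.

    The motif's member counts are recomputed in the primary data and in every
    held-out shuffled replicate.  One p-value is produced per replicate by a
    leave-one-out jackknife — the primary count against the other replicates
    pooled — and the value at rank ceil(0.95 * nScore) toward
    non-significance is returned, so a single unlucky replicate cannot make
    the motif look good."""
    y0 = float(len(enriched.accepted_rows))
    if y0 == 0:
        return 0.0
    ys, ws = [], []
    for t in score_tables:
        rows, grp = t.member_rows(enriched.member_codes)
        used = np.zeros(pooled.n_nodes, dtype=np.bool_)
        cnt, _ = _joint_znic(pooled.occ, rows, grp, max(len(enriched.member_codes), 1), used)
        ys.append(float(cnt.sum()))
        ws.append(float(t.total))
    ys_a, ws_a = np.array(ys), np.array(ws)
    if len(ys_a) == 1:
        loo_y, loo_w = ys_a, ws_a
    else:
        loo_y, loo_w = ys_a.sum() - ys_a, ws_a.sum() - ws_a
    logps = _negbin_logsf(
        np.full(len(ys_a), y0), float(primary.total), loo_y, loo_w,
        np.full(len(ys_a), y0), float(primary.total),
    ) / math.log(config.log_base)
    logps = np.sort(logps)  # ascending = most significant first
    idx = min(math.ceil(0.95 * len(logps)), len(logps)) - 1
    return float(logps[idx])


def erase_motif(pooled: _Pooled, occupied: np.ndarray, control_labels: list[np.ndarray]) -> None:
    """Set the cell type of every occupied node to 0 (erased) in the primary
    labels and every control replicate; erased nodes never match again."""
    pooled.labels[occupied] = 0
    for lab in control_labels:
        lab[occupied] = 0


def discover(
    graphs: dict,
    config: DiscoveryConfig,
    control_config: ControlConfig | None = None,
    paths_by_sec: dict | None = None,
    plan: SamplingPlan | None = None,
) -> list[MotifResult]:
    """Full iterative motif discovery over one or more sections.

    Paths may be supplied directly (``paths_by_sec``) or sampled here with a
    :class:`SamplingPlan` (per-section child seeds derived from ``plan.seed``).
    Control replicates are regenerated from the *current* primary labels at
    the start of every round: erasing a motif's nodes removes a biased subset
    of labels, so reshuffling the eroded label multiset (erased nodes stay
    erased everywhere) is the only way to keep primary and control multisets
    identical after the first motif.  Deterministic given the seeds in the
    plan and control config.
    """
    if paths_by_sec is None:
        if plan is None:
            raise ValueError("provide either paths_by_sec or a SamplingPlan")
        ss = np.random.SeedSequence(plan.seed)
        paths_by_sec = {}
        for sec, child in zip(graphs, ss.spawn(len(graphs))):
            sec_plan = SamplingPlan(plan.k, plan.p, plan.radial,
                                    int(child.generate_state(1)[0] % (2**31)))
            paths_by_sec[sec] = sample_paths(graphs[sec], sec_plan)

    pooled = _pool(graphs, paths_by_sec, config.W)
    if config.background is not None:
        b = np.asarray(config.background, dtype=float)
        b = b / b.sum()
    else:
        cnt = np.bincount(pooled.labels[pooled.labels > 0], minlength=pooled.L + 1)[1:]
        b = cnt / cnt.sum()

    if control_config is None:
        control_config = ControlConfig()
    round_ss = np.random.SeedSequence(control_config.seed)

    def fresh_controls() -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Shuffle the current (possibly eroded) primary labels; erased
        nodes keep label 0 and never participate in the shuffle."""
        eroded = {
            sec: g.with_labels(pooled.labels[pooled.offsets[sec]:
                                             pooled.offsets[sec] + g.n_nodes])
            for sec, g in pooled.graphs.items()
        }
        train_set, score_set = build_controls(
            eroded,
            ControlConfig(
                method=control_config.method, K=control_config.K,
                fixed_types=control_config.fixed_types,
                n_train=control_config.n_train, n_score=control_config.n_score,
                seed=int(round_ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
            ),
        )
        return ([pooled.globalize(rep) for rep in train_set.replicates],
                [pooled.globalize(rep) for rep in score_set.replicates])

    results: list[MotifResult] = []
    while len(results) < config.max_motifs:
        primary = build_seed_table(pooled.occ, pooled.labels, pooled.L, pooled.n_nodes)
        if primary.total == 0:
            break
        train_labels, score_labels = fresh_controls()
        train_tables = [build_seed_table(pooled.occ, lab, pooled.L, pooled.n_nodes)
                        for lab in train_labels]
        score_tables = [build_seed_table(pooled.occ, lab, pooled.L, pooled.n_nodes)
                        for lab in score_labels]

        order, init_logp = evaluate_initial_seeds(primary, train_tables, config)
        finalists = refine_and_enrich(order, pooled, primary, train_tables,
                                      init_logp, config, b)
        if not finalists:
            break
        # winner = finalist with the strongest combined evidence: training
        # enrichment p plus hold-out score p.  Training p alone is inflated
        # by selection (seed, members and cutoff all minimize it), while the
        # hold-out score alone is noisy; their sum separates real motifs
        # (strong on both) from lucky word sets (strong on at most one).
        scored = [
            (score_motif(e, pooled, primary, score_tables, config), rank, e)
            for rank, (e, _) in enumerate(finalists)
        ]
        scored.sort(key=lambda t: (t[0] + t[2].logp, t[1]))
        log_p_score, _, enriched = scored[0]
        prior = np.full(pooled.L, 1.0 / pooled.L) if config.uniform_prior else b
        pwm = PWM(update_pwm_mle(enriched.members, prior, config.rho).matrix, b, config.rho)

        occupied = np.unique(pooled.occ[enriched.accepted_rows])
        occ_by_sec = {}
        for sec, g in pooled.graphs.items():
            off = pooled.offsets[sec]
            sel = occupied[(occupied >= off) & (occupied < off + g.n_nodes)] - off
            occ_by_sec[sec] = sel
        results.append(MotifResult(
            pwm=pwm,
            members=enriched.members,
            score_threshold=enriched.threshold,
            log_p_train=enriched.logp,
            log_p_score=log_p_score,
            occupied_nodes=occ_by_sec,
            rank=len(results) + 1,
            n_sites=int(len(enriched.accepted_rows)),
        ))
        erase_motif(pooled, occupied, train_labels + score_labels)
        if config.stop_logp is not None and log_p_score > config.stop_logp:
            break
    return results


def motif_frequency_matrix(
    graphs: dict, paths_by_sec: dict, motifs: list[MotifResult], W: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sections x motifs matrix of per-section member-word ZNIC counts, plus
    the pairwise Pearson correlation between section rows (the structural
    fingerprint used to cluster tissues)."""
    if len(graphs) < 2:
        raise ValueError("section correlation requires at least two sections")
    secs = list(graphs)
    L = int(max(int(g.labels.max(initial=0)) for g in graphs.values()))
    member_codes = [
        encode_words(np.array([m.word for m in motif.members], dtype=np.int64), L)
        for motif in motifs
    ]
    mat = np.zeros((len(secs), len(motifs)))
    for i, sec in enumerate(secs):
        g = graphs[sec]
        ps = paths_by_sec[sec]
        occ = extract_wmers(add_reverses(ps), W) if len(ps) else np.empty((0, W), dtype=np.int64)
        table = build_seed_table(occ, g.labels, L, g.n_nodes)
        for j in range(len(motifs)):
            mat[i, j] = table.lookup(member_codes[j]).sum()
    keep = mat.any(axis=0)
    if not keep.all():
        warnings.warn("motifs absent from every section excluded from correlation")
    used_mat = mat[:, keep]
    corr = np.corrcoef(used_mat)
    return mat, corr
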