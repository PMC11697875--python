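"""Motif-engine unit tests: ZNIC counting, the negative-binomial seed test,
PWM construction/scoring/update, enrichment mechanics, and small end-to-end
discovery runs."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_graph
from spatialmotif.discovery import (
    PWM,
    DiscoveryConfig,
    SeedMember,
    build_seed_table,
    discover,
    encode_words,
    decode_words,
    extract_wmers,
    initial_pwm,
    lr_score,
    motif_frequency_matrix,
    negbin_log_pvalue,
    update_pwm_mle,
    znic_count,
)
from spatialmotif.graph import NeighborhoodGraph
from spatialmotif.nulls import ControlConfig
from spatialmotif.paths import PathSet, add_reverses, enumerate_paths


# ---------------------------------------------------------------------------
# W-mer extraction
# ---------------------------------------------------------------------------

def _pathset(rows, labels, n=20):
    g = NeighborhoodGraph(
        np.random.RandomState(0).rand(n, 2), np.asarray(labels),
        [(i, i + 1) for i in range(n - 1)], "s",
    )
    return PathSet(np.asarray(rows), g)


def test_extract_wmers_window_counts():
    labels = np.arange(1, 21)
    ps = _pathset([[0, 1, 2, 3]], labels)
    assert extract_wmers(ps, 4).shape == (1, 4)
    ps5 = _pathset([[0, 1, 2, 3, 4]], labels)
    assert extract_wmers(ps5, 3).shape == (3, 3)
    with pytest.raises(ValueError):
        extract_wmers(ps, 5)


def test_extract_wmers_reverse_augmented_words():
    labels = np.arange(1, 21)
    ps = add_reverses(_pathset([[0, 1, 2]], labels))
    occ = extract_wmers(ps, 3)
    words = labels[occ]
    assert {tuple(w) for w in words} == {(1, 2, 3), (3, 2, 1)}


# ---------------------------------------------------------------------------
# ZNIC counting
# ---------------------------------------------------------------------------

def test_znic_basic_overlap_rules():
    count, sel = znic_count([(1, 2, 3), (3, 4, 5)])
    assert count == 1 and sel == [(1, 2, 3)]
    count, sel = znic_count([(1, 2, 3), (4, 5, 6)])
    assert count == 2


def _max_disjoint(occs):
    best = 0
    for r in range(len(occs), 0, -1):
        for combo in itertools.combinations(occs, r):
            nodes = [n for occ in combo for n in occ]
            if len(nodes) == len(set(nodes)):
                return r
    return best


@pytest.mark.parametrize("seed", range(10))
def test_znic_greedy_vs_exact_maximum(seed):
    """Greedy count >= exact maximum / 2 and the selection is maximal."""
    rng = np.random.default_rng(seed)
    occs = [tuple(rng.choice(12, size=3, replace=False)) for _ in range(10)]
    count, sel = znic_count(occs)
    exact = _max_disjoint(occs)
    assert count >= exact / 2
    used = {n for occ in sel for n in occ}
    for occ in occs:  # maximality: nothing addable remains
        assert used.intersection(occ)


def test_seed_table_matches_scalar_znic():
    """The vectorized table agrees with the scalar greedy on every word
    (occurrences scanned in their deterministic input order per word)."""
    rng = np.random.default_rng(3)
    occ = rng.integers(0, 30, size=(200, 3)).astype(np.int64)
    occ = occ[np.array([len(set(r)) == 3 for r in occ])]
    labels = rng.integers(1, 4, 30).astype(np.int32)
    table = build_seed_table(occ, labels, 3, 30)
    words = labels[occ]
    by_word = {}
    for i in range(len(occ)):  # stable sort keeps input order within a word
        by_word.setdefault(tuple(words[i]), []).append(tuple(occ[i]))
    for code, znic in zip(table.codes, table.znic):
        word = tuple(decode_words(np.array([code]), 3, 3)[0])
        assert znic_count(by_word[word])[0] == znic
    assert table.total == table.znic.sum()


def test_erased_windows_dropped():
    occ = np.array([[0, 1, 2], [3, 4, 5]], dtype=np.int64)
    labels = np.array([1, 1, 1, 1, 0, 1], dtype=np.int32)
    table = build_seed_table(occ, labels, 2, 6)
    assert table.total == 1  # the window touching the erased node is gone


# ---------------------------------------------------------------------------
# negative-binomial seed test
# ---------------------------------------------------------------------------

def _negbin_oracle(y0, w0, y, w, alpha=None, beta=None):
    """Textbook survival sum of the negative-binomial predictive, written
    from the definition with lgamma terms."""
    alpha = y0 if alpha is None else alpha
    beta = w0 if beta is None else beta
    a_n = alpha + sum(y)
    b_n = beta + sum(w)
    p_n = w0 / (b_n + w0)
    if y0 == 0:
        return 0.0
    total = 0.0
    k = y0
    while True:
        lt = (math.lgamma(a_n + k) - math.lgamma(k + 1) - math.lgamma(a_n)
              + k * math.log(p_n) + a_n * math.log(1 - p_n))
        term = math.exp(lt)
        total += term
        if term < total * 1e-16 and k > y0 + 10:
            break
        k += 1
    return math.log10(total)


def test_negbin_worked_example():
    """y0=3, y=[1,1], w0=w1=w2=100, alpha=3, beta=100 -> shape 5, p_n=1/4."""
    got = negbin_log_pvalue(3, 100, [1, 1], [100, 100], alpha=3, beta=100)
    assert got == pytest.approx(math.log10(0.24359130859375), rel=1e-9)


def test_negbin_zero_count_full_support():
    assert negbin_log_pvalue(0, 50, [5], [60]) == 0.0


def test_negbin_validation():
    with pytest.raises(ValueError):
        negbin_log_pvalue(3, 0, [1], [10])
    with pytest.raises(ValueError):
        negbin_log_pvalue(-1, 10, [1], [10])


@pytest.mark.parametrize("seed", range(4))
def test_negbin_matches_oracle_on_random_draws(seed):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        y0 = int(rng.integers(1, 50))
        w0 = float(rng.integers(50, 5000))
        n = int(rng.integers(1, 8))
        y = rng.integers(0, 50, n).tolist()
        w = rng.integers(50, 5000, n).astype(float).tolist()
        got = negbin_log_pvalue(y0, w0, y, w)
        assert got == pytest.approx(_negbin_oracle(y0, w0, y, w), rel=1e-9)


def test_negbin_monotone_in_y0():
    vals = [negbin_log_pvalue(y0, 100, [3, 4], [100, 100]) for y0 in range(1, 30)]
    assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def test_negbin_natural_log_base():
    l10 = negbin_log_pvalue(5, 100, [2], [100])
    ln = negbin_log_pvalue(5, 100, [2], [100], log_base=math.e)
    assert ln == pytest.approx(l10 * math.log(10), rel=1e-12)


# ---------------------------------------------------------------------------
# PWM construction and scoring
# ---------------------------------------------------------------------------

def test_initial_pwm_rho_zero_one_hot():
    pwm = initial_pwm((2, 1), np.full(3, 1 / 3), rho=0.0)
    assert np.allclose(pwm.matrix[:, 0], [0, 1, 0])
    assert np.allclose(pwm.matrix[:, 1], [1, 0, 0])


def test_initial_pwm_formula_hand_computed():
    """L=3, W=1, word (1), uniform b, rho=0.01; column built from the prior
    formula by hand, then renormalized."""
    rho, b = 0.01, 1 / 3
    match = (1 + rho * b) / (1 + rho)
    miss = rho / (1 + rho)
    expected = np.array([match, miss, miss]) / (match + 2 * miss)
    pwm = initial_pwm((1,), np.full(3, b), rho=rho)
    assert np.allclose(pwm.matrix[:, 0], expected, atol=1e-12)


def test_pwm_columns_stochastic_and_validation():
    pwm = initial_pwm((1, 2, 3), np.array([0.5, 0.3, 0.2]), rho=0.01)
    assert np.allclose(pwm.matrix.sum(axis=0), 1.0)
    with pytest.raises(ValueError):
        initial_pwm((1,), np.full(3, 1 / 3), rho=-0.1)
    with pytest.raises(ValueError):
        initial_pwm((4,), np.full(3, 1 / 3))
    with pytest.raises(ValueError):
        PWM(np.array([[0.5, 0.2], [0.6, 0.8]]), np.array([0.5, 0.5]))


def test_lr_score_closed_forms():
    L = 4
    b = np.full(L, 1 / L)
    pwm = initial_pwm((2, 3), b, rho=0.0)
    # perfect match of the one-hot seed scores W * log(L)
    assert lr_score(pwm, (2, 3)) == pytest.approx(2 * math.log(L))
    uniform = PWM(np.full((L, 2), 1 / L), b)
    for word in itertools.product(range(1, L + 1), repeat=2):
        assert lr_score(uniform, word) == pytest.approx(0.0)
    assert lr_score(uniform, (0, 1)) == -math.inf


def test_lr_score_consensus_is_maximum():
    rng = np.random.default_rng(2)
    M = rng.random((4, 3))
    M /= M.sum(axis=0)
    pwm = PWM(M, np.full(4, 0.25))
    best = max(
        itertools.product(range(1, 5), repeat=3), key=lambda w: lr_score(pwm, w)
    )
    assert tuple(best) == pwm.consensus


def test_update_pwm_mle_cases():
    b = np.full(2, 0.5)
    m1 = SeedMember(word=(1, 2), Z=5, N=5, P=-8.0)
    pwm = update_pwm_mle([m1], b, rho=0.0)
    assert np.allclose(pwm.matrix, [[1, 0], [0, 1]])
    # duplicated member: weights add, normalization absorbs
    pwm2 = update_pwm_mle([m1, m1], b, rho=0.0)
    assert np.allclose(pwm.matrix, pwm2.matrix)
    # two equally weighted one-column members -> (0.5, 0.5)
    ma = SeedMember(word=(1,), Z=3, N=3, P=-5.0)
    mb = SeedMember(word=(2,), Z=3, N=3, P=-5.0)
    assert np.allclose(update_pwm_mle([ma, mb], b, rho=0.0).matrix[:, 0], [0.5, 0.5])
    with pytest.raises(ValueError):
        update_pwm_mle([], b)
    with pytest.raises(ValueError):
        update_pwm_mle([SeedMember(word=(1,), Z=0, N=3, P=-5.0)], b)


# ---------------------------------------------------------------------------
# enrichment cutoff selection
# ---------------------------------------------------------------------------

def test_cutoff_default_vs_differential():
    """Cumulative p-series [-10, -11, -9, -13]: the default mode takes the
    global minimum (-13); differential mode stops before the first
    non-improvement (-11)."""
    from spatialmotif.discovery import _select_cutoff

    series = np.array([-10.0, -11.0, -9.0, -13.0])
    assert _select_cutoff(series, differential=False) == 3
    assert _select_cutoff(series, differential=True) == 1
    assert _select_cutoff(np.array([-4.0]), differential=True) == 0


# ---------------------------------------------------------------------------
# end-to-end discovery on small synthetic graphs
# ---------------------------------------------------------------------------

def _embedded_graph(n=2000, f=0.06, seed=3, embed_seed=5, section="s"):
    """Random Delaunay graph with the benchmark's degenerate (A/B)CDE
    pattern embedded on node-disjoint radial paths."""
    from spatialmotif.benchmark import (
        EmbeddingSpec, background_frequencies, embed_patterns,
        generate_random_graph, parse_pattern,
    )

    G = generate_random_graph(n, seed=seed)
    paths = enumerate_paths(G, 4, radial=True)
    spec = EmbeddingSpec(pattern=parse_pattern("(A/B)CDE"), f=f, L=12, seed=embed_seed)
    labels, truth, gt = embed_patterns(G, spec, radial_paths=paths)
    g = NeighborhoodGraph(G.coords, labels, G.edges, section)
    return g, PathSet(paths.nodes, g), gt, background_frequencies(12)


def test_discover_recovers_embedded_word():
    from spatialmotif.benchmark import best_pwm_correlation

    g, paths, gt, b = _embedded_graph()
    cfg = DiscoveryConfig(W=4, max_motifs=1, stop_logp=None, background=b)
    motifs = discover({"s": g}, cfg, ControlConfig(n_train=10, n_score=20, seed=1),
                      paths_by_sec={"s": paths})
    assert len(motifs) == 1
    assert best_pwm_correlation(motifs[0].pwm, gt) > 0.9
    assert motifs[0].log_p_train < -3


def test_discover_deterministic():
    g, paths, _, b = _embedded_graph(n=1200, f=0.08)
    cfg = DiscoveryConfig(W=4, max_motifs=2, stop_logp=None, background=b)
    runs = [
        discover({"s": g}, cfg, ControlConfig(n_train=5, n_score=10, seed=5),
                 paths_by_sec={"s": paths})
        for _ in range(2)
    ]
    for a, b_ in zip(*runs):
        assert a.consensus == b_.consensus
        assert a.log_p_train == b_.log_p_train
        assert a.log_p_score == b_.log_p_score
        assert np.array_equal(a.pwm.matrix, b_.pwm.matrix)


def test_discover_erasure_removes_motif_sites():
    g, paths, _, b = _embedded_graph(n=1200, f=0.08)
    cfg = DiscoveryConfig(W=4, max_motifs=3, stop_logp=None, background=b)
    motifs = discover({"s": g}, cfg, ControlConfig(n_train=5, n_score=10, seed=1),
                      paths_by_sec={"s": paths})
    assert len(motifs) >= 2
    seen = set()
    for m in motifs:  # erased nodes cannot recur in a later motif
        occ = set(m.occupied_nodes["s"])
        assert not occ & seen
        seen |= occ


def test_discover_max_motifs_zero():
    g, paths, _, _ = _embedded_graph(n=1200)
    cfg = DiscoveryConfig(W=4, max_motifs=0)
    assert discover({"s": g}, cfg, ControlConfig(n_train=2, n_score=2, seed=0),
                    paths_by_sec={"s": paths}) == []


def test_motif_frequency_matrix_clusters_shared_pattern():
    """Two sections carrying the same embedded pattern correlate more with
    each other than either does with a pattern-free section."""
    ga, pa, _, b = _embedded_graph(n=900, f=0.08, seed=21, embed_seed=31, section="a")
    gb, pb, _, _ = _embedded_graph(n=900, f=0.08, seed=22, embed_seed=32, section="b")
    gc, pc, _, _ = _embedded_graph(n=900, f=0.0, seed=23, embed_seed=33, section="c")
    graphs = {"a": ga, "b": gb, "c": gc}
    paths = {"a": pa, "b": pb, "c": pc}
    cfg = DiscoveryConfig(W=4, max_motifs=2, stop_logp=None, background=b)
    motifs = discover(graphs, cfg, ControlConfig(n_train=5, n_score=10, seed=3),
                      paths_by_sec=paths)
    mat, corr = motif_frequency_matrix(graphs, paths, motifs, 4)
    assert mat.shape == (3, len(motifs))
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)
    off = corr[np.triu_indices_from(corr, 1)]
    assert corr[0, 1] == off.max()


def test_motif_frequency_matrix_single_section_rejected():
    g, _, _, _ = _embedded_graph(n=900)
    with pytest.raises(ValueError, match="two sections"):
        motif_frequency_matrix({"s": g}, {}, [], 4)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.lists(st.integers(0, 15), min_size=3, max_size=3, unique=True).map(tuple),
        min_size=0, max_size=12,
    )
)
def test_znic_invariants_property(occs):
    """ZNIC selection invariants for arbitrary occurrence lists: selected
    subset is node-disjoint, maximal, counted correctly, never larger than
    the input."""
    count, sel = znic_count(occs)
    assert count == len(sel) <= len(occs)
    used = [n for occ in sel for n in occ]
    assert len(used) == len(set(used))  # pairwise node-disjoint
    for occ in occs:  # maximality
        assert set(used) & set(occ) or occ in sel
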