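import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

from rtsig.errors import ValidationError
from rtsig.io import ExpressionMatrix
from rtsig.nmf import (_cophenetic_of_consensus, consensus_cluster,
                       hierarchical_cluster, nmf_factorize, pac,
                       pearson_distance, select_rank)


def two_block_matrix(n_genes=60, per_group=8, effect=3.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 9, size=n_genes)
    x = base[:, None] + rng.normal(0, noise, (n_genes, 2 * per_group))
    x[: n_genes // 2, :per_group] += effect
    x[n_genes // 2:, per_group:] += effect
    cols = [f"A{i}" for i in range(per_group)] + \
        [f"B{i}" for i in range(per_group)]
    return x, cols


def test_rank1_exact_reconstruction():
    V = np.array([[1.0, 2.0], [2.0, 4.0]])
    res = nmf_factorize(V, rank=1, seed=0, max_iter=500, tol=1e-12)
    assert res.objective_trace[-1] < 1e-6


def test_objective_trace_non_increasing(rng):
    V = rng.uniform(0, 5, size=(30, 12))
    res = nmf_factorize(V, rank=3, seed=4, max_iter=150, tol=0.0)
    diffs = np.diff(res.objective_trace)
    assert (diffs <= 1e-8 * (1 + res.objective_trace[:-1])).all()


def test_factorization_deterministic(rng):
    V = rng.uniform(0, 5, size=(20, 10))
    a = nmf_factorize(V, rank=2, seed=7)
    b = nmf_factorize(V, rank=2, seed=7)
    np.testing.assert_array_equal(a.W, b.W)
    np.testing.assert_array_equal(a.H, b.H)


def test_negative_input_rejected():
    with pytest.raises(ValidationError):
        nmf_factorize(np.array([[1.0, -0.1], [0.5, 2.0]]), rank=1)


def test_best_of_restarts_no_worse(rng):
    V = rng.uniform(0, 5, size=(40, 15))
    single = nmf_factorize(V, rank=3, seed=5)
    multi = nmf_factorize(V, rank=3, seed=5, n_init=8)
    assert multi.objective_trace[-1] <= single.objective_trace[-1] * 1.001


def test_matches_sklearn_fit_quality(rng):
    """Independent cross-check: our multiplicative updates reach a fit
    comparable to scikit-learn's NMF on the same matrix."""
    from sklearn.decomposition import NMF

    V = rng.uniform(0, 5, size=(50, 20))
    ours = nmf_factorize(V, rank=3, seed=2, max_iter=500, tol=1e-9,
                         n_init=5)
    sk = NMF(n_components=3, init="random", random_state=0, max_iter=1000,
             solver="mu", tol=1e-9).fit(V)
    sk_err = np.linalg.norm(V - sk.transform(V) @ sk.components_) ** 2
    assert ours.objective_trace[-1] <= sk_err * 1.05


# ---------------------------------------------------------------------------
# PAC
# ---------------------------------------------------------------------------

def _consensus_from_offdiag(offdiag):
    n = 4
    c = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    c[iu] = offdiag
    c[(iu[1], iu[0])] = offdiag
    return c


def test_pac_binary_consensus_is_zero():
    c = _consensus_from_offdiag([0, 1, 0, 1, 0, 1])
    assert pac(c) == 0.0


def test_pac_all_ambiguous_is_one():
    c = _consensus_from_offdiag([0.5] * 6)
    assert pac(c) == 1.0


def test_pac_enumerated_example():
    c = _consensus_from_offdiag([0, 0.2, 0.5, 0.5, 0.8, 1])
    assert pac(c, 0.1, 0.9) == pytest.approx(4 / 6)


def test_pac_bad_bounds_rejected():
    with pytest.raises(ValidationError):
        pac(np.eye(3), lower=0.9, upper=0.1)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=6, max_size=6),
       st.floats(0.05, 0.45), st.floats(0.55, 0.95),
       st.floats(0.0, 0.049), st.floats(0.951, 1.0))
def test_pac_monotone_in_bounds(offdiag, lo, hi, lo2, hi2):
    c = _consensus_from_offdiag(offdiag)
    assert pac(c, lo2, hi2) >= pac(c, lo, hi) - 1e-12


def brute_pac(c, lower=0.1, upper=0.9):
    vals = [c[i][j] for i in range(len(c)) for j in range(i + 1, len(c))]
    return (sum(v <= upper for v in vals) - sum(v <= lower for v in vals)) \
        / len(vals)


def test_pac_matches_brute_force(rng):
    for _ in range(20):
        n = int(rng.integers(3, 20))
        offdiag = rng.uniform(0, 1, n * (n - 1) // 2)
        c = np.ones((n, n))
        iu = np.triu_indices(n, k=1)
        c[iu] = offdiag
        c[(iu[1], iu[0])] = offdiag
        assert pac(c) == pytest.approx(brute_pac(c))


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------

def test_consensus_two_blocks_clean():
    x, cols = two_block_matrix()
    res = consensus_cluster(x, rank=2, n_runs=20, seed=0, sample_ids=cols)
    offdiag = res.consensus[np.triu_indices(len(cols), k=1)]
    assert np.all((offdiag <= 0.1) | (offdiag >= 0.9))
    assert res.cophenetic > 0.99
    assert res.pac < 0.01


def test_consensus_invariants(rng):
    V = rng.uniform(0, 5, size=(30, 10))
    res = consensus_cluster(V, rank=2, n_runs=5, seed=1)
    c = res.consensus
    np.testing.assert_allclose(c, c.T)
    np.testing.assert_allclose(np.diag(c), 1.0)
    assert c.min() >= 0 and c.max() <= 1


def test_consensus_needs_two_runs(rng):
    with pytest.raises(ValidationError):
        consensus_cluster(rng.uniform(0, 1, (10, 6)), rank=2, n_runs=1)


def test_perfect_block_consensus_cophenetic_is_one():
    c = np.ones((6, 6)) * 0.0
    c[:3, :3] = 1.0
    c[3:, 3:] = 1.0
    assert _cophenetic_of_consensus(c) == pytest.approx(1.0)


def test_select_rank_two_blocks():
    x, _ = two_block_matrix()
    sel = select_rank(x, ranks=[2, 3, 4], n_runs=15, seed=0)
    assert sel.rank == 2
    assert not sel.weak_structure


def test_select_rank_single_candidate():
    x, _ = two_block_matrix()
    sel = select_rank(x, ranks=[2], n_runs=5, seed=0)
    assert sel.rank == 2


def test_select_rank_structureless_flags_weak(rng):
    V = rng.uniform(0, 1, size=(40, 16))
    with pytest.warns(UserWarning, match="weak"):
        sel = select_rank(V, ranks=[2, 3], n_runs=10, seed=3)
    assert sel.weak_structure


def test_select_rank_empty_rejected(rng):
    with pytest.raises(ValidationError):
        select_rank(rng.uniform(0, 1, (10, 6)), ranks=[])


# ---------------------------------------------------------------------------
# Hierarchical clustering on 1 - Pearson
# ---------------------------------------------------------------------------

def brute_average_linkage_heights(D):
    """Naive agglomerative average linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def test_linkage_matches_brute_force(rng):
    x = rng.normal(size=(15, 12))   # 12 samples, 15 genes
    m = ExpressionMatrix(pd.DataFrame(
        x, index=[f"G{i}" for i in range(15)],
        columns=[f"S{i}" for i in range(12)]))
    _, Z = hierarchical_cluster(m, k=2)
    D = pearson_distance(x)
    np.testing.assert_allclose(sorted(Z[:, 2]),
                               brute_average_linkage_heights(D), rtol=1e-9)


def test_duplicate_profiles_always_co_cluster(rng):
    x = rng.normal(size=(20, 5))
    x = np.c_[x, x[:, 0]]   # sample 5 duplicates sample 0
    m = ExpressionMatrix(pd.DataFrame(
        x, index=[f"G{i}" for i in range(20)],
        columns=[f"S{i}" for i in range(6)]))
    for k in (2, 3):
        labels, _ = hierarchical_cluster(m, k=k)
        assert labels["S0"] == labels["S5"]


def test_two_block_cohort_recovers_truth():
    x, cols = two_block_matrix()
    m = ExpressionMatrix(pd.DataFrame(
        x, index=[f"G{i}" for i in range(x.shape[0])], columns=cols))
    labels, _ = hierarchical_cluster(m, k=2)
    groups = {labels[c] for c in cols[:8]}, {labels[c] for c in cols[8:]}
    assert len(groups[0]) == 1 and len(groups[1]) == 1
    assert groups[0] != groups[1]


def test_zero_variance_sample_named(rng):
    x = rng.normal(size=(10, 3))
    x[:, 1] = 4.2
    m = ExpressionMatrix(pd.DataFrame(
        x, index=[f"G{i}" for i in range(10)], columns=["A", "BAD", "C"]))
    with pytest.raises(ValidationError, match="BAD"):
        hierarchical_cluster(m, k=2)


def test_sample_permutation_consistency():
    x, cols = two_block_matrix(seed=5)
    m = ExpressionMatrix(pd.DataFrame(
        x, index=[f"G{i}" for i in range(x.shape[0])], columns=cols))
    perm = np.random.default_rng(2).permutation(len(cols))
    m2 = ExpressionMatrix(m.data.iloc[:, perm])
    la, _ = hierarchical_cluster(m, k=2)
    lb, _ = hierarchical_cluster(m2, k=2)
    # same partition up to cluster relabeling
    pairs = {(la[a] == la[b]) == (lb[a] == lb[b])
             for a in cols for b in cols}
    assert pairs == {True}
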