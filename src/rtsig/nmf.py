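"""Consensus non-negative matrix factorization and rank diagnostics.

The expression matrix V (genes x samples, shifted to be non-negative) is
factorized as V ~ W H with multiplicative updates minimising the squared
Frobenius error.  Repeating the factorization from many random starts and
recording how often pairs of samples land in the same metagene-defined
cluster yields a consensus matrix, whose cophenetic correlation and
proportion of ambiguous clustering (PAC) diagnose cluster stability and
drive the choice of the number of groups.

Cluster membership of a sample in one run is the argmax over its column
of H, the standard consensus-clustering convention.  PAC is the mass of
consensus entries falling strictly between two empirical-CDF evaluation
points, (0.1, 0.9) by default: PAC_k = CDF_k(upper) - CDF_k(lower).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import ExpressionMatrix

_EPS = 1e-10


@dataclass
class NMFResult:
    W: np.ndarray                 # genes x rank, non-negative
    H: np.ndarray                 # rank x samples, non-negative
    rank: int
    objective_trace: np.ndarray   # squared Frobenius error per iteration
    seed: int

    @property
    def sample_clusters(self) -> np.ndarray:
        """Cluster id per sample: argmax metagene of H."""
        return self.H.argmax(axis=0)


@dataclass
class ConsensusResult:
    rank: int
    consensus: np.ndarray         # samples x samples, symmetric, unit diagonal
    cophenetic: float
    pac: float
    n_runs: int
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        c = self.consensus
        if not np.allclose(c, c.T):
            raise ValidationError("consensus matrix is not symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValidationError("consensus diagonal is not 1")
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValidationError("consensus entries outside [0, 1]")


@dataclass
class RankSelection:
    rank: int
    results: list[ConsensusResult]
    weak_structure: bool

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": [r.rank for r in self.results],
            "pac": [r.pac for r in self.results],
            "cophenetic": [r.cophenetic for r in self.results],
            "n_runs": [r.n_runs for r in self.results],
        })


def _as_nonnegative(V: np.ndarray) -> np.ndarray:
    """Min-shift a matrix per call so NMF sees non-negative input."""
    lo = V.min()
    return V - lo if lo < 0 else V


def nmf_factorize(V: np.ndarray, rank: int, seed: int = 0,
                  max_iter: int = 200, tol: float = 1e-4,
                  n_init: int = 1) -> NMFResult:
    """Multiplicative-update NMF minimising ||V - WH||_F^2.

    W and H start from uniform(0, 1] entries scaled by mean(V); the update
    rules guarantee a non-increasing objective, and iteration stops when
    the relative objective change drops below ``tol``.  With ``n_init`` > 1
    the factorization is restarted from that many random initialisations
    (seeds derived from ``seed``) and the best fit — lowest final
    objective — is returned, the usual guard against local optima.
    """
    if n_init > 1:
        init_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1,
                                                          size=n_init)
        runs = [nmf_factorize(V, rank, seed=int(s), max_iter=max_iter,
                              tol=tol) for s in init_seeds]
        return min(runs, key=lambda r: r.objective_trace[-1])
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValidationError("NMF input must be non-negative")
    n, m = V.shape
    if not 1 <= rank < min(n, m) + 1:
        raise ValidationError(f"rank {rank} out of range for shape {V.shape}")
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    # uniform over (0, 1]: avoids exactly-zero factors that MU cannot leave
    W = (1.0 - rng.random((n, rank))) * scale
    H = (1.0 - rng.random((rank, m))) * scale

    trace = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        trace.append(err)
        if prev is not None and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return NMFResult(W=W, H=H, rank=rank,
                     objective_trace=np.asarray(trace), seed=seed)


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering of a consensus matrix.

    Empirical CDF of the off-diagonal upper-triangle entries, evaluated at
    ``upper`` minus at ``lower``.
    """
    if not 0 <= lower < upper <= 1:
        raise ValidationError(f"need 0 <= lower < upper <= 1, got "
                              f"({lower}, {upper})")
    c = np.asarray(consensus, dtype=float)
    iu = np.triu_indices(c.shape[0], k=1)
    entries = c[iu]
    if entries.size == 0:
        return 0.0
    return float(np.mean(entries <= upper) - np.mean(entries <= lower))


def _cophenetic_of_consensus(consensus: np.ndarray) -> float:
    """Pearson correlation between (1 - consensus) dissimilarities and the
    cophenetic distances of their average-linkage dendrogram."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0]):
        # all pairwise dissimilarities equal: trivially ultrametric
        return 1.0
    Z = sch.linkage(condensed, method="average")
    c, _ = sch.cophenet(Z, condensed)
    return float(c)


def consensus_cluster(V: np.ndarray, rank: int, n_runs: int = 50,
                      seed: int = 0, max_iter: int = 200, tol: float = 1e-4,
                      sample_ids: list[str] | None = None,
                      pac_bounds: tuple[float, float] = (0.1, 0.9),
                      ) -> ConsensusResult:
    """Consensus matrix over repeated randomly initialised NMF runs.

    Entry (i, j) is the fraction of runs in which samples i and j were
    assigned the same argmax metagene.
    """
    if n_runs < 2:
        raise ValidationError("consensus needs at least 2 runs")
    V = _as_nonnegative(np.asarray(V, dtype=float))
    m = V.shape[1]
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    co = np.zeros((m, m))
    for s in run_seeds:
        res = nmf_factorize(V, rank, seed=int(s), max_iter=max_iter, tol=tol)
        labels = res.sample_clusters
        co += (labels[:, None] == labels[None, :]).astype(float)
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    return ConsensusResult(
        rank=rank, consensus=consensus,
        cophenetic=_cophenetic_of_consensus(consensus),
        pac=pac(consensus, *pac_bounds),
        n_runs=n_runs, sample_ids=sample_ids)


def select_rank(V: np.ndarray, ranks: list[int], n_runs: int = 50,
                seed: int = 0, max_iter: int = 200, tol: float = 1e-4,
                pac_bounds: tuple[float, float] = (0.1, 0.9),
                weak_pac: float = 0.1) -> RankSelection:
    """Choose the factorization rank minimising PAC.

    Ties are broken by higher cophenetic correlation, then by lower rank.
    When even the best rank leaves PAC above ``weak_pac`` the selection is
    flagged as weak structure (no rank yields unambiguous co-clustering).
    """
    if not ranks:
        raise ValidationError("empty rank list")
    rng = np.random.default_rng(seed)
    results = []
    for r in sorted(ranks):
        rank_seed = int(rng.integers(0, 2**31 - 1))
        results.append(consensus_cluster(
            V, r, n_runs=n_runs, seed=rank_seed, max_iter=max_iter,
            tol=tol, pac_bounds=pac_bounds))
    best = min(results, key=lambda c: (c.pac, -c.cophenetic, c.rank))
    weak = best.pac > weak_pac
    if weak:
        warnings.warn("no rank gives unambiguous consensus (weak structure)",
                      stacklevel=2)
    return RankSelection(rank=best.rank, results=results, weak_structure=weak)


# ---------------------------------------------------------------------------
# Hierarchical clustering on 1 - Pearson correlation
# ---------------------------------------------------------------------------

def pearson_distance(values: np.ndarray, sample_ids: list[str] | None = None,
                     ) -> np.ndarray:
    """Sample x sample distance matrix d = 1 - Pearson correlation."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0)
    scale = max(1.0, float(np.abs(values).max(initial=0.0)))
    degenerate = sd <= 1e-12 * scale
    if degenerate.any():
        idx = int(np.argmax(degenerate))
        name = sample_ids[idx] if sample_ids else f"column {idx}"
        raise ValidationError(
            f"zero-variance sample {name}: correlation distance undefined")
    d = 1.0 - np.corrcoef(values.T)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def hierarchical_cluster(matrix: ExpressionMatrix, k: int,
                         ) -> tuple[dict[str, int], np.ndarray]:
    """Average-linkage clustering on 1 - Pearson distance, cut into k groups.

    Returns a sample -> cluster-id map (ids 1..k) and the linkage matrix
    encoding the dendrogram.
    """
    samples = matrix.sample_ids
    if len(samples) < k:
        raise ValidationError(f"cannot cut {len(samples)} samples into {k}")
    d = pearson_distance(matrix.values, samples)
    Z = sch.linkage(squareform(d, checks=False), method="average")
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(samples, (int(c) for c in flat))), Z
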