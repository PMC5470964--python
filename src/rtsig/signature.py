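"""Differential signatures: NMF metagene contrast and Welch t-tests.

Two parallel routes define the rhabdoid (RT) vs non-rhabdoid (SD-NRT)
signature: a metagene-contrast score on the basis matrix of a rank-2
factorization, and per-gene Welch t-tests with Benjamini-Hochberg
correction.  Their overlap quantifies the concordance of the two routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix

_EPS = 1e-12


@dataclass
class SignatureGeneSet:
    """Class-labelled, score-ordered gene lists (RT-up and SD-NRT-up)."""

    rt_up: list[tuple[str, float]]
    nrt_up: list[tuple[str, float]]
    method: str

    def __post_init__(self) -> None:
        rt = {g for g, _ in self.rt_up}
        nrt = {g for g, _ in self.nrt_up}
        if rt & nrt:
            raise ValidationError(f"genes in both classes: {sorted(rt & nrt)[:5]}")
        for lst in (self.rt_up, self.nrt_up):
            scores = [s for _, s in lst]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValidationError("scores must be sorted descending")

    @property
    def rt_genes(self) -> list[str]:
        return [g for g, _ in self.rt_up]

    @property
    def nrt_genes(self) -> list[str]:
        return [g for g, _ in self.nrt_up]

    @property
    def genes(self) -> list[str]:
        return self.rt_genes + self.nrt_genes

    def __len__(self) -> int:
        return len(self.rt_up) + len(self.nrt_up)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "RT_up", s) for g, s in self.rt_up]
        rows += [(g, "NRT_up", s) for g, s in self.nrt_up]
        return pd.DataFrame(rows, columns=["gene_id", "class", "score"])


def metagene_contrast(W: np.ndarray) -> np.ndarray:
    """Per-gene contrast score |w1 - w2| / (w1 + w2) on unit-sum columns.

    0 when both scaled weights are 0; 1 when a gene loads on exactly one
    metagene.  This is the default "most differential by NMF" score; any
    callable with the same signature can replace it.
    """
    W = np.asarray(W, dtype=float)
    col_sums = W.sum(axis=0)
    Wn = W / np.where(col_sums > 0, col_sums, 1.0)
    total = Wn.sum(axis=1)
    diff = np.abs(Wn[:, 0] - Wn[:, 1])
    return np.where(total > 0, diff / np.where(total > 0, total, 1.0), 0.0)


def nmf_signature(W: np.ndarray, H: np.ndarray, gene_ids: list[str],
                  sample_labels: list[str], fraction: float = 0.2,
                  score_fn=metagene_contrast) -> SignatureGeneSet:
    """Select the top ``fraction`` most metagene-contrasted genes.

    Requires a rank-2 factorization (pairwise contrast).  The metagene
    whose H weights dominate among training RT samples defines the RT
    class; each selected gene is assigned to the class of its larger
    scaled basis weight.  Exactly ceil(fraction * n_genes) genes are
    returned.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != 2:
        raise ValidationError("nmf_signature requires a rank-2 basis matrix")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if len(gene_ids) != W.shape[0]:
        raise ValidationError("gene_ids do not match W rows")
    if len(sample_labels) != np.asarray(H).shape[1]:
        raise ValidationError("sample_labels do not match H columns")

    scores = np.asarray(score_fn(W), dtype=float)
    n_top = math.ceil(fraction * len(gene_ids))
    order = np.argsort(-scores, kind="stable")[:n_top]

    rt_mask = np.asarray([lab == "RT" for lab in sample_labels])
    if not rt_mask.any() or rt_mask.all():
        raise ValidationError("sample_labels must contain RT and non-RT")
    H = np.asarray(H, dtype=float)
    # metagene with the larger mean weight over RT samples is the RT metagene
    rt_metagene = int(np.argmax(H[:, rt_mask].mean(axis=1)))

    col_sums = W.sum(axis=0)
    Wn = W / np.where(col_sums > 0, col_sums, 1.0)
    rt_up, nrt_up = [], []
    for i in order:
        entry = (gene_ids[i], float(scores[i]))
        if Wn[i, rt_metagene] >= Wn[i, 1 - rt_metagene]:
            rt_up.append(entry)
        else:
            nrt_up.append(entry)
    return SignatureGeneSet(rt_up=rt_up, nrt_up=nrt_up, method="nmf")


def welch_de(matrix: ExpressionMatrix, rt_samples: list[str],
             alpha: float = 0.05, correction: str = "BH") -> pd.DataFrame:
    """Per-gene Welch t-test of RT samples against all the rest.

    Returns a DataFrame indexed by gene with t statistic (positive when
    RT mean is higher), Welch-Satterthwaite df, two-sided p, BH q (equal
    to p when correction="none"), log2 mean difference, direction, and a
    significance flag (q < alpha).
    """
    if correction not in ("BH", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    rt_set = set(rt_samples)
    samples = matrix.sample_ids
    mask = np.asarray([s in rt_set for s in samples])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValidationError("both groups need at least 2 samples")
    a = matrix.values[:, mask]
    b = matrix.values[:, ~mask]

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]
    se2a, se2b = va / na, vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    # a constant gene in both groups has zero variance: t undefined -> 0, p 1
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    df = np.where(np.isnan(df), na + nb - 2, df)

    if correction == "BH":
        _, q, _, _ = multipletests(p, method="fdr_bh")
    else:
        q = p.copy()
    diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame({
        "t_statistic": t, "df": df, "p_value": p, "q_value": q,
        "mean_diff_log2": diff,
        "direction": np.where(diff >= 0, "RT_up", "NRT_up"),
        "significant": q < alpha,
    }, index=pd.Index(matrix.gene_ids, name="gene_id"))
    table.attrs["alpha"] = alpha
    table.attrs["correction"] = correction
    return table


def pairwise_welch(matrix: ExpressionMatrix, rt_samples: list[str],
                   subtype_samples: list[str], top_n: int = 20,
                   alpha: float = 0.05, correction: str = "BH",
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Welch test of RT against a single subtype, with its top-gene list.

    The comparison is restricted to the named samples; the returned list
    holds the ``top_n`` genes by p-value (all genes when fewer exist).
    """
    sub = matrix.subset_samples(list(rt_samples) + list(subtype_samples))
    table = welch_de(sub, rt_samples, alpha=alpha, correction=correction)
    top = table.sort_values("p_value", kind="stable").index[:top_n]
    return table, list(top)


@dataclass(frozen=True)
class OverlapCounts:
    n_shared: int
    n_a: int
    n_b: int
    by_direction: dict = field(default_factory=dict)


def signature_overlap(sig: SignatureGeneSet, de: pd.DataFrame,
                      alpha: float = 0.05, use_q: bool = True,
                      ) -> OverlapCounts:
    """Count signature genes contained in the Welch-significant list.

    Direction-aware: RT-up signature genes are matched against Welch
    RT-up significant genes, and likewise for SD-NRT.
    """
    col = "q_value" if use_q else "p_value"
    sig_de = de[de[col] < alpha]
    welch_rt = set(sig_de.index[sig_de["direction"] == "RT_up"])
    welch_nrt = set(sig_de.index[sig_de["direction"] == "NRT_up"])
    rt_shared = len(set(sig.rt_genes) & welch_rt)
    nrt_shared = len(set(sig.nrt_genes) & welch_nrt)
    return OverlapCounts(
        n_shared=rt_shared + nrt_shared,
        n_a=len(sig),
        n_b=len(welch_rt) + len(welch_nrt),
        by_direction={"RT_up": rt_shared, "NRT_up": nrt_shared},
    )
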