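"""Gene-set over-representation by the one-sided hypergeometric test.

Used to ask whether a curated set (e.g. imprinted genes) is enriched in a
differential list relative to the universe of genes that survived
filtering.  Equivalent to the one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .errors import ValidationError
from .io import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int       # N
    set_size: int            # K, after intersection with the universe
    list_size: int           # n
    overlap: int             # k
    p_value: float
    fold_enrichment: float
    test: str = "hypergeometric_upper_tail"

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.list_size):
            raise ValidationError("overlap exceeds set or list size")
        if max(self.set_size, self.list_size) > self.universe_size:
            raise ValidationError("set or list larger than universe")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p outside [0, 1]")


def overrepresentation_test(de_genes: Iterable[str], gene_set: GeneSet,
                            universe: Iterable[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) for the overlap of a list with
    a gene set inside a universe.

    ``de_genes`` must be a subset of the universe; the gene set is
    intersected with the universe before testing.  Fold enrichment is
    (k/n) / (K/N).
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValidationError("empty universe")
    if not de:
        raise ValidationError("empty differential list")
    outside = de - universe
    if outside:
        raise ValidationError(
            f"differential genes outside the universe: {sorted(outside)[:5]}")
    K_set = set(gene_set.genes) & universe
    N, K, n = len(universe), len(K_set), len(de)
    k = len(de & K_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else float("inf") if k > 0 else 0.0
    return EnrichmentResult(universe_size=N, set_size=K, list_size=n,
                            overlap=k, p_value=min(p, 1.0),
                            fold_enrichment=fold)
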