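"""Exome variant filter cascade and copy-number summaries.

The cascade mirrors a tumor-sequencing workflow downstream of calling and
annotation: a basic quality/depth/supporting-read filter, a population
polymorphism filter, removal of synonymous changes, then either matched
tumor/normal allele-fraction rules or, for tumors without a constitutional
sample, an evidence rescue (COSMIC id or recurrently mutated gene).  All
boundary semantics are strict: quality *under* 20, depth *under* 10,
*less than* 5 supporting reads, *more than* 1% population frequency.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

SOMATIC_HET = "somatic_het"
SOMATIC_HOM_ALT = "somatic_hom_alt"
REJECTED = "rejected"


@dataclass
class VariantRecord:
    """One candidate variant with the annotations the cascade consumes.

    ``vaf_tumor``/``vaf_normal`` are alt-supporting reads over depth (x).
    ``pop_freqs`` maps {"1000g", "ESP6500", "ExAC"} to frequencies when
    reported.  ``predictor_calls`` maps effect predictors to
    damaging/benign/unknown.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: float
    depth_tumor: int
    alt_reads_tumor: int
    vaf_tumor: float
    gene: str | None = None
    sample_id: str | None = None
    depth_normal: int | None = None
    alt_reads_normal: int | None = None
    vaf_normal: float | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    synonymous: bool = False
    cosmic_id: str | None = None
    predictor_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError("positions are 1-based: pos >= 1")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        if self.alt_reads_tumor > self.depth_tumor:
            raise ValidationError("alt reads exceed tumor depth")
        if not 0.0 <= self.vaf_tumor <= 1.0:
            raise ValidationError("tumor VAF outside [0, 1]")
        if self.vaf_normal is not None and not 0.0 <= self.vaf_normal <= 1.0:
            raise ValidationError("normal VAF outside [0, 1]")

    @property
    def has_normal(self) -> bool:
        return (self.vaf_normal is not None
                and self.alt_reads_normal is not None)


def basic_filter(v: VariantRecord) -> bool:
    """Keep iff quality >= 20, tumor depth >= 10, >= 5 supporting reads."""
    return (v.quality >= 20.0 and v.depth_tumor >= 10
            and v.alt_reads_tumor >= 5)


def polymorphism_filter(v: VariantRecord) -> bool:
    """Keep iff no reported population frequency exceeds 1%.

    A missing frequency counts as not reported, never as zero or as a
    rejection.
    """
    return all(f <= 0.01 for f in v.pop_freqs.values())


def _all_available_benign(v: VariantRecord) -> bool:
    calls = [c for c in v.predictor_calls.values() if c is not None]
    return bool(calls) and all(c == "benign" for c in calls)


def somatic_filter(v: VariantRecord, apply_predictors: bool = True) -> str:
    """Classify a matched-pair variant by tumor/normal allele fractions.

    somatic_het: tumor heterozygous (0.1 <= x_t <= 0.8) with the
    constitutional sample homozygous reference (x_n < 0.1 and at most 2
    alt-supporting reads).  somatic_hom_alt: tumor homozygous alternative
    (x_t > 0.8) with the constitutional heterozygous (0.4 <= x_n <= 0.6).
    Anything else — including variants whose every available effect
    predictor calls them benign — is rejected.
    """
    if not v.has_normal:
        raise ValidationError(
            "missing normal fields: use unmatched_filter for this record")
    if apply_predictors and _all_available_benign(v):
        return REJECTED
    xt, xn = v.vaf_tumor, v.vaf_normal
    if 0.1 <= xt <= 0.8 and xn < 0.1 and v.alt_reads_normal <= 2:
        return SOMATIC_HET
    if xt > 0.8 and 0.4 <= xn <= 0.6:
        return SOMATIC_HOM_ALT
    return REJECTED


def unmatched_filter(v: VariantRecord,
                     recurrent_genes: Iterable[str] = ()) -> bool:
    """Rescue rule for tumors without a constitutional sample.

    Keep iff the variant carries a COSMIC id or hits a gene found mutated
    in the matched tumors.
    """
    recurrent = set(recurrent_genes)
    return v.cosmic_id is not None or (v.gene is not None
                                       and v.gene in recurrent)


def run_cascade(records: Sequence[VariantRecord], matched: bool,
                recurrent_genes: Iterable[str] = (),
                apply_predictors: bool = True,
                ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the full filter cascade in its fixed order.

    Order: basic quality/depth filter, polymorphism filter, synonymous
    removal, then the matched somatic rules or the unmatched rescue.
    Returns the kept records and a per-stage attrition table (number of
    records removed at each stage).
    """
    attrition = {"input": len(records), "basic": 0, "polymorphism": 0,
                 "synonymous": 0, "somatic" if matched else "unmatched": 0,
                 "kept": 0}
    kept: list[VariantRecord] = []
    for v in records:
        if not basic_filter(v):
            attrition["basic"] += 1
            continue
        if not polymorphism_filter(v):
            attrition["polymorphism"] += 1
            continue
        if v.synonymous:
            attrition["synonymous"] += 1
            continue
        if matched:
            if somatic_filter(v, apply_predictors=apply_predictors) == REJECTED:
                attrition["somatic"] += 1
                continue
        else:
            ok = unmatched_filter(v, recurrent_genes)
            if ok and apply_predictors and _all_available_benign(v):
                ok = False
            if not ok:
                attrition["unmatched"] += 1
                continue
        kept.append(v)
    attrition["kept"] = len(kept)
    return kept, attrition


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

COPY_STATES = ("loss", "neutral", "gain")


@dataclass(frozen=True)
class CNVSegment:
    sample_id: str
    chrom: str
    start: int      # 1-based inclusive
    end: int
    copy_state: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.sample_id} {self.chrom}: start > end")
        if self.copy_state not in COPY_STATES:
            raise ValidationError(f"unknown copy state {self.copy_state!r}")


def _check_no_overlap(segments: Sequence[CNVSegment]) -> None:
    by_track: dict[tuple[str, str], list[CNVSegment]] = defaultdict(list)
    for s in segments:
        by_track[(s.sample_id, s.chrom)].append(s)
    for (sample, chrom), segs in by_track.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments on {sample}/{chrom} at {b.start}")


def cnv_summary(segments: Sequence[CNVSegment],
                groups: Mapping[str, str] | None = None,
                ) -> tuple[dict[str, int], dict[str, float]]:
    """Per-sample CNV counts (non-neutral segments) and per-group medians.

    ``groups`` maps sample ids to group names; samples present in
    ``groups`` but without any segment count 0.  Overlapping segments on
    one sample/chromosome are a validation error.
    """
    _check_no_overlap(segments)
    counts: dict[str, int] = defaultdict(int)
    for s in segments:
        counts.setdefault(s.sample_id, 0)
        if s.copy_state != "neutral":
            counts[s.sample_id] += 1
    medians: dict[str, float] = {}
    if groups:
        for sample in groups:
            counts.setdefault(sample, 0)
        by_group: dict[str, list[int]] = defaultdict(list)
        for sample, grp in groups.items():
            by_group[grp].append(counts[sample])
        medians = {g: float(np.median(c)) for g, c in by_group.items()}
    return dict(counts), medians


def chromothripsis_flag(segments: Sequence[CNVSegment],
                        min_breakpoints: int = 10,
                        max_chroms: int = 3) -> dict[str, bool]:
    """Flag chromosomes with massive localized rearrangement.

    A breakpoint is a boundary between consecutive segments whose copy
    states differ.  A chromosome is flagged when its breakpoint count
    reaches ``min_breakpoints`` — but only if at most ``max_chroms``
    chromosomes carry any non-neutral segment, i.e. the rearrangement is
    confined to few chromosomes rather than genome-wide instability.
    """
    by_chrom: dict[str, list[CNVSegment]] = defaultdict(list)
    for s in segments:
        by_chrom[s.chrom].append(s)
    affected = [c for c, segs in by_chrom.items()
                if any(s.copy_state != "neutral" for s in segs)]
    breakpoints: dict[str, int] = {}
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        breakpoints[chrom] = sum(
            1 for a, b in zip(segs, segs[1:]) if a.copy_state != b.copy_state)
    few_chroms = len(affected) <= max_chroms
    return {chrom: few_chroms and breakpoints[chrom] >= min_breakpoints
            for chrom in by_chrom}
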