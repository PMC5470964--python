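"""Synthetic cohorts with the statistical structure the pipeline assumes.

The expression generator emulates a two-class tumor cohort: a rhabdoid
(RT) class and a SMARCB1-deficient non-rhabdoid (SD-NRT) class with
ES/RMC/UC substructure, plus a study cohort of the same mixture with
hidden labels.  Noise is additive Gaussian on the log2 scale (the usual
microarray approximation).  A planted differential signature of
configurable effect size separates the classes; disjoint gene blocks
carry subtype-specific effects; a configurable fraction of genes is
forced below the background threshold; part of the RT-up signature is
tagged as an "imprinted" gene set so over-representation is recoverable
by construction.  Study samples may also be drawn from a third,
orthogonal expression profile to model tumors belonging to neither
class.

The variant generator plants classes that target each stage of the
filter cascade: true somatic records satisfy every pass rule, germline
records violate the population-frequency or tumor/normal allele-fraction
rules, artifacts violate the quality/depth/supporting-read rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSet, SampleAnnotation
from .signature import SignatureGeneSet
from .variants import VariantRecord


@dataclass
class SimulationConfig:
    """Cohort sizes, planted effects and noise of the expression generator.

    Training-set sizes default to 16 RT, 8 ES, 5 RMC and 3 UC; the study
    cohort defaults to 37 samples whose hidden composition mirrors the
    molecular re-classification of the real series (16 RT-like, 8
    subtype-like, 13 drawn from an orthogonal profile).  Effects are log2
    shifts; noise_sd is the per-value Gaussian sd on the log2 scale.
    """

    n_rt: int = 16
    n_es: int = 8
    n_rmc: int = 5
    n_uc: int = 3
    n_study_rt: int = 16
    n_study_es: int = 6
    n_study_rmc: int = 1
    n_study_uc: int = 1
    n_study_other: int = 13
    n_genes: int = 2000
    n_signature: int = 200
    effect_size_log2: float = 2.0
    subtype_effect_log2: float = 1.0
    subtype_block_size: int = 50
    other_block_size: int = 100
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    background_fraction: float = 0.2
    background_ceiling: float = 3.45
    imprinted_overlap_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_rt, self.n_es, self.n_rmc, self.n_uc,
                  self.n_study_rt, self.n_study_es, self.n_study_rmc,
                  self.n_study_uc, self.n_study_other)
        if any(c < 0 for c in counts):
            raise ConfigError("cohort sizes must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction must be in [0, 1]")
        if not 0.0 <= self.imprinted_overlap_fraction <= 1.0:
            raise ConfigError("imprinted_overlap_fraction must be in [0, 1]")
        if self.effect_size_log2 < 0 or self.subtype_effect_log2 < 0:
            raise ConfigError("effect sizes must be non-negative")
        n_structured = (self.n_signature + 3 * self.subtype_block_size
                        + self.other_block_size)
        n_background = int(round(self.background_fraction * self.n_genes))
        if n_structured + n_background > self.n_genes:
            raise ConfigError(
                f"signature + subtype + orthogonal blocks ({n_structured}) "
                f"plus background ({n_background}) exceed n_genes "
                f"({self.n_genes})")

    @property
    def n_training(self) -> int:
        return self.n_rt + self.n_es + self.n_rmc + self.n_uc

    @property
    def n_study(self) -> int:
        return (self.n_study_rt + self.n_study_es + self.n_study_rmc
                + self.n_study_uc + self.n_study_other)


@dataclass
class SimulatedCohort:
    matrix: ExpressionMatrix
    annotations: list[SampleAnnotation]
    truth_signature: SignatureGeneSet
    truth_labels: dict[str, str]          # sample -> RT/ES/RMC/UC/OTHER
    imprinted: GeneSet
    config: SimulationConfig

    @property
    def training_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations
                if a.cohort == "training"]

    @property
    def study_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations if a.cohort == "study"]

    @property
    def training_labels(self) -> dict[str, str]:
        return {s: self.truth_labels[s] for s in self.training_ids}

    def training_matrix(self) -> ExpressionMatrix:
        return self.matrix.subset_samples(self.training_ids)

    def study_matrix(self) -> ExpressionMatrix:
        return self.matrix.subset_samples(self.study_ids)


def _sample_plan(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(sample_id, cohort, truth_label) triples, training first."""
    plan = []
    for i in range(config.n_rt):
        plan.append((f"TRT{i + 1:02d}", "training", "RT"))
    for i in range(config.n_es):
        plan.append((f"TES{i + 1:02d}", "training", "ES"))
    for i in range(config.n_rmc):
        plan.append((f"TRMC{i + 1:02d}", "training", "RMC"))
    for i in range(config.n_uc):
        plan.append((f"TUC{i + 1:02d}", "training", "UC"))
    study_labels = (["RT"] * config.n_study_rt + ["ES"] * config.n_study_es
                    + ["RMC"] * config.n_study_rmc
                    + ["UC"] * config.n_study_uc
                    + ["OTHER"] * config.n_study_other)
    for i, lab in enumerate(study_labels):
        plan.append((f"ST{i + 1:02d}", "study", lab))
    return plan


def generate_expression(config: SimulationConfig | None = None,
                        ) -> SimulatedCohort:
    """Draw a full synthetic cohort from the stated generative model.

    Per-gene baselines are uniform over ``baseline_mean_range``; all
    values get N(0, noise_sd) log2 noise.  Half the signature genes are
    shifted +effect in RT samples, half +effect in non-RT tumor samples;
    subtype blocks add ``subtype_effect_log2`` on disjoint genes;
    "other" study samples express an orthogonal block instead of either
    signature half.  Background genes are clamped below the background
    threshold.  Identical config and seed give identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    plan = _sample_plan(config)
    sample_ids = [p[0] for p in plan]
    labels = {p[0]: p[2] for p in plan}

    g = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    n_sig = config.n_signature
    n_rt_up = n_sig // 2
    blk = config.subtype_block_size
    rt_up = list(range(0, n_rt_up))
    nrt_up = list(range(n_rt_up, n_sig))
    es_block = list(range(n_sig, n_sig + blk))
    rmc_block = list(range(n_sig + blk, n_sig + 2 * blk))
    uc_block = list(range(n_sig + 2 * blk, n_sig + 3 * blk))
    other_block = list(range(n_sig + 3 * blk,
                             n_sig + 3 * blk + config.other_block_size))
    n_background = int(round(config.background_fraction * g))
    background = list(range(g - n_background, g)) if n_background else []

    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=g)
    if background:
        baseline[background] = rng.uniform(0.5, 2.0, size=len(background))

    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(g, len(sample_ids)))

    eff, sub_eff = config.effect_size_log2, config.subtype_effect_log2
    for j, sid in enumerate(sample_ids):
        lab = labels[sid]
        if lab == "RT":
            values[rt_up, j] += eff
        elif lab in ("ES", "RMC", "UC"):
            values[nrt_up, j] += eff
            block = {"ES": es_block, "RMC": rmc_block, "UC": uc_block}[lab]
            values[block, j] += sub_eff
        elif lab == "OTHER":
            values[other_block, j] += eff
    if background:
        values[background, :] = np.minimum(values[background, :],
                                           config.background_ceiling)

    matrix = ExpressionMatrix(pd.DataFrame(
        values, index=gene_ids, columns=sample_ids))

    truth_signature = SignatureGeneSet(
        rt_up=[(gene_ids[i], eff) for i in rt_up],
        nrt_up=[(gene_ids[i], eff) for i in nrt_up],
        method="planted")

    n_imprinted_sig = int(round(config.imprinted_overlap_fraction * n_rt_up))
    imprinted_members = [gene_ids[i] for i in rt_up[:n_imprinted_sig]]
    # pad with unshifted genes so the set is not a pure signature subset
    neutral_start = n_sig + 3 * blk + config.other_block_size
    neutral_pool = [gene_ids[i]
                    for i in range(neutral_start, g - n_background)]
    imprinted_members += neutral_pool[:max(n_imprinted_sig, 1)]
    imprinted = GeneSet(name="IMPRINTED_SYNTHETIC",
                        genes=frozenset(imprinted_members))

    annotations = _generate_annotations(plan, rng)
    return SimulatedCohort(matrix=matrix, annotations=annotations,
                           truth_signature=truth_signature,
                           truth_labels=labels, imprinted=imprinted,
                           config=config)


_AGE_RANGES = {"RT": (0.1, 4.5), "ES": (13.0, 50.0), "RMC": (8.0, 40.0),
               "UC": (2.0, 3.5), "OTHER": (5.0, 55.0)}


def _generate_annotations(plan: list[tuple[str, str, str]],
                          rng: np.random.Generator,
                          ) -> list[SampleAnnotation]:
    out = []
    for sid, cohort, lab in plan:
        lo, hi = _AGE_RANGES[lab]
        if cohort == "study" and lab == "RT":
            lo, hi = 0.2, 43.0   # study RT span pediatric and adult onset
        age = round(float(rng.uniform(lo, hi)), 1)
        has_outcome = rng.random() < 0.8
        outcome = None
        followup = None
        if has_outcome:
            outcome = "DOD" if rng.random() < 0.45 else "NED"
            if rng.random() < 0.9:
                followup = float(rng.integers(30, 1800))
        out.append(SampleAnnotation(
            sample_id=sid, cohort=cohort,
            diagnosis_label=("unknown" if cohort == "study"
                             else ("SD-NRT" if lab == "OTHER" else lab)),
            age_years=age, location="synthetic", outcome=outcome,
            followup_days=followup))
    return out


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_DAMAGING = {"pp2_hdiv": "damaging", "pp2_hvar": "damaging",
             "lrt": "damaging", "mutationtaster": "unknown",
             "mutationassessor": "damaging"}
_BENIGN = {t: "benign" for t in _DAMAGING}


def generate_variants(n_true_somatic: int, n_germline: int, n_artifacts: int,
                      matched: bool = True, seed: int = 0,
                      sample_id: str = "TUMOR01",
                      ) -> tuple[list[VariantRecord], list[str]]:
    """Plant variant records targeting each stage of the filter cascade.

    True somatic records satisfy every pass criterion (in unmatched mode
    they carry a COSMIC id so the rescue rule keeps them).  Germline
    records fail the population-frequency rule or show a constitutional
    heterozygous pattern.  Artifacts cycle through quality, depth and
    supporting-read violations.  Returns the records plus a parallel
    truth-label list ("somatic" / "germline" / "artifact").
    """
    if min(n_true_somatic, n_germline, n_artifacts) < 0:
        raise ConfigError("variant counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    truth: list[str] = []
    pos = iter(range(1_000_000, 9_000_000, 1000))
    bases = "ACGT"

    def alleles() -> tuple[str, str]:
        r = bases[rng.integers(4)]
        a = bases[(bases.index(r) + 1 + int(rng.integers(3))) % 4]
        return r, a

    for i in range(n_true_somatic):
        ref, alt = alleles()
        depth = int(rng.integers(40, 120))
        hom_alt = matched and i % 4 == 3
        vaf = float(rng.uniform(0.85, 0.97)) if hom_alt else \
            float(rng.uniform(0.2, 0.7))
        alt_reads = max(5, int(round(vaf * depth)))
        if matched:
            depth_n = int(rng.integers(30, 90))
            vaf_n = float(rng.uniform(0.42, 0.58)) if hom_alt else 0.0
            alt_n = int(round(vaf_n * depth_n))
        else:
            depth_n = alt_n = vaf_n = None
        records.append(VariantRecord(
            sample_id=sample_id, chrom=f"chr{1 + i % 22}", pos=next(pos),
            ref=ref, alt=alt, gene=f"GENE{i + 1:03d}",
            quality=float(rng.uniform(30, 90)), depth_tumor=depth,
            alt_reads_tumor=min(alt_reads, depth), vaf_tumor=vaf,
            depth_normal=depth_n, alt_reads_normal=alt_n, vaf_normal=vaf_n,
            pop_freqs={} if i % 2 else {"ExAC": float(rng.uniform(0, 0.005))},
            synonymous=False,
            cosmic_id=f"COSM{10000 + i}" if (not matched or i % 2) else None,
            predictor_calls=dict(_DAMAGING)))
        truth.append("somatic")

    for i in range(n_germline):
        ref, alt = alleles()
        depth = int(rng.integers(40, 120))
        vaf = float(rng.uniform(0.45, 0.55))
        if matched:
            depth_n = int(rng.integers(30, 90))
            vaf_n = float(rng.uniform(0.45, 0.55))
            alt_n = int(round(vaf_n * depth_n))
        else:
            depth_n = alt_n = vaf_n = None
        # half are common polymorphisms, half constitutional carriers
        common = (i % 2 == 0) or not matched
        records.append(VariantRecord(
            sample_id=sample_id, chrom=f"chr{1 + i % 22}", pos=next(pos),
            ref=ref, alt=alt, gene=f"GERM{i + 1:03d}",
            quality=float(rng.uniform(30, 90)), depth_tumor=depth,
            alt_reads_tumor=min(int(round(vaf * depth)), depth),
            vaf_tumor=vaf, depth_normal=depth_n, alt_reads_normal=alt_n,
            vaf_normal=vaf_n,
            pop_freqs={"1000g": float(rng.uniform(0.02, 0.3))} if common
            else {},
            synonymous=False, cosmic_id=None,
            predictor_calls=dict(_BENIGN)))
        truth.append("germline")

    for i in range(n_artifacts):
        ref, alt = alleles()
        kind = i % 3
        quality = float(rng.uniform(2, 19.9)) if kind == 0 else \
            float(rng.uniform(30, 90))
        depth = int(rng.integers(1, 10)) if kind == 1 else \
            int(rng.integers(40, 120))
        alt_reads = min(depth, int(rng.integers(0, 5))) if kind != 1 else \
            min(depth, int(rng.integers(0, depth + 1)))
        if kind == 0:  # quality failure alone: give plausible support
            alt_reads = max(5, int(round(0.4 * depth)))
        records.append(VariantRecord(
            sample_id=sample_id, chrom=f"chr{1 + i % 22}", pos=next(pos),
            ref=ref, alt=alt, gene=f"ART{i + 1:03d}",
            quality=quality, depth_tumor=depth,
            alt_reads_tumor=alt_reads,
            vaf_tumor=alt_reads / depth if depth else 0.0,
            depth_normal=int(rng.integers(30, 90)) if matched else None,
            alt_reads_normal=0 if matched else None,
            vaf_normal=0.0 if matched else None,
            pop_freqs={}, synonymous=False, cosmic_id=None,
            predictor_calls=dict(_DAMAGING)))
        truth.append("artifact")

    return records, truth
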