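"""Readers and writers for the flat-text tables the pipeline consumes.

Expression matrices travel as TSV (genes in rows, header of sample ids) or
GCT v1.2; gene sets as GMT; clinical annotations as CSV; variants as a flat
named-column TSV (with a converter from minimal VCF); copy-number segments
as SEG-like TSV.  All readers validate their schema strictly and never
coerce a missing token to zero.

Expression values are assumed to already be on the log2 scale (the output
of array normalisation); the :class:`ExpressionMatrix` carries that
assumption as a flag so downstream writers can record it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Tokens accepted as "missing" in clinical tables; source tables use
#: all four interchangeably.
MISSING_TOKENS: tuple[str, ...] = ("NA", "?", "-", "")

DIAGNOSIS_LABELS = ("RT", "ES", "RMC", "UC", "SD-NRT", "unknown")
OUTCOME_LABELS = ("DOD", "NED")
COHORT_LABELS = ("training", "study")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A dense genes x samples matrix of log2 intensities.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample id.
    log2:
        Records the assumption that values are log2 intensities.
    """

    data: pd.DataFrame
    log2: bool = True

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.dtype.kind not in "fi":
            raise SchemaError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise SchemaError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], log2=self.log2)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise SchemaError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)], log2=self.log2)


def _to_numeric_strict(df: pd.DataFrame, what: str) -> pd.DataFrame:
    converted = df.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric {what} value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if converted.isna().to_numpy().any():
        r, c = np.argwhere(converted.isna().to_numpy())[0]
        raise SchemaError(
            f"missing {what} value at row {df.index[r]!r}, column "
            f"{df.columns[c]!r}; missing values are not coerced"
        )
    return converted.astype(float)


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.2.

    The TSV dialect expects a header row of sample ids and one row per
    gene; GCT additionally carries the two-line preamble and a
    ``Description`` column, both of which are skipped.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "gct":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, skiprows=2)
        desc = [c for c in df.columns if c.lower() == "description"]
        df = df.drop(columns=desc)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(_to_numeric_strict(df, "expression"))


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene_id")
    elif dialect == "gct":
        n_genes, n_samples = matrix.shape
        body = matrix.data.copy()
        body.insert(0, "Description", "na")
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise SchemaError(f"gene set {self.name!r} is empty")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then tab-separated members."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise SchemaError(f"GMT line {lineno}: no members for {parts[0]!r}")
        genes = frozenset(p.strip() for p in parts[2:] if p.strip())
        sets.append(GeneSet(name=parts[0], genes=genes))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """One row of a clinical table (the study/training cohort schema)."""

    sample_id: str
    cohort: str
    diagnosis_label: str
    age_years: float | None = None
    location: str | None = None
    outcome: str | None = None
    followup_days: float | None = None
    sex: str | None = None
    initial_diagnosis: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_LABELS:
            raise SchemaError(f"{self.sample_id}: unknown cohort {self.cohort!r}")
        if self.diagnosis_label not in DIAGNOSIS_LABELS:
            raise SchemaError(
                f"{self.sample_id}: unknown diagnosis {self.diagnosis_label!r}")
        if self.cohort == "training" and self.diagnosis_label == "unknown":
            raise SchemaError(
                f"{self.sample_id}: training samples must carry a diagnosis")
        if self.outcome is not None and self.outcome not in OUTCOME_LABELS:
            raise SchemaError(f"{self.sample_id}: unknown outcome {self.outcome!r}")
        if self.age_years is not None and self.age_years < 0:
            raise SchemaError(f"{self.sample_id}: negative age")
        if self.followup_days is not None and self.followup_days < 0:
            raise SchemaError(f"{self.sample_id}: negative follow-up")


def _parse_age(token: str | None, missing: Sequence[str]) -> float | None:
    if token is None or token.strip() in missing:
        return None
    token = token.strip()
    # censored bounds like "<2" are recorded at the stated bound
    m = re.fullmatch(r"[<>]\s*(\d+(?:\.\d+)?)", token)
    if m:
        return float(m.group(1))
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"cannot parse age {token!r}") from exc


def _parse_followup(token: str | None, missing: Sequence[str]) -> float | None:
    if token is None or token.strip() in missing:
        return None
    token = token.strip()
    # follow-up columns use a day scale but occasionally annotate years
    m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*yrs?", token)
    if m:
        return float(m.group(1)) * 365.0
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"cannot parse follow-up {token!r}") from exc


def read_clinical(path: str | Path,
                  missing_tokens: Sequence[str] = MISSING_TOKENS,
                  ) -> list[SampleAnnotation]:
    """Read a clinical CSV with the cohort-table schema.

    Required columns: ``sample_id``, ``cohort``, ``diagnosis_label``,
    ``age_years``, ``outcome``, ``followup_days``.  Optional:
    ``location``, ``sex``, ``initial_diagnosis``.  The tokens in
    ``missing_tokens`` denote missing values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort", "diagnosis_label", "age_years",
                "outcome", "followup_days"}
    if not required.issubset(df.columns):
        raise SchemaError(f"clinical table misses columns "
                          f"{sorted(required - set(df.columns))}")
    missing = [str(t) for t in missing_tokens]

    def opt(row: pd.Series, col: str) -> str | None:
        if col not in row or str(row[col]).strip() in missing:
            return None
        return str(row[col]).strip()

    out: list[SampleAnnotation] = []
    for _, row in df.iterrows():
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]).strip(),
            cohort=str(row["cohort"]).strip(),
            diagnosis_label=str(row["diagnosis_label"]).strip(),
            age_years=_parse_age(str(row["age_years"]), missing),
            location=opt(row, "location"),
            outcome=opt(row, "outcome"),
            followup_days=_parse_followup(str(row["followup_days"]), missing),
            sex=opt(row, "sex"),
            initial_diagnosis=opt(row, "initial_diagnosis"),
        ))
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate sample ids in clinical table: {dup[:5]}")
    return out


def write_clinical(annotations: Iterable[SampleAnnotation],
                   path: str | Path) -> None:
    rows = []
    for a in annotations:
        d = dataclasses.asdict(a)
        for k, v in d.items():
            if v is None:
                d[k] = "NA"
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Variant tables and copy-number segments
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "quality",
    "depth_tumor", "alt_reads_tumor", "vaf_tumor", "depth_normal",
    "alt_reads_normal", "vaf_normal", "freq_1000g", "freq_esp6500",
    "freq_exac", "synonymous", "cosmic_id", "pp2_hdiv", "pp2_hvar",
    "lrt", "mutationtaster", "mutationassessor",
]

PREDICTOR_TOOLS = ("pp2_hdiv", "pp2_hvar", "lrt", "mutationtaster",
                   "mutationassessor")
PREDICTOR_CALLS = ("damaging", "benign", "unknown")


def variants_to_frame(records: Iterable) -> pd.DataFrame:
    """Flatten VariantRecord objects into the named-column TSV layout."""
    rows = []
    for v in records:
        row = {
            "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "gene": v.gene, "quality": v.quality,
            "depth_tumor": v.depth_tumor, "alt_reads_tumor": v.alt_reads_tumor,
            "vaf_tumor": v.vaf_tumor, "depth_normal": v.depth_normal,
            "alt_reads_normal": v.alt_reads_normal, "vaf_normal": v.vaf_normal,
            "freq_1000g": v.pop_freqs.get("1000g"),
            "freq_esp6500": v.pop_freqs.get("ESP6500"),
            "freq_exac": v.pop_freqs.get("ExAC"),
            "synonymous": v.synonymous, "cosmic_id": v.cosmic_id,
        }
        for tool in PREDICTOR_TOOLS:
            row[tool] = v.predictor_calls.get(tool)
        rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants(records: Iterable, path: str | Path) -> None:
    df = variants_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_variants(path: str | Path):
    """Read a flat variant TSV into :class:`~rtsig.variants.VariantRecord`."""
    from .variants import VariantRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MISSING_TOKENS)

    def fnum(tok: str) -> float | None:
        return None if tok in missing else float(tok)

    def fint(tok: str) -> int | None:
        return None if tok in missing else int(float(tok))

    records = []
    for _, r in df.iterrows():
        pop = {}
        for key, col in (("1000g", "freq_1000g"), ("ESP6500", "freq_esp6500"),
                         ("ExAC", "freq_exac")):
            val = fnum(r[col])
            if val is not None:
                pop[key] = val
        preds = {}
        for tool in PREDICTOR_TOOLS:
            if r[tool] not in missing:
                preds[tool] = r[tool]
        records.append(VariantRecord(
            sample_id=r["sample_id"], chrom=r["chrom"], pos=int(r["pos"]),
            ref=r["ref"], alt=r["alt"], gene=r["gene"],
            quality=float(r["quality"]), depth_tumor=int(r["depth_tumor"]),
            alt_reads_tumor=int(r["alt_reads_tumor"]),
            vaf_tumor=float(r["vaf_tumor"]),
            depth_normal=fint(r["depth_normal"]),
            alt_reads_normal=fint(r["alt_reads_normal"]),
            vaf_normal=fnum(r["vaf_normal"]),
            pop_freqs=pop,
            synonymous=str(r["synonymous"]).lower() in ("true", "1", "yes"),
            cosmic_id=None if r["cosmic_id"] in missing else r["cosmic_id"],
            predictor_calls=preds,
        ))
    return records


def read_segments(path: str | Path, mean_thresholds: tuple[float, float] = (-0.3, 0.3)):
    """Read a SEG-like TSV into :class:`~rtsig.variants.CNVSegment`.

    Accepts either an explicit ``copy_state`` column (loss/neutral/gain) or
    a numeric ``seg_mean`` column thresholded at ``mean_thresholds``.
    """
    from .variants import CNVSegment

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise SchemaError(f"segment table misses columns "
                          f"{sorted(required - set(df.columns))}")
    lo, hi = mean_thresholds
    segments = []
    for _, r in df.iterrows():
        if "copy_state" in df.columns and r["copy_state"].strip():
            state = r["copy_state"].strip()
        elif "seg_mean" in df.columns:
            m = float(r["seg_mean"])
            state = "loss" if m < lo else ("gain" if m > hi else "neutral")
        else:
            raise SchemaError("segment table needs copy_state or seg_mean")
        segments.append(CNVSegment(
            sample_id=r["sample_id"], chrom=r["chrom"],
            start=int(r["start"]), end=int(r["end"]), copy_state=state))
    return segments


def write_segments(segments: Iterable, path: str | Path) -> None:
    rows = [{"sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
             "end": s.end, "copy_state": s.copy_state} for s in segments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def vcf_to_variants(path: str | Path, tumor_sample: str,
                    normal_sample: str | None = None):
    """Convert a minimal VCF 4.x (with AD/DP FORMAT fields) to records.

    Annotation fields the cascade needs but VCF lacks (population
    frequencies, predictor calls, COSMIC ids) are left missing and can be
    merged in afterwards.
    """
    from .variants import VariantRecord

    header_cols: list[str] = []
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            header_cols = line.lstrip("#").split("\t")
            continue
        if not header_cols:
            raise ParseError("VCF misses the #CHROM header line")
        fields = dict(zip(header_cols, line.split("\t")))
        fmt = fields["FORMAT"].split(":")

        def sample_depths(sample: str) -> tuple[int, int]:
            vals = dict(zip(fmt, fields[sample].split(":")))
            ad = [int(x) for x in vals["AD"].split(",")]
            depth = int(vals.get("DP", sum(ad)))
            return depth, ad[1] if len(ad) > 1 else 0

        dt, at = sample_depths(tumor_sample)
        dn = an = None
        if normal_sample is not None:
            dn, an = sample_depths(normal_sample)
        records.append(VariantRecord(
            sample_id=tumor_sample, chrom=fields["CHROM"],
            pos=int(fields["POS"]), ref=fields["REF"], alt=fields["ALT"],
            gene=None,
            quality=float(fields["QUAL"]) if fields["QUAL"] != "." else 0.0,
            depth_tumor=dt, alt_reads_tumor=at,
            vaf_tumor=at / dt if dt else 0.0,
            depth_normal=dn, alt_reads_normal=an,
            vaf_normal=(an / dn if dn else None) if dn is not None else None,
            pop_freqs={}, synonymous=False, cosmic_id=None,
            predictor_calls={}))
    return records


# ---------------------------------------------------------------------------
# qPCR tables and run reports
# ---------------------------------------------------------------------------

def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a Ct table with columns sample_id, gene, ct (optional replicate)."""
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(df.columns):
        raise SchemaError(f"qPCR table misses columns "
                          f"{sorted(required - set(df.columns))}")
    if not np.isfinite(df["ct"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite Ct value")
    return df


def write_run_report(path: str | Path, stage: str,
                     params: Mapping[str, object]) -> None:
    """Write a JSON run report recording the stage parameters.

    Every report records the standing assumption that expression values
    are log2 intensities.
    """
    payload = {
        "stage": stage,
        "assumes_log2_expression": True,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(v: object) -> object:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (set, frozenset)):
        return sorted(v)
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, float) and math.isnan(v):
        return None
    return v
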