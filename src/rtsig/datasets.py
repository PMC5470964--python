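"""Bundled clinical tables and the synthetic imprinted-gene stand-in.

The two clinical CSVs transcribe the training-set and study-cohort
clinical tables of the underlying tumor series (32 training tumors with
ascertained diagnoses; 37 study tumors with their corrected molecular
classification, outcome and follow-up).  The GMT file is a synthetic
stand-in for a curated imprinted-gene catalogue: well-known imprinted
loci, shipped only so the enrichment stage has a concrete input.
"""

from __future__ import annotations

from importlib import resources

from .io import GeneSet, SampleAnnotation, read_clinical, read_gene_sets


def _data_path(name: str):
    return resources.files("rtsig").joinpath("data", name)


def load_training_table() -> list[SampleAnnotation]:
    """Training-set cohort: 16 RT, 8 ES, 5 RMC, 3 UC."""
    with resources.as_file(_data_path("table1_training.csv")) as p:
        return read_clinical(p)


def load_study_table() -> list[SampleAnnotation]:
    """Study cohort (37 tumors) with corrected diagnoses and outcomes."""
    with resources.as_file(_data_path("table2_study.csv")) as p:
        return read_clinical(p)


def load_imprinted_synthetic() -> GeneSet:
    """Synthetic stand-in imprinted-gene set (see module docstring)."""
    with resources.as_file(_data_path("imprinted_synthetic.gmt")) as p:
        return read_gene_sets(p)[0]
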