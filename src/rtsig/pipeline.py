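"""End-to-end synthetic demonstration pipeline.

Chains the stages in analysis order — simulate, gene filtering, consensus
NMF rank selection, signature extraction, study-cohort classification,
imprinted-set enrichment, variant cascade — writing each stage's tables
and a JSON report.  Fully deterministic under a fixed master seed: all
stage seeds derive from it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import classify_cohort, results_to_frame
from .enrichment import overrepresentation_test
from .filtering import GeneFilterParams, filter_genes
from .nmf import nmf_factorize, select_rank
from .signature import nmf_signature, signature_overlap, welch_de
from .simulate import SimulationConfig, generate_expression, generate_variants
from .variants import run_cascade

DEFAULT_RANKS = (2, 3, 4, 5)


def classification_accuracy(results, truth_labels: dict[str, str],
                            ) -> dict[str, float]:
    """Label accuracy on study samples against the planted truth.

    The correct label for an RT / subtype truth is its class (RT or
    SD-NRT); the correct label for a planted orthogonal sample — a tumor
    belonging to neither class — is "unclassified".  Reports the overall
    accuracy over all study samples, the accuracy restricted to samples
    with a class truth, and the fraction of orthogonal samples correctly
    left unclassified.
    """
    n_ok = n_class = n_other = n_other_unclassified = 0
    for r in results:
        if r.is_training:
            continue
        truth = truth_labels[r.sample_id]
        if truth == "OTHER":
            n_other += 1
            n_other_unclassified += r.label == "unclassified"
        else:
            n_class += 1
            want = "RT" if truth == "RT" else "SD-NRT"
            n_ok += r.label == want
    n_all = n_class + n_other
    return {
        "n_study_with_class": n_class,
        "accuracy": n_ok / n_class if n_class else float("nan"),
        "n_other": n_other,
        "other_unclassified_rate": (n_other_unclassified / n_other
                                    if n_other else float("nan")),
        "overall_accuracy": ((n_ok + n_other_unclassified) / n_all
                             if n_all else float("nan")),
    }


def run_pipeline(seed: int = 0, out_dir: str | Path | None = None,
                 config: SimulationConfig | None = None,
                 ranks: tuple[int, ...] = DEFAULT_RANKS,
                 n_runs: int = 50,
                 filter_params: GeneFilterParams | None = None,
                 signature_fraction: float = 0.2,
                 threshold_quantile: float = 0.0,
                 alpha: float = 0.05) -> dict:
    """Run every stage on one synthetic cohort; return the JSON-able report.

    Gene filtering is unsupervised preprocessing and is computed on the
    full series (training + study); the supervised steps (NMF signature,
    Welch test) use training samples only.  Supervised clustering uses
    the full filtered, NMF-class-labelled gene list — the filter already
    reduces the pool to signature scale — while the ``signature_fraction``
    contrast list is extracted and reported alongside.  When ``out_dir``
    is given, stage outputs are written there as TSV/CSV plus a
    ``report.json``.
    """
    rng = np.random.default_rng(seed)
    sim_seed, nmf_seed, var_seed, fact_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=4))

    config = config or SimulationConfig(seed=sim_seed)
    cohort = generate_expression(config)

    filtered_full, filter_report = filter_genes(
        cohort.matrix, filter_params or GeneFilterParams())
    filtered = filtered_full.subset_samples(cohort.training_ids)
    train = filtered
    study = filtered_full.subset_samples(cohort.study_ids)

    V = filtered.values
    V = V - V.min() if V.min() < 0 else V
    selection = select_rank(V, list(ranks), n_runs=n_runs, seed=nmf_seed)
    rank2 = next(r for r in selection.results if r.rank == 2)

    fact = nmf_factorize(V, rank=2, seed=fact_seed, n_init=10)
    train_classes = ["RT" if cohort.truth_labels[s] == "RT" else "SD-NRT"
                     for s in filtered.sample_ids]
    sig = nmf_signature(fact.W, fact.H, filtered.gene_ids, train_classes,
                        fraction=signature_fraction)
    classify_sig = nmf_signature(fact.W, fact.H, filtered.gene_ids,
                                 train_classes, fraction=1.0)

    de = welch_de(filtered, [s for s in filtered.sample_ids
                             if cohort.truth_labels[s] == "RT"], alpha=alpha)
    overlap = signature_overlap(sig, de, alpha=alpha)

    results = classify_cohort(train, cohort.training_labels, study,
                              classify_sig,
                              threshold_quantile=threshold_quantile)
    acc = classification_accuracy(results, cohort.truth_labels)

    universe = filtered.gene_ids
    rt_up_significant = [g for g in de.index[de["significant"]
                                             & (de["direction"] == "RT_up")]]
    enr = overrepresentation_test(rt_up_significant, cohort.imprinted,
                                  universe)

    records, truth = generate_variants(5, 4, 3, matched=True, seed=var_seed)
    kept, attrition = run_cascade(records, matched=True)
    kept_ids = {id(v) for v in kept}
    tp = sum(1 for v, t in zip(records, truth)
             if t == "somatic" and id(v) in kept_ids)

    report = {
        "seed": seed,
        "n_genes_filtered": filtered.shape[0],
        "selected_rank": selection.rank,
        "weak_structure": selection.weak_structure,
        "rank2_cophenetic": rank2.cophenetic,
        "rank2_pac": rank2.pac,
        "signature_size": len(sig),
        "welch_significant": int(de["significant"].sum()),
        "signature_welch_overlap": overlap.n_shared,
        "classification": acc,
        "imprinted_enrichment_p": enr.p_value,
        "imprinted_fold_enrichment": enr.fold_enrichment,
        "variant_attrition": attrition,
        "variant_true_positives": tp,
        "variant_kept": len(kept),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_expression(cohort.matrix, out / "expression.tsv")
        io.write_clinical(cohort.annotations, out / "clinical.csv")
        io.write_gene_sets([cohort.imprinted], out / "imprinted.gmt")
        filter_report.to_csv(out / "filter_report.tsv", sep="\t")
        selection.diagnostics().to_csv(out / "rank_diagnostics.tsv",
                                       sep="\t", index=False)
        sig.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
        de.to_csv(out / "welch_de.tsv", sep="\t")
        results_to_frame(results).to_csv(out / "classification.tsv",
                                         sep="\t", index=False)
        io.write_variants(records, out / "variants.tsv")
        pd.DataFrame({"truth": truth}).to_csv(out / "variant_truth.tsv",
                                              sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
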