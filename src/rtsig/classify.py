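"""Study-cohort assignment: supervised clustering, silhouettes, subtype calls.

Training and study samples are clustered jointly on the signature gene
set (average linkage, 1 - Pearson distance, cut at k = 2).  The cluster
holding the majority of training RT samples is the RT cluster.  Each
study sample keeps its cluster's class only when its silhouette width is
at least as high as a chosen quantile of the training silhouettes within
that cluster (default: the minimum, i.e. "at least equivalent to the
training scores"); otherwise it is left unclassified.  Samples assigned
to the non-rhabdoid class additionally receive a nearest-centroid
subtype call (ES / RMC / UC) by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from .errors import ValidationError
from .io import ExpressionMatrix, SampleAnnotation
from .nmf import hierarchical_cluster, pearson_distance
from .signature import SignatureGeneSet

SUBTYPES = ("ES", "RMC", "UC")


@dataclass
class ClassificationResult:
    sample_id: str
    cluster: str                      # "RT_cluster" or "NRT_cluster"
    silhouette: float
    label: str                        # "RT", "SD-NRT" or "unclassified"
    is_training: bool = False
    subtype_call: str = "none"
    subtype_correlations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.silhouette <= 1.0 + 1e-9:
            raise ValidationError(
                f"{self.sample_id}: silhouette {self.silhouette} out of range")


@dataclass(frozen=True)
class SubtypeCall:
    best: str                        # subtype name or "none"
    correlations: dict[str, float]
    tied: bool = False


def silhouette_scores(matrix: ExpressionMatrix,
                      labels: dict[str, int | str]) -> dict[str, float]:
    """Silhouette width per sample under 1 - Pearson distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)); members of singleton clusters
    score 0 by convention.
    """
    samples = matrix.sample_ids
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValidationError(f"samples without cluster label: {missing[:5]}")
    y = np.asarray([labels[s] for s in samples])
    if len(np.unique(y)) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    d = pearson_distance(matrix.values, samples)
    scores = silhouette_samples(d, y, metric="precomputed")
    return dict(zip(samples, (float(s) for s in scores)))


def subtype_call(sample_values: np.ndarray, training: ExpressionMatrix,
                 training_subtypes: dict[str, str]) -> SubtypeCall:
    """Nearest-centroid subtype assignment by Pearson correlation.

    Each subtype centroid is the mean profile of its training samples on
    the supplied gene space.  A constant (zero-variance) query profile is
    flagged and returns "none"; exact ties resolve alphabetically with
    the tie flag set.
    """
    x = np.asarray(sample_values, dtype=float)
    if x.std() == 0:
        return SubtypeCall(best="none", correlations={}, tied=False)
    corrs: dict[str, float] = {}
    for st in sorted(set(training_subtypes.values())):
        members = [s for s, lab in training_subtypes.items() if lab == st]
        centroid = training.subset_samples(members).values.mean(axis=1)
        if centroid.std() == 0:
            continue
        corrs[st] = float(np.corrcoef(x, centroid)[0, 1])
    if not corrs:
        return SubtypeCall(best="none", correlations={}, tied=False)
    best_val = max(corrs.values())
    winners = sorted(st for st, c in corrs.items() if c == best_val)
    return SubtypeCall(best=winners[0], correlations=corrs,
                       tied=len(winners) > 1)


def classify_cohort(training: ExpressionMatrix,
                    training_labels: dict[str, str],
                    study: ExpressionMatrix,
                    sig: SignatureGeneSet,
                    threshold_quantile: float = 0.0,
                    ) -> list[ClassificationResult]:
    """Assign each study sample to RT / SD-NRT / unclassified.

    ``training_labels`` maps training sample ids to "RT" or a non-RT
    label (either "SD-NRT" or a subtype name, used for centroid calls).
    Joint average-linkage clustering of training + study samples on the
    signature genes is cut at k = 2; silhouettes are computed on that
    joint clustering.  A study sample in cluster X is labelled with X's
    class iff its silhouette reaches the ``threshold_quantile`` quantile
    of the training silhouettes within X.
    """
    if not 0.0 <= threshold_quantile <= 1.0:
        raise ValidationError("threshold_quantile must be in [0, 1]")
    genes = sig.genes
    if not genes:
        raise ValidationError("empty signature gene set")
    train_sub = training.subset_genes(genes)
    study_sub = study.subset_genes(genes)
    train_ids = train_sub.sample_ids
    rt_train = {s for s in train_ids if training_labels.get(s) == "RT"}
    if not rt_train or len(rt_train) == len(train_ids):
        raise ValidationError("training must contain both RT and non-RT")

    joint = ExpressionMatrix(
        pd.concat([train_sub.data, study_sub.data], axis=1),
        log2=training.log2)
    clusters, _ = hierarchical_cluster(joint, k=2)
    sil = silhouette_scores(joint, clusters)

    n_rt_in_1 = sum(1 for s in rt_train if clusters[s] == 1)
    if 2 * n_rt_in_1 == len(rt_train):
        raise ValidationError(
            "unstable training separation: RT samples split evenly")
    rt_cluster = 1 if n_rt_in_1 > len(rt_train) - n_rt_in_1 else 2

    thresholds: dict[int, float] = {}
    for cl in (1, 2):
        train_in_cl = [sil[s] for s in train_ids if clusters[s] == cl]
        # a cluster with no training members accepts nothing
        thresholds[cl] = (float(np.quantile(train_in_cl, threshold_quantile))
                          if train_in_cl else np.inf)

    subtype_train = {s: lab for s, lab in training_labels.items()
                     if lab in SUBTYPES}
    results: list[ClassificationResult] = []
    for s in joint.sample_ids:
        cl = clusters[s]
        cluster_name = "RT_cluster" if cl == rt_cluster else "NRT_cluster"
        cls = "RT" if cl == rt_cluster else "SD-NRT"
        is_training = s in set(train_ids)
        if is_training:
            label = training_labels[s] if training_labels[s] == "RT" else "SD-NRT"
        else:
            label = cls if sil[s] >= thresholds[cl] else "unclassified"
        call = SubtypeCall(best="none", correlations={})
        if label == "SD-NRT" and not is_training and subtype_train:
            call = subtype_call(joint.data[s].to_numpy(), train_sub,
                                subtype_train)
        results.append(ClassificationResult(
            sample_id=s, cluster=cluster_name, silhouette=sil[s],
            label=label, is_training=is_training,
            subtype_call=call.best, subtype_correlations=call.correlations))
    return results


def results_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "cluster": r.cluster,
               "silhouette": r.silhouette, "label": r.label,
               "is_training": r.is_training, "subtype_call": r.subtype_call}
        for st, c in r.subtype_correlations.items():
            row[f"corr_{st}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def marker_report(matrix: ExpressionMatrix, markers: list[str],
                  z_threshold: float = 2.0) -> pd.DataFrame:
    """Per-sample z-scores for marker genes, with high-expression flags.

    z is relative to the cohort mean/sd of each marker; a marker constant
    across the cohort scores 0 everywhere.  Samples with z above
    ``z_threshold`` are flagged.
    """
    missing = [m for m in markers if m not in matrix.data.index]
    if missing:
        raise ValidationError(f"markers absent from matrix: {missing}")
    rows = []
    for m in markers:
        x = matrix.data.loc[m].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        for s, zi in zip(matrix.sample_ids, z):
            rows.append({"marker": m, "sample_id": s, "z_score": float(zi),
                         "flagged": bool(zi >= z_threshold)})
    return pd.DataFrame(rows)


def silhouette_age_correlation(results: list[ClassificationResult],
                               annotations: list[SampleAnnotation],
                               label: str = "RT") -> tuple[float, float]:
    """Pearson correlation of silhouette vs age over samples with a label.

    Samples with missing age are dropped; fewer than 3 usable pairs is an
    error.
    """
    ages = {a.sample_id: a.age_years for a in annotations}
    pairs = [(r.silhouette, ages[r.sample_id]) for r in results
             if r.label == label and ages.get(r.sample_id) is not None]
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 {label} samples with known age, got {len(pairs)}")
    sil, age = zip(*pairs)
    r, p = stats.pearsonr(sil, age)
    return float(r), float(p)
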