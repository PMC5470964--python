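import numpy as np
import pandas as pd
import pytest

from rtsig.classify import (classify_cohort, marker_report,
                            silhouette_age_correlation, silhouette_scores,
                            subtype_call)
from rtsig.errors import ValidationError
from rtsig.io import ExpressionMatrix, SampleAnnotation
from rtsig.nmf import pearson_distance
from rtsig.signature import SignatureGeneSet


def brute_silhouette(D, labels):
    """Direct evaluation of s(i) = (b - a) / max(a, b)."""
    n = len(labels)
    out = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(np.mean([D[i, j] for j in range(n)
                         if labels[j] == other])
                for other in set(labels) if other != labels[i])
        out.append((b - a) / max(a, b))
    return out


def _expr(values, samples):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"G{i}" for i in range(values.shape[0])],
        columns=samples))


def two_class_matrix(per_group=6, n_genes=40, effect=3.0, noise=0.3, seed=0,
                     prefix=("R", "N")):
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 9, n_genes)
    x = base[:, None] + rng.normal(0, noise, (n_genes, 2 * per_group))
    x[: n_genes // 2, :per_group] += effect
    x[n_genes // 2:, per_group:] += effect
    cols = [f"{prefix[0]}{i}" for i in range(per_group)] + \
        [f"{prefix[1]}{i}" for i in range(per_group)]
    return _expr(x, cols), cols


def test_silhouette_matches_brute_force(rng):
    x = rng.normal(size=(25, 14))
    m = _expr(x, [f"S{i}" for i in range(14)])
    labels = {f"S{i}": i % 3 for i in range(14)}
    ours = silhouette_scores(m, labels)
    D = pearson_distance(x)
    expected = brute_silhouette(D, [labels[s] for s in m.sample_ids])
    np.testing.assert_allclose([ours[s] for s in m.sample_ids], expected,
                               atol=1e-10)


def test_silhouette_tight_separated_clusters():
    m, cols = two_class_matrix(effect=5.0, noise=0.1)
    labels = {c: ("R" if c.startswith("R") else "N") for c in cols}
    scores = silhouette_scores(m, labels)
    assert min(scores.values()) > 0.9


def test_silhouette_single_cluster_rejected(tiny_matrix):
    with pytest.raises(ValidationError):
        silhouette_scores(tiny_matrix, {"S1": 1, "S2": 1})


def _signature(matrix):
    genes = matrix.gene_ids
    half = len(genes) // 2
    return SignatureGeneSet(
        rt_up=[(g, 1.0) for g in genes[:half]],
        nrt_up=[(g, 1.0) for g in genes[half:]], method="planted")


def test_duplicated_training_profile_is_accepted():
    train, cols = two_class_matrix(seed=1)
    labels = {c: ("RT" if c.startswith("R") else "SD-NRT") for c in cols}
    study = ExpressionMatrix(train.data[["R0"]].rename(columns={"R0": "Q"}))
    res = classify_cohort(train, labels, study, _signature(train))
    q = next(r for r in res if r.sample_id == "Q")
    assert q.cluster == "RT_cluster"
    assert q.label == "RT"


def test_orthogonal_noise_sample_unclassified(rng):
    train, cols = two_class_matrix(seed=2)
    labels = {c: ("RT" if c.startswith("R") else "SD-NRT") for c in cols}
    noise = rng.uniform(4, 10, size=(train.shape[0], 2))
    study = _expr(noise, ["Q1", "Q2"])
    res = classify_cohort(train, labels, study, _signature(train))
    for q in ("Q1", "Q2"):
        assert next(r for r in res if r.sample_id == q).label == \
            "unclassified"


def test_study_order_invariance(small_cohort):
    train = small_cohort.training_matrix()
    study = small_cohort.study_matrix()
    sig = small_cohort.truth_signature
    a = classify_cohort(train, small_cohort.training_labels, study, sig)
    perm = np.random.default_rng(3).permutation(study.shape[1])
    study_perm = ExpressionMatrix(study.data.iloc[:, perm])
    b = classify_cohort(train, small_cohort.training_labels, study_perm, sig)
    res_a = {r.sample_id: (r.label, round(r.silhouette, 12)) for r in a}
    res_b = {r.sample_id: (r.label, round(r.silhouette, 12)) for r in b}
    assert res_a == res_b


def test_monotone_acceptance_in_quantile(small_cohort):
    train = small_cohort.training_matrix()
    study = small_cohort.study_matrix()
    sig = small_cohort.truth_signature
    labels = small_cohort.training_labels
    lo = classify_cohort(train, labels, study, sig, threshold_quantile=0.0)
    hi = classify_cohort(train, labels, study, sig, threshold_quantile=0.5)
    lo_uncl = {r.sample_id for r in lo if r.label == "unclassified"}
    hi_uncl = {r.sample_id for r in hi if r.label == "unclassified"}
    assert lo_uncl <= hi_uncl


def test_even_rt_split_is_error(rng):
    # two anti-correlated RT profiles force a 1/1 split of training RT
    base = rng.uniform(5, 9, 20)
    profile = rng.normal(0, 1, 20)
    x = np.c_[base + 3 * profile, base - 3 * profile,
              base + 3 * profile + rng.normal(0, .01, 20),
              base - 3 * profile + rng.normal(0, .01, 20)]
    train = _expr(x, ["RT1", "RT2", "N1", "N2"])
    labels = {"RT1": "RT", "RT2": "RT", "N1": "SD-NRT", "N2": "SD-NRT"}
    study = _expr(base[:, None], ["Q"])
    with pytest.raises(ValidationError, match="unstable"):
        classify_cohort(train, labels, study, _signature(train))


def test_no_study_samples_matches_training_silhouettes(small_cohort):
    from rtsig.nmf import hierarchical_cluster

    train = small_cohort.training_matrix()
    sig = small_cohort.truth_signature
    empty = ExpressionMatrix(train.data.iloc[:, :0])
    res = classify_cohort(train, small_cohort.training_labels, empty, sig)
    sub = train.subset_genes(sig.genes)
    clusters, _ = hierarchical_cluster(sub, k=2)
    expected = silhouette_scores(sub, clusters)
    for r in res:
        assert r.silhouette == pytest.approx(expected[r.sample_id])


def test_subtype_call_exact_centroid():
    train, cols = two_class_matrix(seed=4, prefix=("E", "M"))
    subtypes = {c: ("ES" if c.startswith("E") else "RMC") for c in cols}
    es_centroid = train.data[[c for c in cols if c.startswith("E")]] \
        .mean(axis=1).to_numpy()
    call = subtype_call(es_centroid, train, subtypes)
    assert call.best == "ES"
    assert call.correlations["ES"] == pytest.approx(1.0)
    assert not call.tied


def test_subtype_call_constant_profile_flagged():
    train, cols = two_class_matrix(seed=4, prefix=("E", "M"))
    subtypes = {c: ("ES" if c.startswith("E") else "RMC") for c in cols}
    call = subtype_call(np.full(train.shape[0], 3.0), train, subtypes)
    assert call.best == "none"
    assert call.correlations == {}


def test_planted_subtype_recovered(small_cohort):
    """A UC-truth study sample correlates best with the UC centroid on the
    subtype-informative gene space."""
    cfg = small_cohort.config
    n_sig, blk = cfg.n_signature, cfg.subtype_block_size
    gene_ids = small_cohort.matrix.gene_ids
    space = gene_ids[:n_sig + 3 * blk]
    train = small_cohort.training_matrix().subset_genes(space)
    subtypes = {s: lab for s, lab in small_cohort.training_labels.items()
                if lab in ("ES", "RMC", "UC")}
    uc_study = [s for s in small_cohort.study_ids
                if small_cohort.truth_labels[s] == "UC"]
    profile = small_cohort.study_matrix().subset_genes(space) \
        .data[uc_study[0]].to_numpy()
    assert subtype_call(profile, train, subtypes).best == "UC"


def test_marker_report_flags_outlier():
    rng = np.random.default_rng(0)
    x = rng.normal(8, 0.3, size=(2, 10))
    x[0, 3] += 5 * 0.3
    m = _expr(x, [f"S{i}" for i in range(10)])
    report = marker_report(m, ["G0", "G1"], z_threshold=2.0)
    flagged = report[report["flagged"]]
    assert ("G0", "S3") in set(zip(flagged["marker"], flagged["sample_id"]))
    # oracle: recompute z directly
    row = report[(report["marker"] == "G0")
                 & (report["sample_id"] == "S3")].iloc[0]
    assert row["z_score"] == pytest.approx(
        (x[0, 3] - x[0].mean()) / x[0].std())


def test_marker_report_constant_and_missing():
    m = _expr(np.full((1, 4), 2.0), list("ABCD"))
    rep = marker_report(m, ["G0"])
    assert (rep["z_score"] == 0).all()
    with pytest.raises(ValidationError, match="EPCAM"):
        marker_report(m, ["EPCAM"])


def _results_with(sils, label="RT"):
    from rtsig.classify import ClassificationResult
    return [ClassificationResult(sample_id=f"S{i}", cluster="RT_cluster",
                                 silhouette=s, label=label)
            for i, s in enumerate(sils)]


def _annotations_with(ages):
    return [SampleAnnotation(sample_id=f"S{i}", cohort="study",
                             diagnosis_label="unknown", age_years=a)
            for i, a in enumerate(ages)]


def test_age_correlation_proportional():
    res = _results_with([0.1, 0.2, 0.3, 0.4])
    ann = _annotations_with([1.0, 2.0, 3.0, 4.0])
    r, p = silhouette_age_correlation(res, ann)
    assert r == pytest.approx(1.0)


def test_age_correlation_hand_example():
    # silhouettes linear in (0,1,2,3)/4; ages (0,1,2,4): r is scale-free
    res = _results_with([0.0, 0.25, 0.5, 0.75])
    ann = _annotations_with([0.0, 1.0, 2.0, 4.0])
    r, _ = silhouette_age_correlation(res, ann)
    assert r == pytest.approx(0.9827, abs=1e-4)


def test_age_correlation_null_under_permutation(rng):
    sils = rng.uniform(0.3, 0.9, 30)
    rs = []
    for _ in range(200):
        ages = rng.permutation(np.linspace(1, 40, 30))
        r, _ = silhouette_age_correlation(_results_with(sils),
                                          _annotations_with(ages))
        rs.append(r)
    assert abs(np.mean(rs)) < 0.05


def test_age_correlation_needs_three_pairs():
    res = _results_with([0.1, 0.2])
    ann = _annotations_with([1.0, 2.0])
    with pytest.raises(ValidationError):
        silhouette_age_correlation(res, ann)
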