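# Methods

## Scope and data model

`rtsig` operates downstream of expression normalisation and of variant
calling/annotation: its inputs are a normalized log2 expression matrix
(genes x samples), clinical annotation tables, GMT gene sets, flat
variant tables with annotation columns, SEG-like copy-number segments
and qPCR Ct tables.  Gene identifiers are treated as opaque strings —
no probe-to-gene mapping is attempted — and every output records the
standing assumption that expression values are log2 intensities.
Missing-value tokens in clinical tables are `NA`, `?`, `-` and the
empty string (configurable); readers refuse to coerce a missing value
to zero.  Follow-up accepts an explicit `<N>yrs` suffix (converted at
365 days/year) and ages accept a censored bound (`<2` is recorded as
2), both occurring in the bundled tables.

## Gene filtering

A gene is kept iff all three hold:

* max log2 intensity >= `background_threshold` (default 3.5). 3.5 is
  read as a log2-intensity floor: it is implausible as a linear
  intensity for normalized array data.
* linear fold change `2**(max - min)` >= `fold_change_threshold`
  (default 1.2).  The scale of the ratio is a package choice; the
  linear scale makes 1.2 a meaningful "20% spread" minimum.
* RIQR = max(Q3-Q2, Q2-Q1)/Q2 >= `riqr_threshold` (default 0.9),
  computed by default on anti-logged (linear) values — 0.9 would be an
  implausibly large spread relative to log2 medians — with quartiles
  by linear interpolation.  A `quantile` mode (keep genes above the 0.9 quantile
  of the RIQR distribution) is available behind a flag; the absolute
  cutoff is the default.

The filter is strictly per-gene (order-independent) and monotone in
each threshold.  One behaviour of the absolute linear cutoff is worth
knowing: a balanced two-group gene with a pure log2 shift e has a
noiseless RIQR limit of (2^e - 1)/(2^e + 1) < 0.9 for e <= 4.25, so at
effect 2 with noise 0.5 only about half of such genes clear 0.9 — the
filter trades recall of moderate-effect genes for a near-zero
pass-rate of invariant genes.  The test suite verifies the
implementation gene-by-gene against a brute-force oracle rather than
asserting that every planted gene survives.

Filtering is unsupervised preprocessing and is therefore computed on
the full series (training + study) in the pipeline.  Fitting it on the
training samples alone selects genes whose training-set spread is
noise-boosted, which measurably breaks the exchangeability between
training and study silhouettes that the classification threshold
relies on.

## Consensus NMF and rank selection

V (min-shifted per call to be non-negative, since log2 matrices can be
negative) is factorized as V ~ WH by multiplicative updates minimising
||V - WH||_F^2, with uniform(0,1] initial factors scaled by mean(V)
and a non-increasing objective trace; iteration stops at relative
objective change < 1e-4 or 200 iterations.  `n_init` restarts (best
final objective wins) guard against local optima; the pipeline uses 10
restarts for the factorization that feeds the signature, after
observing degenerate one-sided metagene contrasts in a noticeable
fraction of single-start runs.

Consensus clustering repeats the factorization from `n_runs = 50`
random starts per rank; per run, each sample joins its argmax metagene.
The consensus matrix of co-clustering frequencies is scored by

* the cophenetic correlation between (1 - consensus) dissimilarities
  and the cophenetic distances of their average-linkage dendrogram
  (defined as 1.0 in the degenerate all-equal case, which is trivially
  ultrametric), and
* PAC = ECDF(0.9) - ECDF(0.1) over the off-diagonal upper-triangle
  entries.  The (0.1, 0.9) evaluation points are the established
  convention and are configurable.

`select_rank` minimises PAC, breaking ties by higher cophenetic and
then lower rank, and flags the selection as *weak structure* when even
the best PAC exceeds 0.1 (no rank yields unambiguous co-clustering).

All hierarchical clustering uses average linkage on
d = 1 - Pearson correlation between sample profiles; a zero-variance
sample is a named error, since its correlation is undefined.

## Signatures

* NMF route: W columns scaled to unit sum; per-gene contrast
  |w1 - w2|/(w1 + w2) (0 where both weights are 0); top
  ceil(fraction x n_genes) genes (default fraction 0.2 of the filtered
  pool); each gene is assigned to the class whose metagene (identified
  via mean H weights over training RT samples) dominates.  The scoring
  function is pluggable.
* Welch route: per-gene Welch t-test of RT vs all SD-NRT
  (Welch–Satterthwaite df; a gene constant in both groups gets t = 0,
  p = 1), BH correction at alpha 0.05 by default (raw-p mode
  available; the choice is recorded in the table attributes).
  Pairwise mode restricts to RT vs one subtype and reports the top-n
  genes by p.
* `signature_overlap` counts, direction-aware, how many NMF-signature
  genes the Welch-significant list contains.

For the supervised classification step the pipeline uses the full
filtered, NMF-class-labelled gene list rather than the 20% contrast
list: the linear-RIQR filter already reduces a 2000-gene simulation to
a signature-scale pool (~100–250 genes), and a ~20-gene list makes
sample correlations unstable (measured as silhouette collapse in a
fraction of seeds).  The 20% list is still extracted and reported.

## Classification

Training and study samples are clustered jointly (one combined
dendrogram) on the signature genes, cut at k = 2; the cluster holding
the majority of training RT is the RT cluster (an exact 50/50 split is
an "unstable training separation" error).  Silhouettes are computed on
the joint clustering with the same 1 - Pearson distance; singleton
clusters score 0.  A study sample is labelled with its cluster's class
iff its silhouette >= the `threshold_quantile` quantile (default 0,
i.e. the minimum) of the training silhouettes within that cluster —
"at least as well-placed as the training members" — otherwise it is
left unclassified.  Raising the quantile only ever converts labels to
unclassified (monotone acceptance).

A consequence of the minimum-threshold rule: for a study sample drawn
from the same population as n exchangeable training members of its
cluster, the probability of falling below the training minimum is
1/(n + 1) (~6% at n = 16), so even a perfect two-class cohort leaves a
few true-class samples unclassified.  The package therefore reports
classification quality as overall label accuracy, where the correct
label for a sample belonging to neither class is "unclassified",
alongside the class-restricted accuracy.

Subtype calls are nearest-centroid by Pearson correlation against the
training ES/RMC/UC mean profiles (ties resolve alphabetically with a
tie flag; constant profiles are flagged and get no call) — a proximity
call, deliberately not a re-clustering at deeper cuts.  Marker
screening reports per-sample z-scores
per marker (cohort mean/sd; constant markers score 0) with a
configurable flag threshold (default z >= 2).  The silhouette–age
association is the Pearson correlation over RT-labelled samples with
known age (>= 3 pairs required).

## Enrichment

One-sided hypergeometric upper tail P(X >= k) for the overlap k of a
differential list (size n) with a gene set (size K after intersection
with the universe) in a universe of size N, with fold enrichment
(k/n)/(K/N).  The universe is the filtered gene set, not the whole
array — enrichment is asked relative to the genes the analysis could
have seen.  Equivalent to a one-sided Fisher exact test; the test name
is recorded in the result.

## Variant cascade

Fixed stage order: basic filter (quality >= 20 AND tumor depth >= 10
AND >= 5 alt reads; the boundaries "under"/"less than" are strict, so
the stated values themselves pass), polymorphism filter
(discard if any reported population frequency > 1%; a missing
frequency is "not reported", never a rejection), synonymous removal,
then either the matched somatic rules — heterozygous somatic
0.1 <= x_t <= 0.8 with homozygous-reference constitutional (x_n < 0.1
and <= 2 alt-supporting reads: the "<= 2" is interpreted as
alt-supporting reads, since a total depth <= 2 would contradict the
depth >= 10 rule) or homozygous-alternative somatic x_t > 0.8 with
heterozygous constitutional 0.4 <= x_n <= 0.6 — or, without a matched
normal, the rescue rule (COSMIC id, or a gene found mutated in the
matched tumors).  A variant whose every available effect-predictor
call is benign is rejected (a single damaging or unknown call retains
it); this applies in both matched and unmatched mode and is
configurable.  The cascade is idempotent and reports per-stage
attrition counts.

CNV counts are non-neutral segments per sample (overlapping segments
on one sample/chromosome are a validation error) with per-group
medians.  The chromothripsis flag marks chromosomes with >=
`min_breakpoints` state-change boundaries (default 10), but only when
at most `max_chroms` chromosomes (default 3) carry any non-neutral
segment — localized shattering, not genome-wide instability.
Coordinates are 1-based inclusive throughout.

## qPCR

2^-ddCt relative quantification against a reference gene (default
*TBP*): technical replicates are averaged on the Ct scale, the
calibrator delta-Ct is the mean over a designated reference sample
group (a group mean is a more stable calibrator than any single
sample), and fold = 2^-(dCt_sample - dCt_calibrator).  Assay
efficiency terms shared by sample and calibrator cancel; no
efficiency-corrected (Pfaffl) model is attempted.

## Cohort summaries

The adult-onset outcome summary filters a cohort table to one
diagnosis group, age strictly > 15 years, and outcome present; it
counts deaths of disease and takes the median follow-up over cases
with a numeric follow-up (cases with an outcome but no usable
follow-up count toward the totals but not the median).  Grouping
convention: the SD-NRT group aggregates corrected diagnoses
{SD-NRT, ES, RMC}; a case re-assigned to undifferentiated chordoma is
tallied with that specific entity rather than the aggregate.  Both
label sets are overridable.  The bundled tables transcribe the
training-set (32 tumors: 16 RT, 8 ES, 5 RMC, 3 UC) and study-cohort
(37 tumors) clinical tables of the underlying series; one follow-up is
recorded in years inside the day-scale column — values are reported as
recorded.

## Synthetic data

The generator draws per-gene baselines uniform on (5, 12) log2 with
additive Gaussian noise (sd 0.5) — the standard microarray
approximation; no noise model is stated by the source.  Planted
structure, all on the log2 scale:

* 200 signature genes (of 2000): half shifted +2 in RT samples, half
  +2 in non-RT tumor samples ("effect 2, noise 0.5" are the package's
  reference conditions throughout the stochastic tests);
* disjoint 50-gene blocks shifted +1 in ES, RMC and UC samples;
* a 100-gene block shifted +2 in "other" study samples, which are
  otherwise baseline on the signature genes — an orthogonal third
  profile modelling tumors belonging to neither class;
* 20% background genes clamped below 3.45 log2;
* an "imprinted" set tagging 30% of the RT-up genes plus an equal
  number of unshifted genes, so over-representation is recoverable by
  construction.

Cohort sizes mirror the study design: training 16 RT + 8 ES + 5 RMC +
3 UC; study 37 with hidden truth 16 RT, 6 ES, 1 RMC, 1 UC and 13
orthogonal (matching the molecular re-classification of the real
series).  Clinical annotations (ages by entity, outcomes, follow-ups)
are drawn with realistic ranges but carry no planted association.  The
variant generator plants records that by construction satisfy every
pass rule (somatic), violate the population-frequency or constitutional
VAF rules (germline), or cycle through quality/depth/supporting-read
violations (artifacts).

What the simulation does *not* emulate: batch effects, probe-level
noise, correlated genes, intensity-dependent variance, mixed or
borderline histologies, and sequencing read-level artifacts.  Passing
tests therefore demonstrate that the pipeline recovers the structure
it assumes when that structure is present — not performance on real
arrays.

## Problem sizes and numerical choices

The stochastic test battery uses 20 simulation seeds at full cohort
size (2000 genes, 69 samples), 50-run consensus over ranks 2–5 on the
filtered training matrix, and 20 x 1000-gene null cohorts for the
Welch calibration; the full suite runs in about half a minute on one
CPU.  NMF uses epsilon 1e-10 in the update denominators; consensus
matrices are symmetrized and their diagonal fixed at 1; correlation
distances are clipped to [0, 2]; quartiles use linear interpolation
everywhere; BH q-values come from statsmodels and silhouettes from
scikit-learn (both cross-checked against brute-force oracles in the
tests).

## Known limitations

* The acceptance rule's minimum-threshold order-statistic effect (see
  Classification) caps class-restricted accuracy near 94% for
  16-member training clusters; the quantile is exposed for stricter or
  looser acceptance.
* Rank selection is only as good as PAC on the chosen bounds; subtle
  substructure (e.g. subtypes within classes) is deliberately handled
  by centroid calls rather than deeper cuts.
* The imprinted-gene GMT shipped with the package is a synthetic
  stand-in (well-known imprinted loci), not a published catalogue.
* Variant filtering consumes annotation columns as given; it does not
  validate predictor or frequency provenance.
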