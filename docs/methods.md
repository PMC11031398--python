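# Methods

This note documents the models, rules and numerical choices behind
`neurotraj`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Year-anchor resolution

Clinical-history sentences are segmented with an abbreviation-aware
splitter (the concatenation of the output equals the input modulo
whitespace). Year anchors resolve as follows:

* literal 4-digit years in 1800–2099, bounded by birth and death years when
  known; a year after the year of death is implausible and is dropped with
  a parse warning;
* ranges `Y1–Y2` expand to every year of the closed interval;
* `last N years` spans anchor-inclusive from `anchor − N` to the anchor
  (the section year when `YEAR:` headers are present, else the year of
  death) — "last 2 years" before a 2010 death is 2008, 2009, 2010;
* sub-year expressions (`last 2 months`) resolve to the single anchor
  year: a finer rule is not derivable from year-resolved trajectories, and
  one year is the conservative reading;
* `at birth` maps to `death_year − age_at_death`, the only derivable
  anchor;
* back-references (`in comparison to 2003`) contribute nothing — the
  sentence keeps only its own year.

Sentences with no resolvable anchor fall into an explicit *year-unknown*
category. They participate in general exploration but are excluded from
temporal profiling, modeling and dimensionality reduction.

## Synthetic cohorts

The generator emulates the three input families of a brain-bank trajectory
study. Each disease profile assigns its attributes a normal onset-age
distribution (mean/sd in years), a per-year observation probability while
symptomatic, and an optional bounded symptomatic window
(`duration_years`; default: symptomatic until death). Integer ages inside
the window are observed independently. Donors receive sex
(default ratio 0.5), an integer age at death (normal, default 80 ± 8,
clipped to 40–105), an autopsy year (uniform 1997–2020), an APOE genotype
(4/4 with a per-disease probability, default baseline 0.02), and a CD list
equal to the disease's own class, perturbed by a configurable misdiagnosis
rate through a confusion map, optionally extended with an umbrella class.
All randomness flows through one seeded generator; a config reproduces its
cohort byte-for-byte.

The bounded symptomatic window exists so that two profiles can share
attributes *and* lifetime observation counts while differing only in onset
age. Without it, early onset mechanically inflates lifetime counts and the
flattened featurization alone would separate onset-shifted pairs — the
temporal modality would never be necessary and its recovery test would be
vacuous.

Sentences are rendered from templates (two surface forms per attribute,
optional two-attribute conjunctions, label-free distractors), so gold
multilabel vectors are known by construction. What the generator does
**not** emulate: realistic clinical language (template vocabulary is
nearly disjoint across attributes, so classifier scores sit near ceiling —
a passing round trip shows the split/selection/retention machinery is
correct, not that real clinical text is this easy), comorbidity networks,
survival-time confounders, annotator disagreement, and reporting biases in
who writes the histories. Exports can coarsen exact ages to the released
public dialect (5-year bins, 95+ top and 35 bottom categories); analyses
using coarsened ages carry a flag and use the bin midpoint.

## Multilabel classification

Splits use the iterative-stratification heuristic (Sechidis, Tsoumakas &
Vlahavas, 2011), implemented in-package: 20% held-out test, then 5 folds
over the remainder, each label's positives balanced across subsets within
the algorithm's tolerance. Attributes with zero positives are excluded
from stratification with a warning.

The two reference baselines are a bag-of-words logistic regression on word
frequencies and a linear SVM, both after English stop-word removal and
count vectorization, wrapped one-vs-rest. Transformer families plug in
behind the same `ModelSpec`/pipeline interface but are not implemented —
the decision logic (tuning, selection, retention), not the network, is
what this package carries. The random search spans C ∈ log-uniform
[1e−3, 1e3], n-grams (1,1)/(1,2) and min document frequency {1, 2, 5};
each trial scores the mean micro-F1 over the 5 folds; the final spec is
the max-micro-precision trial among the top five by micro-F1, ties broken
by lowest trial index. An attribute is retained for corpus-wide prediction
iff its held-out precision ≥ 0.8 **or** F1 ≥ 0.8 — monotone in both
metrics by construction.

Zero-division conventions: precision, recall and F1 are 0.0 when their
denominator is empty (with a warning); Cohen's κ is NaN when both
annotators are constant.

## Trajectories, imputation, filters

Sentence predictions collapse per (donor, year, attribute) to a single
binary presence. Ages derive as `year − (death_year − age_at_death)`.
Persistence imputation fills qualifying attributes (flagged
neurodegeneration-associated, donor flagged progressive neurodegenerative)
from first observation through the year of death; added rows are marked
`imputed`, and the operation is idempotent. Imputed rows do **not** count
toward the ≥5-observation cohort filter by default (`count_imputed`
switches this): the filter gauges how informative the source record is,
which imputation cannot improve. Filters apply in a fixed order (summary
length, autopsy year, diagnosis allow-list, observation minimum) and every
exclusion is logged with a reason code. Control donors are exempt from the
observation minimum. The diagnosis allow-lists (single common NDs plus
AD-DLB for modeling; additionally psychiatric and mixed-dementia codes for
clustering) are package data that callers can override.

## Enrichment and profiling statistics

The permuted statistic is the per-group mean observation count — the same
quantity the dot plot colours — with the donor proportion available as a
switch. The one-sided p uses the upper tail, ties counted as ≥, with the
add-one correction p = (1 + #{perm ≥ obs}) / (1 + n_perm), which keeps p
valid (never 0) and BH-FDR conservative. An exhaustive mode enumerates all
distinct label assignments on tiny cohorts and omits the add-one (the
identity assignment is already included). Significance is q < 0.1 after
BH-FDR across the attribute × diagnosis panel; the profiling heatmaps use
p ≤ 0.01 for display. The diagnostic-importance test is a two-sided
Pearson χ² without continuity correction on the 2×2 table of significant ×
a-priori flags; zero expected cells raise an error rather than a silent
NaN.

Pairwise group comparisons (observation counts, observation ages,
post-onset survival durations) are two-sided Mann–Whitney U tests with
BH-FDR over all pairs in a panel. When the number of distinct group
assignments is ≤ 25,000 the null distribution of U is enumerated exactly —
this is the only correct small-sample treatment under ties — otherwise the
tie-corrected normal approximation is used. Sex balancing subsamples every
group to its minority-sex count; single-sex groups are dropped from
balanced panels with a warning. Survival after first symptom observation
is the Kaplan–Meier product-limit estimate over
`death_age − first_observation_age` (durations are fully observed in an
autopsy cohort, so censoring is the exception, not the rule; group
comparisons therefore use Mann–Whitney on durations rather than log-rank).

## Verdicts and diagnosis prediction

The accuracy dictionary derives from a disease-class hierarchy: per
covered ND an accurate class set, and umbrella ancestors (e.g. bare
"dementia") as ambiguous. Verdict precedence: an accurate CD wins
(*accurate*) unless another CD is disease-specific for a different covered
disorder, which demotes to *ambiguous* — recording both AD and FTD for an
AD donor is a hedge, not a correct diagnosis. Umbrella-only matches are
*ambiguous*; everything else *inaccurate*. An exact match alongside an
umbrella CD stays accurate by default (`strict_umbrella` demotes it) —
clinicians routinely record the umbrella term next to the specific one,
and penalizing that would conflate notation with error. Model-prediction
verdicts: exact match accurate, partial overlap with a combined ND (AD
predicted for AD-DLB) ambiguous, else inaccurate. Verdicts partition the
cohort by construction.

The prediction harness is diagnosis-stratified 5-fold: each donor is
predicted exactly once by a model that never saw it. The baseline
classifier is a standardized multinomial logistic regression over
aggregated trajectory features (per-attribute observation-year counts and
first-observation ages with a −1 missing sentinel, sex, age at death).
Classes under 5 donors fold into a rare stratum for training (with a
warning) but are scored against their original ND — rare classes are
expected to be mostly missed, and the harness should show that rather than
hide it. A decay-based recurrent alternative is not included; the
`classifier_factory` hook accepts any scikit-learn-style estimator.

## Two-modality clustering

The flattened matrix counts observation-years per attribute over the whole
lifespan; the temporal matrix counts them in overlapping age bins, width
30 stepped by 5, half-open `[start, start + 30)`, grid spanning age 0 to
the cohort's maximum age at death. Each observation age away from the grid
edges therefore falls in exactly 6 consecutive bins. Each matrix is
totals-normalized to the median library size, log1p-transformed, feature
standardized (zero-variance features dropped) and reduced by full-SVD PCA
(default 30 components; truncated with a warning beyond the data rank).

Modality fusion follows the within- vs cross-modality
neighbor-prediction scheme of weighted-nearest-neighbor integration at
default k = 20: for each donor and modality, the modality's score is
`exp(−d_within/σ) − exp(−d_cross/σ)` where `d_within` is the distance to
the mean of its own-modality kNN, `d_cross` to the mean of the other
modality's kNN (both measured in the modality's embedding), and σ is the
distance to the k-th neighbor; a softmax turns the two scores into
per-donor weights summing to 1. Identical modalities give exactly (0.5,
0.5); a pure-noise modality is down-weighted. The joint graph keeps each
donor's top-k neighbors by weighted affinity; clustering is Leiden
modularity optimization (resolution 0.8, seeded). UMAP coordinates are
computed from the weight-scaled concatenated embeddings and are
visualization-only.

Resolution 0.8 is the cohort-level default; it recovers six planted
symptom programs at ARI ≥ 0.8 (and the flattened matrix alone does not,
because the onset-shifted pair collapses). Subcluster analyses asking a
coarser question (is this one cluster or two?) should match resolution to
that granularity — at 0.8 Leiden tends to over-partition a true pair
without mixing the boundary; 0.4 recovers a planted two-subtype split
exactly. Overrepresentation uses one-sided Fisher exact tests for
diagnosis and inaccurate-CD enrichment and two-sided for APOE4/4 (under-
*or* over-representation both matter there), BH-FDR across the panel.
Marker detection is cluster-vs-rest rank-sum on both matrices with the
same exact-under-ties small-sample treatment as the profiling tests.

## Problem sizes

The test suite and the acceptance script run deliberately desk-scale
studies: cohorts of 60–600 donors, corpora of a few thousand rendered
sentences, 1,000–10,000 permutations (100,000 remains the analysis default
for real panels), 20 generator seeds for calibration and power checks.
These sizes were chosen so the planted effects sit far from the decision
thresholds (3-fold enrichments, disjoint or onset-shifted symptom
programs), making the checks sharp rather than marginal.

## Known limitations

* English-only parsing with a fixed abbreviation list; no month-level
  temporal resolution.
* Template-rendered corpora make the extraction task nearly separable;
  classifier ceilings on synthetic data say nothing about transformer-vs-
  baseline gaps on real clinical text.
* The WNN implementation follows the published weighting scheme but is not
  numerically identical to any particular package's internals; the
  contract (weight normalization, symmetry, noise down-weighting,
  planted-structure recovery) is what is tested.
* Survival comparisons use Mann–Whitney on observed durations; a log-rank
  or Cox treatment would be needed for genuinely censored cohorts.
* Verdicts depend entirely on the accuracy dictionary; a sparse hierarchy
  under-reports ambiguity.
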