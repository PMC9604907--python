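# Methods

This note records the models, parameter choices and numerical conventions
behind `vocrepeat`, and what the synthetic validation does and does not
demonstrate about real breath data.

## Synthetic cohort model

The generator emulates a short-term repeatability study: `n_subjects` (14)
patients each providing one breath sample on `n_days` (5) consecutive days,
analysed in run order (each day's subjects consecutively) in analytical
sequences of `batch_size` (4) breath runs bracketed by a QC tube and a
blank. Feature abundances are multiplicative log-normal:

```
x[i,j,v] = exp( mu_v + b[i,v] + lambda_v * t2_i + gamma_batch(i,j) + e[i,j,v] )
```

* `mu_v` — base log abundance, uniform on [ln 2·10³, ln 2·10⁵] (arbitrary
  instrument units; no units or dynamic range are prescribed for real data,
  so these are configurable).
* `b[i,v] ~ N(0, sigma_subject,v)` — subject random effects (between-subject
  spread); `e[i,j,v] ~ N(0, sigma_day,v)` — day-level noise (within-subject
  spread).
* `gamma ~ N(0, 0.25)` — one log-shift per analytical sequence of four
  breath runs. The analytical sequence is the only batch-like unit in the
  study design, so it is the batch variable throughout.
* `t2_i ~ N(0,1)` — a latent type-2 airway-inflammation factor per subject.
  Sixteen designated potential-biomarker features carry loadings
  `lambda_v = ±1.0` with alternating sign (inflammation raises some VOCs and
  suppresses others; the sign balance also keeps the across-feature mean
  free of the factor, which batch-effect estimation implicitly relies on).

A log-normal multiplicative model is the natural choice here: CV-style
statistics are scale-free on it, and the skewness it produces is exactly
what motivates a MAD:median coefficient of variation over a conventional
SD:mean one.

### Planted categories

Each feature's `(sigma_subject, sigma_day)` pair is set by its planted
category: low SD = 0.15, high SD = 1.0 (subject) / 0.9 (day). On the
abundance scale a log-SD `s` maps to CV_MAD ≈ 0.6745·s for small `s`, so
"low" sits near 0.10 and "high" near 0.6 — both well clear of the 0.30
decision threshold, which is what makes the categories recoverable from
only 5 samples per subject and 14 subjects. Default counts are 14 Conserved
/ 48 PotentialBiomarker / 27 Erratic / 0 Noisy (89 features), matching the
cohort composition the analysis is designed around.

### Clinical covariates

One row per subject. Skewed markers (FeNO, IgE, granulocyte percentages,
blood counts) are log-normal, the rest normal, truncated to valid ranges;
location/spread target the cohort's published overall medians and
quartiles. The T2 block shares the latent factor:
`ln FeNO = ln 38.5 + 0.35·t2 + N(0, 0.2)` (total log-SD ≈ 0.40, matching
the observed FeNO IQR), sputum eosinophils couple at 1.2 on the log scale,
and atopy via a logistic shift. All other covariates are drawn
independently — the minimal structure needed for principal components to
carry a recoverable inflammation signal.

### Missingness and peak emission

Cells below `lod_threshold` (100 units) are LOD-censored: in peak tables the
peak is simply absent; on assembly the cell is filled with the baseline
minimum (here `lod_threshold/2`; real baseline integration is out of
scope). Non-LOD missingness (interference) strikes 1% of cells everywhere
plus an extra 5% on Erratic features, and is emitted as a peak with NaN
area. Each sequence's retention axis is distorted by a monotone
piecewise-linear warp (segment slopes 1 ± 0.003, offset SD 0.08 min) whose
interior knots sit on QC compounds, and peak areas are multiplied by the
local warp slope — the distortion the alignment stage must undo. Peak-level
retention jitter is 0.004 min.

All randomness flows from one seed through named SeedSequence children
(abundance, clinical, missingness, warp), so equal configurations give
bit-identical cohorts and the missingness pattern does not depend on, e.g.,
how many clinical covariates were drawn.

### What the generator does not emulate

Raw chromatograms and mass spectra, co-eluting peak shapes, sputum
cytology, medication effects, circadian or dietary VOC drift, and any
day-of-week structure. Passing tests therefore demonstrate that the
pipeline's logic is correct under the stated statistical model, not that
real breath data satisfy that model.

## Alignment and curation

* **Map construction.** Anchors are (observed QC compound position,
  compound-specific median across all QC runs), sorted by observed
  position; the map is continuous piecewise-linear through the anchors.
  Non-monotone anchors are rejected outright — they signal QC peak
  misassignment, not a correctable drift.
* **Scope.** A QC's map applies to the breath runs of its analytical
  sequence (the four runs analysed immediately after it).
* **Area correction.** A time-axis stretch by local slope `s` scales an
  integrated area by `s`, so mapped areas are divided by the local slope.
  At anchor boundaries the left segment's slope applies.
* **Extrapolation** beyond the terminal anchors continues the terminal
  segment's slope; constant extension would flatten the map and break the
  positivity of the area correction.
* **Reference frame.** Alignment converges to the QC-median frame, which
  can drift from nominal method coordinates; feature reference positions
  stated nominally are therefore carried through the nominal→consensus map
  (anchored on the QC compounds) before peak matching. Without this step a
  net median warp silently breaks matching at late retention times.
* **Matching** is nearest reference position within 0.05 min (configurable;
  no tolerance is prescribed for real data). Two peaks hitting one feature
  in one sample is an error — the tolerance is too wide for the data.
* **Filter.** Features with strictly more than 20% non-LOD missing cells
  are excluded (exactly 20% is retained). Surviving sporadic non-LOD cells
  are imputed with the feature's minimum non-missing value — some
  completion rule is mandatory for PCA, and the minimum is conservative for
  cells that were unquantifiable. Imputed cells keep their
  `non_lod_missing` status so the mask remains auditable; samples are never
  removed.

## Normalisation

The public order is batch-correct → log → min-max and is never reordered
(batch correction can be toggled off). Batch correction is parametric
empirical-Bayes location/scale adjustment (ComBat, via scanpy) applied on
the log scale — location/scale adjustment of log-normal abundances is only
well-posed there — and exponentiated back, so the corrected matrix stays on
the positive abundance scale. Only the parametric variant is used. The log
transform is natural-log with a per-feature epsilon of half the smallest
positive value when zeros are present (zero otherwise); the base is
immaterial because min-max scaling removes it. Constant features scale to 0
and are flagged.

Two notes on the empirical-Bayes estimator at this design size:

* With ~4 samples per batch, per-feature batch effects are estimated mostly
  through the cross-feature prior; the per-batch *location* (the quantity
  that matters for CV profiling) is recovered accurately because it
  averages over all features.
* Shrinkage acts on standardised effects, so even a shift that is constant
  across features is removed exactly only when feature scales are equal;
  with heterogeneous scales a small residual (a few percent of the pooled
  SD) is inherent to the estimator. The test fixture that isolates location
  correction therefore standardises features to unit scale first.

## Variance profiling

* CV_MAD is the plain MAD:median ratio; no 1.4826 normal-consistency
  factor (configurable).
* "Averaged across subjects" is the arithmetic mean (median exposed as an
  option); between-subject variability is a single CV_MAD across subject
  means, not a second average.
* Even-length medians are the mean of the two middle values.
* The boundary is ≥ on both axes: exactly 30% counts as high.
* Profiling reads the batch-corrected **abundance** scale, not the
  log/min-max matrix — a ratio-based CV is meaningless after shifting.
  This is configurable (`cv_scale`), defaulting as stated.
* Summary percentages are count/total·100 rounded to two decimals; with
  counts 14/48/27/0 of 89 this gives 15.73 / 53.93 / 30.34 / 0.00. (Note
  27/89 is 30.34% exactly; a figure of 30.35% would make the within-CV
  split sum above 100%.)

## Exploration

* PCA is the standard eigendecomposition of the mean-centred feature
  covariance, with a deterministic sign convention (each loading column's
  largest-magnitude entry positive).
* Subject-level covariates are copied to each of the subject's samples
  before correlating — correlating components of 70 samples against 14
  subjects' characteristics requires it — and the grid flags raw p < 0.05
  with no multiplicity adjustment. These p-values are anti-conservative
  under repeated measures (effective n is nearer the subject count than the
  sample count) and are treated as descriptive, exactly as such grids are
  usually read.
* Sputum granulocyte percentages are log transformed (shared epsilon rule)
  before correlation. Binary covariates use the point-biserial coefficient,
  which is Pearson on the 0/1 coding. Subject identity enters as the
  one-vs-rest point-biserial maximum over subjects (no encoding is
  prescribed; this is the documented choice).
* Group ellipses are axis-aligned with centre the group mean of (PC1, PC2)
  and semi-axes 1.96 × the within-group sample SD per axis — the reading of
  a "95% confidence" ellipse built from per-group means and dispersions.
* The seed-robustness diagnostic for inflammation sensitivity
  (`feno_association_flag`) deliberately does **not** reuse the sample-level
  grid: a family of three raw 5% tests has a ≥ 14% family error rate even
  with independent observations, and the repeated-measures expansion
  inflates it several-fold further, so no sample-level version of the flag
  can have a controlled false-positive rate. The diagnostic instead
  collapses scores to per-subject means (one independent observation per
  subject), correlates PCs 1–3 with FeNO by Pearson, and rejects when the
  smallest p clears the Holm/Bonferroni first step (alpha/3). This controls
  the family rate at 5% while retaining high power under the default
  coupling. The descriptive grid keeps its raw flags.

## Cluster evaluation

* Clustering operates on the fully normalised (log + min-max) matrix — the
  matrix the Euclidean distances are defined on.
* K-means is Lloyd with k-means++ seeding, best inertia of 10 restarts,
  deterministic given the seed. Ward agglomeration uses the Lance–Williams
  update on Euclidean distances with deterministic tie handling; the tree
  is cut at k = number of subjects. k is never chosen any other way.
* ARI and Fowlkes–Mallows are scored against subject identity; the
  silhouette is computed on the *predicted* labels, since it measures how
  distinct the found clusters are, not how well they match anything.
  Degenerate conventions: two all-singleton partitions have FM = 1;
  singleton clusters contribute silhouette 0.
* The feature-set comparison yields one result row per algorithm ×
  feature-set cell (four rows), each carrying ARI, FM and silhouette.

## Problem sizes and determinism

The repeat-seed experiments run at the default cohort size (70 × 89): 20
seeds for category recovery and the cluster feature-set study, 20 signal +
100 null seeds for the FeNO flag rates, 5 seeds for batch-location error.
These sizes put Monte-Carlo error comfortably below the margins being
tested while keeping each experiment in the tens of seconds. The pipeline
is deterministic end-to-end under a fixed configuration: rerunning
reproduces byte-identical tables, and every output is digested in a
manifest.

## Known limitations

* Baseline integration for LOD fills is a configured constant, not a real
  integral over the chromatogram baseline.
* The empirical-Bayes batch model assumes log-normal within-batch
  variation; heavy-tailed contamination would call for the nonparametric
  variant, which is not implemented.
* Category recovery is limited by the between-subject CV_MAD estimated from
  only 14 subject means; features whose true variability sits near the 30%
  boundary will flip categories across seeds regardless of pipeline
  quality.
* The sample-level correlation grid is descriptive only; its p-values are
  anti-conservative under repeated measures, and any confirmatory claim
  should go through subject-level tests such as the FeNO diagnostic.
* Chemical-class labels are pass-through annotations; no spectral
  identification is performed.
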