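# vocrepeat

Short-term repeatability analysis of exhaled volatile organic compounds
(VOCs), built for breathomics studies that collect repeated breath samples
from the same subjects — for example severe-asthma patients sampled on five
consecutive days — and need to know which VOC features are stable enough to
serve as clinical biomarkers.

Breath profiling by thermal-desorption GC-MS yields per-run peak tables
(retention time, area) that drift between analytical sequences and contain
two kinds of missingness: peaks censored at the limit of detection (LOD) and
peaks that are unquantifiable for other reasons (non-LOD missing).
`vocrepeat` implements the full chain from raw peak tables to a
repeatability verdict per feature, plus a synthetic cohort generator with
planted ground truth so every stage can be validated without patient data.

## The core statistic

Feature variability is measured by the robust coefficient of variation
(MAD:median ratio), which behaves well on skewed abundance data:

```
CV_MAD(x) = median(|x_i − median(x)|) / median(x)
```

For each VOC feature *v* over subjects *i* with repeated samples:

* **within-subject variability** — CV_MAD across each subject's samples,
  averaged over subjects;
* **between-subject variability** — CV_MAD across the per-subject mean
  abundances.

A 2×2 rule at a 30% threshold (≥ counts as high) classifies every feature:

| | between < 30% | between ≥ 30% |
|---|---|---|
| **within < 30%** | Conserved | Potential biomarker |
| **within ≥ 30%** | Noisy | Erratic |

Erratic features — variable between subjects but also within the same
subject — are candidates for removal before machine learning: dropping them
should preserve the data's structure (cluster concordance with subject
identity, measured by the Adjusted Rand Index and Fowlkes–Mallows score)
while making clusters more distinct (higher silhouette).

## Pipeline stages

1. **Alignment** (`vocrepeat.preprocess`) — per QC run, a monotone
   piecewise-linear retention-time correction through anchors (observed QC
   compound position, compound-specific median across all QC runs), applied
   to the breath runs of that analytical sequence; peak areas are divided by
   the local slope to preserve quantification.
2. **Curation** — peak-to-feature matching by nearest reference retention
   time, LOD cells filled with the baseline minimum, features with > 20%
   non-LOD missing cells excluded.
3. **Normalisation** (`vocrepeat.normalize`) — empirical-Bayes batch
   correction (ComBat) for analytical-sequence effects, natural log, min-max
   scaling.
4. **Variance profiling** (`vocrepeat.variance`) — CV_MAD profiles and the
   four-way categorisation, summarised overall and by chemical class.
5. **Exploration** (`vocrepeat.exploratory`) — PCA, per-group 95% ellipses,
   and a component × clinical-covariate correlation grid (Pearson /
   point-biserial).
6. **Cluster evaluation** (`vocrepeat.cluster_eval`) — K-means and Ward with
   k = number of subjects, on all vs non-Erratic features.

## Worked example

```python
from vocrepeat.pipeline import RunConfig, run_pipeline

results = run_pipeline(RunConfig(out_dir="results/run", seed=0))
print(results["summary"].to_string(index=False))
```

```
           category  count  percent
          Conserved     17    19.10
 PotentialBiomarker     47    52.81
            Erratic     22    24.72
              Noisy      3     3.37
within_cv_below_0.3     64    71.91
```

The synthetic cohort (14 subjects × 5 days = 70 samples, 89 VOC features)
plants 14 Conserved / 48 PotentialBiomarker / 27 Erratic features; on this
seed 91% of features recover their planted category after the full pipeline
(alignment, curation, batch correction), and 72% of features have
within-subject CV below the 30% threshold — i.e. most VOCs are measured
consistently day to day. The same run reports cluster evaluation:

```
algorithm feature_set  k  ari  fowlkes_mallows  silhouette
   kmeans         all 14  1.0              1.0       0.374
     ward         all 14  1.0              1.0       0.374
   kmeans non_erratic 14  1.0              1.0       0.469
     ward non_erratic 14  1.0              1.0       0.469
```

Subject concordance is at ceiling either way, while removing the 22 features
profiled as Erratic raises the silhouette by ~0.10 for both algorithms — the
variance-based feature selection sharpens clusters without losing structure.

The same chain is available from the shell:

```
vocrepeat all --seed 0 --out results/run
```

and as a stepwise narrative in `analysis/01_simulate_cohort.py` …
`analysis/07_repeat_seed_experiments.py`, each of which prints what it found
and writes its tables under `results/analysis/`.

## Layout

```
src/vocrepeat/     library (simulate, preprocess, normalize, variance,
                   exploratory, cluster_eval, pipeline, experiments, io, cli)
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, assumptions, parameter choices, limitations
```
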