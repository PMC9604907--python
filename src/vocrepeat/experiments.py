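"""Repeat-seed simulation studies over the synthetic cohort.

These are the quantitative experiments the analysis reports: planted-category
recovery through the full pipeline, the effect of dropping Erratic features
on clustering, sensitivity and false-positive rate of the leading-PC FeNO
association, alignment recovery, and batch-correction accuracy.  Both the
test suite and the acceptance script call into here so the numbers they
report come from one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster_eval import compare_feature_sets, results_frame
from .exploratory import feno_association_flag, run_pca
from .normalize import NormalizationRecord, batch_correct, normalize_matrix
from .pipeline import breath_residual_reduction, synthetic_compute
from .preprocess import filter_features
from .simulate import SyntheticConfig, generate_cohort, generate_peak_tables, inject_missingness
from .variance import profile_all


def matrix_stages(config: SyntheticConfig) -> dict:
    """The matrix-level compute path (no peak-table emission).

    generate -> plant missingness -> filter -> normalise; returns curated,
    corrected and scaled matrices plus clinical table and truth.
    """
    matrix, clinical, truth = generate_cohort(config)
    matrix = inject_missingness(matrix, config, truth.feature_category)
    curated, _ = filter_features(matrix)
    corrected, scaled, record = normalize_matrix(curated)
    return {
        "curated": curated,
        "corrected": corrected,
        "scaled": scaled,
        "record": record,
        "clinical": clinical,
        "truth": truth,
    }


def category_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Mean fraction of features recovering their planted category.

    Each seed runs the complete pipeline — peak-table emission, QC-anchored
    alignment, matrix assembly, missingness filtering, batch correction —
    before profiling, so recovery reflects every stage's error, not just the
    categoriser's.
    """
    rates = []
    for i in range(n_seeds):
        res = synthetic_compute(SyntheticConfig(seed=base_seed + i))
        planted = res["truth"].feature_category.reindex(res["profile"].index)
        rates.append(float((res["profile"]["category"] == planted).mean()))
    return {"mean_recovery": float(np.mean(rates)), "per_seed": rates, "n_seeds": n_seeds}


def cluster_feature_set_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Silhouette direction and subject-concordance across seeds.

    For each seed, clusters the normalised cohort with K-means and Ward on
    all features and on non-Erratic features, and records whether the
    restricted set gives the more distinct clusters plus the ARI of every
    algorithm x feature-set cell against subject identity.
    """
    gain_kmeans = gain_ward = 0
    ari_cells: dict[tuple, list] = {}
    for i in range(n_seeds):
        seed = base_seed + i
        st = matrix_stages(SyntheticConfig(seed=seed))
        profile, _ = profile_all(st["corrected"])
        rows = results_frame(
            compare_feature_sets(st["scaled"], profile, st["curated"].subjects, seed=seed)
        ).set_index(["algorithm", "feature_set"])
        gain_kmeans += int(
            rows.loc[("kmeans", "non_erratic"), "silhouette"]
            > rows.loc[("kmeans", "all"), "silhouette"]
        )
        gain_ward += int(
            rows.loc[("ward", "non_erratic"), "silhouette"] > rows.loc[("ward", "all"), "silhouette"]
        )
        for cell in rows.index:
            ari_cells.setdefault(cell, []).append(float(rows.loc[cell, "ari"]))
    return {
        "silhouette_gain_fraction_kmeans": gain_kmeans / n_seeds,
        "silhouette_gain_fraction_ward": gain_ward / n_seeds,
        "mean_ari": {f"{a}_{s}": float(np.mean(v)) for (a, s), v in ari_cells.items()},
        "n_seeds": n_seeds,
    }


def feno_flag_rates(
    n_seeds_signal: int = 20, n_seeds_null: int = 100, base_seed: int = 0
) -> dict:
    """Hit rate of the leading-PC FeNO association flag, with and without a
    planted T2 factor.

    The flag is the subject-level diagnostic (per-subject mean PC scores,
    Pearson against FeNO, multiplicity-corrected over PCs 1-3); with the
    default T2 loading it should fire nearly always, with a zero loading at
    about the nominal 5% rate.
    """

    def rate(n, loading, offset):
        hits = 0
        for i in range(n):
            cfg = SyntheticConfig(seed=base_seed + offset + i, t2_loading=loading)
            st = matrix_stages(cfg)
            pca = run_pca(st["scaled"])
            hits += int(
                feno_association_flag(pca.scores, st["clinical"], st["curated"].subjects)
            )
        return hits / n

    return {
        "signal_rate": rate(n_seeds_signal, SyntheticConfig().t2_loading, 0),
        "null_rate": rate(n_seeds_null, 0.0, 10_000),
        "n_signal": n_seeds_signal,
        "n_null": n_seeds_null,
    }


def alignment_recovery(seed: int = 0) -> dict:
    """Warp recovery on one synthetic cohort: QC-anchor residual reduction
    (exact by construction) and breath-peak dispersion reduction."""
    from .pipeline import qc_residual_reduction

    tables, truth = generate_peak_tables(SyntheticConfig(seed=seed))
    return {
        "qc": qc_residual_reduction(tables),
        "breath": breath_residual_reduction(tables, truth),
    }


def batch_shift_removal(
    delta: float = 0.5, n_per_batch: int = 20, n_features: int = 30, seed: int = 0
) -> dict:
    """Constructed check: a pure constant log-shift between two batches.

    The second batch duplicates the first shifted by ``delta`` log units, and
    features are standardised to exactly unit scale so the location estimate
    is noise-free; correction should remove the shift essentially completely.
    Reports the residual per-batch mean difference relative to the pooled SD.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, (n_per_batch, n_features))
    base = (base - base.mean(0)) / base.std(0)
    log = np.vstack([base + 10.0, base + 10.0 + delta])
    values = pd.DataFrame(
        np.exp(log),
        index=[f"s{i}" for i in range(2 * n_per_batch)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    meta = pd.DataFrame(
        {
            "subject_id": values.index,
            "day": 1,
            "batch": [0] * n_per_batch + [1] * n_per_batch,
        },
        index=values.index,
    )
    from .datatypes import AbundanceMatrix

    matrix = AbundanceMatrix.from_values(values, meta)
    corrected = batch_correct(matrix)
    clog = np.log(corrected.values.to_numpy())
    resid = np.abs(clog[n_per_batch:].mean(0) - clog[:n_per_batch].mean(0)).mean()
    return {
        "residual_shift": float(resid),
        "pooled_sd": float(log.std()),
        "residual_over_pooled_sd": float(resid / log.std()),
    }


def batch_location_error(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Mean absolute error of the estimated vs planted batch log-shifts at
    the default cohort size (shifts compared after centring, since the
    correction only identifies batch effects relative to the grand mean)."""
    errs = []
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=base_seed + i)
        matrix, _, truth = generate_cohort(cfg)
        record = NormalizationRecord()
        batch_correct(matrix, record)
        est = record.batch_location_adjustments
        sizes = matrix.sample_meta["batch"].value_counts().sort_index()
        true = truth.batch_shifts - np.average(truth.batch_shifts, weights=sizes)
        errs.append(float(np.abs(est.to_numpy() - true.to_numpy()).mean()))
    return {"mean_abs_error": float(np.mean(errs)), "per_seed": errs}
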