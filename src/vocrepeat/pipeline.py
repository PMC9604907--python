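"""End-to-end orchestration: simulate -> preprocess -> normalise -> profile
-> explore -> evaluate, producing a report bundle of delimited-text tables,
a JSON manifest with content digests, and a run log.

The stages always run in the fixed order above; configuration can skip batch
correction but never reorder the chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_eval, exploratory, io, normalize, preprocess, variance
from .datatypes import ROLE_QC, AbundanceMatrix
from .simulate import SyntheticConfig, generate_cohort, generate_peak_tables

log = logging.getLogger("vocrepeat")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, file-configurable with CLI overrides."""

    mode: str = "synthetic"  # synthetic | files
    out_dir: str = "results/run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # files mode inputs
    matrix_stem: str | None = None
    clinical_path: str | None = None
    peak_tables_path: str | None = None
    # stage parameters
    cv_threshold: float = 0.30
    non_lod_filter: float = 0.20
    n_components: int = 10
    rt_tolerance: float = 0.05
    do_batch_correct: bool = True
    # scale the CV_MAD profiling reads: corrected abundances (default) or the
    # log+min-max matrix
    cv_scale: str = "corrected"
    cluster_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not (self.matrix_stem and self.clinical_path):
            raise ValueError("files mode needs matrix_stem and clinical_path")
        if not 0 <= self.non_lod_filter <= 1:
            raise ValueError("non_lod_filter must lie in [0, 1]")
        if self.cv_threshold < 0:
            raise ValueError("cv_threshold must be >= 0")
        if self.cv_scale not in ("corrected", "scaled"):
            raise ValueError("cv_scale must be 'corrected' or 'scaled'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in fields(cls)}})
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def synthetic_compute(
    syn: SyntheticConfig,
    rt_tolerance: float = 0.05,
    non_lod_filter: float = 0.20,
    cv_threshold: float = 0.30,
    do_batch_correct: bool = True,
) -> dict:
    """The synthetic-cohort compute path, no file output.

    Generates peak tables, aligns them against the QC runs, assembles and
    filters the feature matrix, normalises, and variance-profiles.  Returns a
    dict with tables, clinical, truth, curated/corrected/scaled matrices,
    profile and summaries, and alignment statistics.
    """
    from .simulate import QC_COMPOUNDS

    _matrix, clinical, _ = generate_cohort(syn)
    tables, truth = generate_peak_tables(syn)
    aligned, _maps = preprocess.align_sequences(tables)
    qc_ref = preprocess.compute_qc_reference([t for t in tables if t.role == ROLE_QC])
    frame = preprocess.nominal_frame_map(qc_ref, QC_COMPOUNDS)
    matching_rt = pd.Series(
        frame.transform(truth.feature_meta["reference_rt"].to_numpy()),
        index=truth.feature_meta.index,
        name="reference_rt",
    )
    matrix = preprocess.assemble_feature_matrix(
        aligned,
        matching_rt,
        _matrix.sample_meta,
        rt_tolerance=rt_tolerance,
        lod_baseline=syn.lod_threshold / 2.0,
    )
    matrix.feature_meta = truth.feature_meta[["reference_rt", "chemical_class"]].reindex(
        matrix.feature_ids
    )
    curated, filter_report = preprocess.filter_features(matrix, non_lod_filter)
    corrected, scaled, record = normalize.normalize_matrix(
        curated, do_batch_correct=do_batch_correct
    )
    profile, summary = variance.profile_all(corrected, threshold=cv_threshold)
    return {
        "tables": tables,
        "clinical": clinical,
        "truth": truth,
        "alignment": qc_residual_reduction(tables),
        "curated": curated,
        "filter_report": filter_report,
        "corrected": corrected,
        "scaled": scaled,
        "normalization": record,
        "profile": profile,
        "summary": summary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Writes the curated matrix, normalisation audit, variance profile and
    category summaries, PCA outputs, correlation grid, ellipse parameters,
    cluster evaluation table, a manifest with SHA-256 digests, and a run log.
    Rerunning with the same configuration reproduces identical tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s finished in %.2fs", name, timings[name])

    # ---- acquire + curate + normalise + profile --------------------------
    stage("acquire")
    alignment_stats = None
    if config.mode == "synthetic":
        syn = config.synthetic
        syn.seed = config.seed
        computed = synthetic_compute(
            syn,
            rt_tolerance=config.rt_tolerance,
            non_lod_filter=config.non_lod_filter,
            cv_threshold=config.cv_threshold,
            do_batch_correct=config.do_batch_correct,
        )
        written.append(io.write_peak_tables(computed["tables"], out / "peak_tables.tsv"))
        written.append(io.write_table(computed["clinical"], out / "clinical.tsv", index=False))
        written.append(io.write_truth(computed["truth"], out / "truth.json"))
        clinical = computed["clinical"]
        alignment_stats = computed["alignment"]
        curated, filter_report = computed["curated"], computed["filter_report"]
        corrected, scaled, record = (
            computed["corrected"],
            computed["scaled"],
            computed["normalization"],
        )
        results["truth"] = computed["truth"]
        done("acquire")
        stage("filter")
        done("filter")
        stage("normalize")
        done("normalize")
        stage("profile")
        if config.cv_scale == "corrected":
            profile, summary = computed["profile"], computed["summary"]
        else:
            profile, summary = variance.profile_all(
                AbundanceMatrix.from_values(scaled, corrected.sample_meta, corrected.feature_meta),
                threshold=config.cv_threshold,
            )
    else:
        matrix = io.read_matrix(config.matrix_stem)
        clinical = pd.read_csv(config.clinical_path, sep="\t")
        if config.peak_tables_path:
            tables = io.read_peak_tables(config.peak_tables_path)
            alignment_stats = qc_residual_reduction(tables)
        for col in ("subject_id", "day"):
            if matrix.sample_meta[col].isna().any():
                raise ValueError(f"inconsistent sample metadata: missing {col}")
        done("acquire")
        stage("filter")
        curated, filter_report = preprocess.filter_features(matrix, config.non_lod_filter)
        done("filter")
        stage("normalize")
        corrected, scaled, record = normalize.normalize_matrix(
            curated, do_batch_correct=config.do_batch_correct
        )
        done("normalize")
        stage("profile")
        cv_input = corrected if config.cv_scale == "corrected" else AbundanceMatrix.from_values(
            scaled, corrected.sample_meta, corrected.feature_meta
        )
        profile, summary = variance.profile_all(cv_input, threshold=config.cv_threshold)

    written += io.write_matrix(curated, out / "curated")
    results["curated"] = curated
    results["filter_report"] = filter_report
    written.append(io.write_table(record.to_frame(), out / "normalization_audit.tsv"))
    if record.batch_location_adjustments is not None:
        written.append(
            io.write_table(
                record.batch_location_adjustments.to_frame(), out / "batch_adjustments.tsv"
            )
        )
    written.append(io.write_table(scaled, out / "normalized_values.tsv"))
    results["corrected"], results["scaled"], results["normalization"] = corrected, scaled, record
    class_summary = variance.summarize_by_class(profile)
    written.append(io.write_table(profile, out / "variance_profile.tsv"))
    written.append(io.write_table(summary, out / "category_summary.tsv", index=False))
    written.append(io.write_table(class_summary, out / "class_summary.tsv", index=False))
    results["profile"], results["summary"], results["class_summary"] = (
        profile,
        summary,
        class_summary,
    )
    done("profile")

    # ---- exploratory -----------------------------------------------------
    stage("exploratory")
    pca = exploratory.run_pca(scaled, n_components=config.n_components)
    grid = exploratory.correlate_pcs(
        pca.scores, clinical, curated.subjects, n_components=config.n_components
    )
    ellipses = exploratory.ellipses_frame(
        exploratory.group_ellipses(pca.scores, curated.subjects)
    )
    written.append(io.write_table(pca.scores, out / "pca_scores.tsv"))
    written.append(io.write_table(pca.loadings, out / "pca_loadings.tsv"))
    written.append(
        io.write_table(pca.explained_variance_ratio.to_frame("explained_variance_ratio"),
                       out / "pca_explained_variance.tsv")
    )
    written.append(io.write_table(grid, out / "correlation_grid.tsv", index=False))
    written.append(io.write_table(ellipses, out / "subject_ellipses.tsv", index=False))
    results["pca"], results["correlations"], results["ellipses"] = pca, grid, ellipses
    done("exploratory")

    # ---- cluster evaluation ---------------------------------------------
    stage("cluster_eval")
    eval_rows = cluster_eval.compare_feature_sets(
        scaled, profile, curated.subjects, seed=config.cluster_seed
    )
    eval_frame = cluster_eval.results_frame(eval_rows)
    written.append(io.write_table(eval_frame, out / "cluster_eval.tsv", index=False))
    results["cluster_eval"] = eval_frame
    done("cluster_eval")

    # ---- bundle ----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "alignment": alignment_stats,
        "outputs": {str(p.relative_to(out)): _digest(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    run_log = [f"{k}: {v:.3f}s" for k, v in timings.items()]
    (out / "run_log.txt").write_text(
        "parameters: " + json.dumps(config.to_dict(), default=str) + "\n" + "\n".join(run_log) + "\n"
    )
    results["manifest"] = manifest
    return results


def qc_residual_reduction(tables) -> dict:
    """Pre- vs post-alignment QC retention-time residuals against reference.

    Returns mean absolute residuals before and after mapping each QC run's
    compound positions through its own alignment map, and the fractional
    reduction.
    """
    qcs = [t for t in tables if t.role == ROLE_QC]
    reference = preprocess.compute_qc_reference(qcs)
    pre, post = [], []
    for t in qcs:
        amap = preprocess.build_alignment_map(t, reference)
        for cid, rt in zip(t.peaks["compound_id"], t.peaks["retention_time_min"]):
            pre.append(abs(rt - reference[cid]))
            post.append(abs(amap.transform(rt) - reference[cid]))
    pre_mean, post_mean = float(np.mean(pre)), float(np.mean(post))
    reduction = 1.0 if pre_mean == 0 else 1.0 - post_mean / pre_mean
    return {"pre_mean_abs": pre_mean, "post_mean_abs": post_mean, "reduction": reduction}


def breath_residual_reduction(tables, truth) -> dict:
    """Alignment recovery measured on breath peaks.

    Alignment maps every run into the QC-median reference frame, so absolute
    truth positions are recovered only up to a common frame offset; the
    informative residual is each peak's deviation from its feature's median
    position across all samples.  Pre-alignment that dispersion reflects the
    per-sequence warps; post-alignment it should collapse to the peak-level
    jitter.  Only peaks inside the QC anchor range enter.
    """
    from .simulate import QC_COMPOUNDS

    aligned, _maps = preprocess.align_sequences(tables)
    ref_rt = truth.feature_meta["reference_rt"]
    lo, hi = min(QC_COMPOUNDS.values()), max(QC_COMPOUNDS.values())
    raw = {t.sample_id: t for t in tables if t.role == "breath"}

    # identify each peak's feature from its *aligned* position (consensus
    # frame, so nearest-reference matching is unambiguous), then measure
    # dispersion of both the raw and the aligned positions per feature
    pre_by_feature: dict[float, list[float]] = {}
    post_by_feature: dict[float, list[float]] = {}
    for t in aligned:
        rts_post = t.peaks["retention_time_min"].to_numpy(float)
        rts_pre = raw[t.sample_id].peaks["retention_time_min"].to_numpy(float)
        true_rts = _true_positions(t, ref_rt)
        for rp, ra, tr in zip(rts_pre, rts_post, true_rts):
            if lo <= tr <= hi:
                pre_by_feature.setdefault(tr, []).append(rp)
                post_by_feature.setdefault(tr, []).append(ra)

    def dispersion(groups):
        resid = []
        for positions in groups.values():
            med = np.median(positions)
            resid.extend(abs(p - med) for p in positions)
        return float(np.mean(resid))

    pre_mean = dispersion(pre_by_feature)
    post_mean = dispersion(post_by_feature)
    return {
        "pre_mean_abs": pre_mean,
        "post_mean_abs": post_mean,
        "reduction": 1.0 - post_mean / pre_mean,
    }


def _true_positions(raw_table, ref_rt: pd.Series) -> np.ndarray:
    # emitted breath peaks follow feature order, whose reference retention
    # times are increasing; match element-wise by nearest reference position
    obs = raw_table.peaks["retention_time_min"].to_numpy(float)
    ref = ref_rt.to_numpy(float)
    idx = np.clip(np.searchsorted(ref, obs), 1, len(ref) - 1)
    nearer = np.where(np.abs(ref[idx - 1] - obs) <= np.abs(ref[idx] - obs), idx - 1, idx)
    return ref[nearer]
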