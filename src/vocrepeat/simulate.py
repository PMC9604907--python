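"""Synthetic breathomics cohorts with planted ground truth.

Emulates a short-term repeatability study: ``n_subjects`` severe-asthma
patients each providing one breath sample on ``n_days`` consecutive days,
profiled by TD-GC-MS into a samples x VOC-features abundance matrix.  The
abundance model is multiplicative log-normal,

    x[i, j, v] = exp(mu_v + b[i, v] + lambda_v * t2_i + gamma_batch(i, j) + e[i, j, v])

with subject random effects ``b`` (between-subject spread), day-level noise
``e`` (within-subject spread), analytical-sequence batch shifts ``gamma`` and
a latent type-2 airway-inflammation factor ``t2`` loading on a designated
subset of features.  Each feature belongs to one of four planted repeatability
categories defined by its (subject SD, day SD) pair:

=================== ============= =========
category            subject SD    day SD
=================== ============= =========
Conserved           low           low
PotentialBiomarker  high          low
Erratic             high          high
Noisy               low           high
=================== ============= =========

The same latent ``t2`` drives the clinical covariates FeNO, sputum
eosinophil % and atopy, so that principal components of the VOC matrix carry
a recoverable inflammation signal.  All randomness flows from a single seed
through named `numpy` SeedSequence children, so equal configurations give
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    LOD_FILLED,
    NON_LOD_MISSING,
    OBSERVED,
    ROLE_BLANK,
    ROLE_BREATH,
    ROLE_QC,
    AbundanceMatrix,
    PeakTable,
)
from .preprocess import PiecewiseLinearMap

CATEGORIES = ("Conserved", "PotentialBiomarker", "Erratic", "Noisy")
# category -> (subject-SD level, day-SD level)
_CATEGORY_LEVELS = {
    "Conserved": ("low", "low"),
    "PotentialBiomarker": ("high", "low"),
    "Erratic": ("high", "high"),
    "Noisy": ("low", "high"),
}

CHEMICAL_CLASSES = (
    "alkane",
    "terpenoid",
    "aldehyde",
    "ketone",
    "ester",
    "aromatic",
    "unidentified",
)
_CLASS_PROBS = (0.24, 0.20, 0.08, 0.08, 0.07, 0.10, 0.23)

# QC tube spiking mix: compound id -> true retention time (minutes)
QC_COMPOUNDS = {
    "QC_C1": 5.0,
    "QC_C2": 15.0,
    "QC_C3": 25.0,
    "QC_C4": 35.0,
    "QC_C5": 45.0,
    "QC_C6": 55.0,
    "QC_C7": 65.0,
    "QC_C8": 75.0,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Log-scale standard deviations are chosen so the planted categories sit
    well clear of the 0.30 CV_MAD threshold: a log-SD sigma maps to a
    CV_MAD of roughly 0.6745 * sigma for small sigma, so 0.15 -> ~0.10
    ("low") and 0.9-1.0 -> ~0.6 ("high").
    """

    n_subjects: int = 14
    n_days: int = 5
    category_counts: dict = field(
        default_factory=lambda: {
            "Conserved": 14,
            "PotentialBiomarker": 48,
            "Erratic": 27,
            "Noisy": 0,
        }
    )
    subject_sd_low: float = 0.15
    subject_sd_high: float = 1.0
    day_sd_low: float = 0.15
    day_sd_high: float = 0.9
    batch_size: int = 4
    batch_shift_sd: float = 0.25
    # latent T2 factor: |loading| on designated potential-biomarker features,
    # alternating in sign (inflammation raises some VOCs and suppresses others)
    t2_loading: float = 1.0
    n_t2_features: int = 16
    # abundance floor; values below it are reported as LOD-filled at half the
    # threshold (the integrated-baseline stand-in)
    lod_threshold: float = 100.0
    non_lod_rate_base: float = 0.01
    non_lod_rate_erratic_extra: float = 0.05
    # base log-abundance range (arbitrary instrument units)
    mu_log_low: float = math.log(2e3)
    mu_log_high: float = math.log(2e5)
    # chromatographic axis for peak-table emission
    rt_min_minutes: float = 3.0
    rt_max_minutes: float = 80.0
    rt_jitter_sd: float = 0.004
    warp_slope_sd: float = 0.003
    warp_offset_sd: float = 0.08
    seed: int = 0

    @property
    def n_features(self) -> int:
        return int(sum(self.category_counts.values()))

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(c < 0 for c in self.category_counts.values()):
            raise ValueError("category counts must be non-negative")
        if self.n_features == 0:
            raise ValueError("all category counts are zero")
        for name in ("subject_sd_low", "subject_sd_high", "day_sd_low", "day_sd_high",
                     "batch_shift_sd", "rt_jitter_sd", "warp_slope_sd", "warp_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.subject_sd_low < self.subject_sd_high:
            raise ValueError("subject_sd_low must be < subject_sd_high")
        if not self.day_sd_low < self.day_sd_high:
            raise ValueError("day_sd_low must be < day_sd_high")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if not 0 <= self.non_lod_rate_base <= 1 or not 0 <= self.non_lod_rate_erratic_extra <= 1:
            raise ValueError("non-LOD rates must be probabilities")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    ``feature_meta`` holds one row per feature: planted ``category``, T2
    ``t2_loading``, base log abundance ``mu``, ``reference_rt`` (true
    chromatographic position) and ``chemical_class``.
    """

    feature_meta: pd.DataFrame
    subject_effects: pd.DataFrame  # subjects x features, log-scale offsets
    batch_shifts: pd.Series  # per batch, log-scale
    t2_latent: pd.Series  # per subject
    warps: dict | None = None  # sequence index -> PiecewiseLinearMap (true RT warp)

    @property
    def feature_category(self) -> pd.Series:
        return self.feature_meta["category"]


def _rngs(seed: int) -> dict:
    """Named, independent RNG streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("abundance", "clinical", "missingness", "warp")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _feature_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_features
    ids = [f"VOC_{i + 1:03d}" for i in range(n)]
    cats = np.repeat(
        [c for c in CATEGORIES if config.category_counts.get(c, 0) > 0],
        [config.category_counts[c] for c in CATEGORIES if config.category_counts.get(c, 0) > 0],
    )
    rng.shuffle(cats)
    subject_sd = np.where(
        [_CATEGORY_LEVELS[c][0] == "high" for c in cats],
        config.subject_sd_high,
        config.subject_sd_low,
    )
    day_sd = np.where(
        [_CATEGORY_LEVELS[c][1] == "high" for c in cats],
        config.day_sd_high,
        config.day_sd_low,
    )
    mu = rng.uniform(config.mu_log_low, config.mu_log_high, n)
    # strictly increasing reference retention times with a guaranteed gap so
    # the default 0.05 min matching window is unambiguous
    gaps = rng.uniform(0.3, 1.0, n)
    rt = config.rt_min_minutes + (config.rt_max_minutes - config.rt_min_minutes) * (
        np.cumsum(gaps) / gaps.sum()
    )
    chem = rng.choice(CHEMICAL_CLASSES, size=n, p=_CLASS_PROBS)
    # T2 loadings: alternating sign on designated PotentialBiomarker features
    loadings = np.zeros(n)
    pb_idx = np.flatnonzero(cats == "PotentialBiomarker")
    chosen = pb_idx[: config.n_t2_features]
    loadings[chosen] = config.t2_loading * np.where(np.arange(len(chosen)) % 2 == 0, 1.0, -1.0)
    table = pd.DataFrame(
        {
            "category": cats,
            "subject_sd": subject_sd,
            "day_sd": day_sd,
            "mu": mu,
            "reference_rt": rt,
            "chemical_class": chem,
            "t2_loading": loadings,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return table


def _sample_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Run-order sample sheet: each day's subjects are analysed consecutively."""
    rows = []
    order = 0
    for day in range(1, config.n_days + 1):
        for s in range(1, config.n_subjects + 1):
            rows.append(
                {
                    "sample_id": f"S{s:02d}_D{day}",
                    "subject_id": f"S{s:02d}",
                    "day": day,
                    "run_order": order,
                    "batch": order // config.batch_size,
                }
            )
            order += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(config: SyntheticConfig):
    """Generate (AbundanceMatrix, clinical table, SyntheticTruth).

    The returned matrix is complete (every cell observed); apply
    :func:`inject_missingness` to plant LOD and non-LOD missing cells.
    """
    config.validate()
    rngs = _rngs(config.seed)
    rng = rngs["abundance"]

    features = _feature_table(config, rng)
    samples = _sample_frame(config)
    n_s, n_d, n_v = config.n_subjects, config.n_days, config.n_features
    subjects = [f"S{i + 1:02d}" for i in range(n_s)]

    b = rng.normal(0.0, 1.0, (n_s, n_v)) * features["subject_sd"].to_numpy()
    t2 = rng.normal(0.0, 1.0, n_s)
    n_batches = samples["batch"].max() + 1
    gamma = rng.normal(0.0, config.batch_shift_sd, n_batches)
    e = rng.normal(0.0, 1.0, (n_s * n_d, n_v)) * features["day_sd"].to_numpy()

    subj_idx = samples["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    log_x = (
        features["mu"].to_numpy()[None, :]
        + b[subj_idx]
        + np.outer(t2[subj_idx], np.ones(n_v)) * features["t2_loading"].to_numpy()[None, :]
        + gamma[samples["batch"].to_numpy()][:, None]
        + e
    )
    values = pd.DataFrame(np.exp(log_x), index=samples.index, columns=features.index)

    matrix = AbundanceMatrix.from_values(
        values,
        samples,
        features[["reference_rt", "chemical_class"]].copy(),
    )
    t2_series = pd.Series(t2, index=pd.Index(subjects, name="subject_id"), name="t2_latent")
    clinical = _draw_clinical(rngs["clinical"], subjects, t2)
    truth = SyntheticTruth(
        feature_meta=features,
        subject_effects=pd.DataFrame(b, index=subjects, columns=features.index),
        batch_shifts=pd.Series(gamma, index=pd.RangeIndex(n_batches, name="batch")),
        t2_latent=t2_series,
    )
    return matrix, clinical, truth


def _draw_clinical(rng: np.random.Generator, subjects, t2) -> pd.DataFrame:
    """Per-subject clinical covariates.

    Target medians/quartiles follow the overall column of the cohort table the
    generator emulates; skewed markers (FeNO, IgE, granulocytes, blood counts)
    are log-normal, the rest normal, truncated to valid ranges.  FeNO, sputum
    eosinophils and atopy share the latent T2 factor.
    """
    t2 = np.asarray(t2, float)
    n = len(subjects)

    def lognorm(median, sigma, coupling=0.0, lo=None, hi=None):
        v = np.exp(math.log(median) + coupling * t2 + rng.normal(0.0, sigma, n))
        if lo is not None or hi is not None:
            v = np.clip(v, lo, hi)
        return v

    def norm(loc, sd, lo, hi):
        return np.clip(rng.normal(loc, sd, n), lo, hi)

    def bern(p):
        return (rng.uniform(size=n) < p).astype(int)

    logit_atopy = math.log(0.571 / (1 - 0.571))
    p_atopy = 1.0 / (1.0 + np.exp(-(logit_atopy + 0.8 * t2)))

    table = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": norm(54.0, 6.7, 18, 80),
            "bmi": norm(25.0, 4.0, 16, 45),
            "feno_ppb": lognorm(38.5, 0.20, coupling=0.35, lo=1.0),
            "sputum_eos_pct": lognorm(2.6, 2.2, coupling=1.2, lo=0.01, hi=99.0),
            "sputum_neut_pct": lognorm(39.8, 0.95, lo=0.5, hi=99.0),
            "blood_eos": lognorm(0.2, 0.5, lo=0.01),
            "blood_neut": lognorm(4.7, 0.30, lo=0.5),
            "total_ige": lognorm(221.8, 1.0, lo=1.0),
            "acq6": norm(2.5, 0.7, 0, 6),
            "post_bd_fev1_pct": norm(81.5, 20.0, 20, 140),
            "post_bd_fev1_fvc": norm(66.0, 10.0, 30, 100),
            "ics_dose": norm(2920.0, 600.0, 500, 6000),
            "exacerbations": rng.poisson(1.3, n),
            "female": bern(0.357),
            "atopy": (rng.uniform(size=n) < p_atopy).astype(int),
            "nasal_polyps": bern(0.462),
            "gord": bern(0.786),
            "maintenance_ocs": bern(0.357),
            "anti_il5": bern(0.214),
            "never_smoker": bern(0.786),
        }
    )
    return table


def generate_clinical(config: SyntheticConfig, n_subjects: int | None = None):
    """Stand-alone clinical draw; returns (table, t2_latent).

    Used to check the latent-factor coupling (e.g. corr(t2, FeNO)) on larger
    subject pools than the cohort default.
    """
    config.validate()
    n = n_subjects if n_subjects is not None else config.n_subjects
    rngs = _rngs(config.seed)
    t2 = rngs["abundance"].normal(0.0, 1.0, n)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    table = _draw_clinical(rngs["clinical"], subjects, t2)
    return table, pd.Series(t2, index=subjects, name="t2_latent")


def inject_missingness(
    matrix: AbundanceMatrix,
    config: SyntheticConfig,
    feature_categories: pd.Series | None = None,
) -> AbundanceMatrix:
    """Plant LOD and non-LOD missingness in a complete matrix.

    Cells below ``lod_threshold`` become LOD-filled at half the threshold (the
    integrated-baseline stand-in).  Non-LOD missingness strikes cells at the
    base rate, plus the configured extra rate on Erratic features when the
    planted categories are supplied.  Observed cells are unchanged.
    """
    if (matrix.status != OBSERVED).to_numpy().any():
        raise ValueError("inject_missingness expects a fully observed matrix")
    out = matrix.copy()
    vals = out.values.to_numpy()
    status = out.status.to_numpy(dtype=object)

    lod = vals < config.lod_threshold
    vals[lod] = config.lod_threshold / 2.0
    status[lod] = LOD_FILLED

    rng = _rngs(config.seed)["missingness"]
    rate = np.full(matrix.n_features, config.non_lod_rate_base)
    if feature_categories is not None:
        erratic = feature_categories.reindex(matrix.feature_ids).to_numpy() == "Erratic"
        rate = rate + config.non_lod_rate_erratic_extra * erratic
    nlm = rng.uniform(size=vals.shape) < rate[None, :]
    vals[nlm] = np.nan
    status[nlm] = NON_LOD_MISSING

    out.values.iloc[:, :] = vals
    out.status.iloc[:, :] = status
    return out


def make_warp(knots_true, knots_warped) -> PiecewiseLinearMap:
    """A true retention-time distortion as a monotone piecewise-linear map."""
    return PiecewiseLinearMap(np.asarray(knots_true, float), np.asarray(knots_warped, float))


def _random_warp(config: SyntheticConfig, rng: np.random.Generator) -> PiecewiseLinearMap:
    # knots bracket the chromatographic axis; interior knots sit on QC
    # compounds so a QC-anchored alignment can represent the warp exactly
    knots = np.array([0.0, 25.0, 55.0, 90.0])
    slopes = 1.0 + rng.normal(0.0, config.warp_slope_sd, len(knots) - 1)
    if (slopes <= 0).any():
        raise ValueError("non-monotone warp: segment slopes must be positive")
    offset = rng.normal(0.0, config.warp_offset_sd)
    warped = offset + knots[0] + np.concatenate([[0.0], np.cumsum(slopes * np.diff(knots))])
    return make_warp(knots, warped)


def _peak_frame(compound_ids, rts, areas) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": list(compound_ids),
            "retention_time_min": np.asarray(rts, float),
            "area": np.asarray(areas, float),
        }
    )


def generate_peak_tables(config: SyntheticConfig):
    """Emit per-run peak tables for the whole cohort.

    Analytical sequences follow the instrument layout: a QC tube (known
    compounds at fixed true retention times), four breath samples, then a
    blank.  Each sequence's retention axis is distorted by a known monotone
    piecewise-linear warp recorded in the returned truth; peak areas are
    scaled by the local warp slope, which QC-anchored alignment must undo.

    Returns (list of PeakTable, SyntheticTruth).  Breath-sample LOD and
    non-LOD missingness are already planted: LOD-censored features are simply
    absent from the table, non-LOD missing features appear with NaN area.
    """
    config.validate()
    matrix, _clinical, truth = generate_cohort(config)
    matrix = inject_missingness(matrix, config, truth.feature_category)
    rng = _rngs(config.seed)["warp"]

    ref_rt = truth.feature_meta["reference_rt"]
    order = matrix.sample_meta.sort_values("run_order").index
    groups = [order[i : i + config.batch_size] for i in range(0, len(order), config.batch_size)]

    tables: list[PeakTable] = []
    warps: dict[int, PiecewiseLinearMap] = {}
    for seq, sample_ids in enumerate(groups):
        warp = _random_warp(config, rng)
        warps[seq] = warp

        qc_rts = np.array([QC_COMPOUNDS[c] for c in QC_COMPOUNDS])
        qc_areas = 1e5 * np.exp(rng.normal(0.0, 0.05, len(qc_rts)))
        tables.append(
            PeakTable(
                sample_id=f"QC_{seq:02d}",
                role=ROLE_QC,
                sequence_index=seq,
                peaks=_peak_frame(QC_COMPOUNDS.keys(), warp.transform(qc_rts), qc_areas),
            )
        )
        for sid in sample_ids:
            present = matrix.status.loc[sid] != LOD_FILLED
            feats = matrix.feature_ids[present]
            true_rt = ref_rt.loc[feats].to_numpy()
            obs_rt = warp.transform(true_rt) + rng.normal(0.0, config.rt_jitter_sd, len(feats))
            # time-axis stretch scales integrated area by the local slope
            areas = matrix.values.loc[sid, feats].to_numpy() * warp.local_slope(true_rt)
            tables.append(
                PeakTable(
                    sample_id=sid,
                    role=ROLE_BREATH,
                    sequence_index=seq,
                    peaks=_peak_frame([""] * len(feats), obs_rt, areas),
                )
            )
        tables.append(
            PeakTable(
                sample_id=f"BLANK_{seq:02d}",
                role=ROLE_BLANK,
                sequence_index=seq,
                peaks=_peak_frame([], [], []),
            )
        )
    truth.warps = warps
    return tables, truth
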