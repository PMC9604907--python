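"""CV_MAD repeatability profiling and the four-way feature categorisation.

The robust coefficient of variation used throughout is the MAD:median ratio

    CV_MAD(x) = median(|x_i - median(x)|) / median(x)

with no normal-consistency constant (the plain ratio; a 1.4826 factor can be
switched on).  It is scale-free on positive data and tolerant of the skewed,
log-normal-like abundance distributions typical of breath VOC data.

For each feature:

* within-subject variability  = mean over subjects of CV_MAD across that
  subject's repeated samples;
* between-subject variability = CV_MAD across the per-subject mean
  abundances.

A 2x2 rule at a 30% threshold (boundary counts as high) assigns each feature
one of four repeatability categories:

====================  ===============  ================
category              within-subject   between-subject
====================  ===============  ================
Conserved             < t              < t
PotentialBiomarker    < t              >= t
Erratic               >= t             >= t
Noisy                 >= t             < t
====================  ===============  ================

Profiling operates on batch-corrected positive abundances, not on the
log/min-max scale: a ratio-based CV is meaningless after shifting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix

CATEGORY_ORDER = ("Conserved", "PotentialBiomarker", "Erratic", "Noisy")

# MAD consistency factor for normal data; off by default (plain MAD:median)
NORMAL_CONSISTENCY = 1.4826


def cv_mad(values, consistency: float = 1.0) -> float:
    """MAD:median ratio of a vector of positive numbers."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    if med <= 0:
        raise ValueError("median must be strictly positive")
    return float(consistency * np.median(np.abs(x - med)) / med)


def within_subject_variability(
    values: pd.Series, subjects: pd.Series, agg: str = "mean", consistency: float = 1.0
) -> float:
    """Average over subjects of the CV_MAD across each subject's samples."""
    per_subject = []
    for _, group in values.groupby(subjects.loc[values.index]):
        if len(group) < 2:
            raise ValueError("every subject needs at least 2 samples")
        per_subject.append(cv_mad(group.to_numpy(), consistency))
    reducer = np.median if agg == "median" else np.mean
    return float(reducer(per_subject))


def between_subject_variability(
    values: pd.Series, subjects: pd.Series, consistency: float = 1.0
) -> float:
    """CV_MAD across the per-subject mean abundances."""
    means = values.groupby(subjects.loc[values.index]).mean()
    if len(means) < 2:
        raise ValueError("need at least 2 subjects")
    return cv_mad(means.to_numpy(), consistency)


def categorize(within: float, between: float, threshold: float = 0.30) -> str:
    """2x2 repeatability rule; values exactly at the threshold count as high."""
    if within < 0 or between < 0:
        raise ValueError("variabilities must be non-negative")
    hi_w = within >= threshold
    hi_b = between >= threshold
    if hi_w:
        return "Erratic" if hi_b else "Noisy"
    return "PotentialBiomarker" if hi_b else "Conserved"


def profile_all(
    matrix: AbundanceMatrix | pd.DataFrame,
    subjects: pd.Series | None = None,
    threshold: float = 0.30,
    agg: str = "mean",
    consistency: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile every feature; returns (profile table, category summary).

    The profile table has one row per feature with columns ``within_cv``,
    ``between_cv``, ``category`` and, when available from the matrix
    annotations, ``chemical_class``.
    """
    if isinstance(matrix, AbundanceMatrix):
        values, subjects = matrix.values, matrix.subjects
        classes = (
            matrix.feature_meta["chemical_class"]
            if "chemical_class" in matrix.feature_meta.columns
            else None
        )
    else:
        if subjects is None:
            raise ValueError("subjects required when profiling a plain DataFrame")
        values, classes = matrix, None

    rows = {}
    for fid in values.columns:
        col = values[fid]
        w = within_subject_variability(col, subjects, agg=agg, consistency=consistency)
        b = between_subject_variability(col, subjects, consistency=consistency)
        rows[fid] = (w, b, categorize(w, b, threshold))
    profile = pd.DataFrame.from_dict(
        rows, orient="index", columns=["within_cv", "between_cv", "category"]
    )
    profile.index.name = "feature_id"
    if classes is not None:
        profile["chemical_class"] = classes.reindex(profile.index)
    return profile, summarize_profile(profile, threshold)


def summarize_profile(profile: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Category bookkeeping: counts and percentages (two decimals).

    Also reports the share of features whose within-subject CV sits below the
    threshold, the headline repeatability figure.
    """
    total = len(profile)
    counts = profile["category"].value_counts()
    rows = []
    for cat in CATEGORY_ORDER:
        n = int(counts.get(cat, 0))
        rows.append({"category": cat, "count": n, "percent": round(100.0 * n / total, 2)})
    below = int((profile["within_cv"] < threshold).sum())
    rows.append(
        {
            "category": f"within_cv_below_{threshold:g}",
            "count": below,
            "percent": round(100.0 * below / total, 2),
        }
    )
    return pd.DataFrame(rows)


def summarize_by_class(
    profile: pd.DataFrame, class_annotations: pd.Series | None = None
) -> pd.DataFrame:
    """Per-chemical-class category frequencies (counts and % within class).

    Unlabelled features are grouped as ``unidentified``.
    """
    classes = (
        class_annotations.reindex(profile.index)
        if class_annotations is not None
        else profile.get("chemical_class")
    )
    if classes is None:
        classes = pd.Series("unidentified", index=profile.index)
    classes = classes.fillna("unidentified")
    rows = []
    for cls, group in profile.groupby(classes):
        n_cls = len(group)
        counts = group["category"].value_counts()
        for cat in CATEGORY_ORDER:
            n = int(counts.get(cat, 0))
            rows.append(
                {
                    "chemical_class": cls,
                    "category": cat,
                    "count": n,
                    "percent_of_class": round(100.0 * n / n_cls, 2),
                }
            )
    return pd.DataFrame(rows)
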