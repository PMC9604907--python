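"""PCA over breath samples and correlation of components with clinical data.

Subject-level clinical covariates are expanded to the sample level (each
subject's value copied across their repeated samples) before correlating
against component scores — this is what relating components of 70 samples to
14 subjects' characteristics requires, and the resulting p-values are
therefore anti-conservative under repeated measures; the grid flags raw
p < 0.05 without adjustment, and a separate subject-level diagnostic
(:func:`feno_association_flag`) is provided for seed-robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import CLINICAL_BINARY, CLINICAL_CONTINUOUS, GRANULOCYTE_COLUMNS


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: pd.Series
    column_means: pd.Series

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)

    def reconstruct(self) -> pd.DataFrame:
        """scores @ loadings.T + column means (exact when all PCs kept)."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            rec + self.column_means.to_numpy()[None, :],
            index=self.scores.index,
            columns=self.loadings.index,
        )


def run_pca(values: pd.DataFrame, n_components: int = 10) -> PCAResult:
    """PCA of the mean-centred feature covariance.

    Deterministic sign convention: each loading column's largest-magnitude
    entry is made positive (scores flipped accordingly).
    """
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if values.isna().to_numpy().any():
        raise ValueError("PCA requires a complete matrix")
    k = min(n_components, values.shape[0] - 1, values.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values.to_numpy(float))
    loadings = pca.components_.T  # features x components
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.index, columns=names),
        loadings=pd.DataFrame(loadings, index=values.columns, columns=names),
        explained_variance_ratio=pd.Series(pca.explained_variance_ratio_, index=names),
        column_means=pd.Series(pca.mean_, index=values.columns),
    )


def transform_granulocytes(values) -> np.ndarray:
    """ln(value + eps) for sputum granulocyte percentages.

    eps is half the smallest positive value when zeros are present, else 0
    (the shared zero-handling rule of the normalisation chain).
    """
    x = np.asarray(values, float)
    if (x < 0).any():
        raise ValueError("granulocyte percentages must be non-negative")
    eps = 0.0
    if (x == 0).any():
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("all-zero vector; cannot pick an epsilon")
        eps = positive.min() / 2.0
    return np.log(x + eps)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_pcs(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    sample_subjects: pd.Series,
    n_components: int = 10,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    include_subject: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlation grid of the first components against clinical covariates.

    Continuous covariates use Pearson's r; binary covariates use the
    point-biserial coefficient (Pearson on 0/1 coding).  Sputum granulocyte
    percentages are log transformed first.  Subject identity enters as the
    one-vs-rest point-biserial maximum across subjects.  Returns a long-format
    grid with columns component, covariate, r, p, method, significant.
    """
    continuous = [c for c in (continuous or CLINICAL_CONTINUOUS) if c in clinical.columns]
    binary = [c for c in (binary or CLINICAL_BINARY) if c in clinical.columns]
    comps = list(scores.columns[: n_components])

    expanded = clinical.set_index("subject_id").loc[sample_subjects.loc[scores.index]]
    expanded.index = scores.index

    rows = []

    def add(comp, covariate, x, y, method):
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append(
                dict(component=comp, covariate=covariate, r=np.nan, p=np.nan,
                     method="skipped_zero_variance", significant=False)
            )
            return
        r, p = _pearson(x, y)
        rows.append(
            dict(component=comp, covariate=covariate, r=r, p=p, method=method,
                 significant=bool(p < alpha))
        )

    for comp in comps:
        x = scores[comp].to_numpy(float)
        for cov in continuous:
            y = expanded[cov].to_numpy(float)
            if cov in GRANULOCYTE_COLUMNS:
                y = transform_granulocytes(y)
            add(comp, cov, x, y, "pearson")
        for cov in binary:
            add(comp, cov, x, expanded[cov].to_numpy(float), "point_biserial")
        if include_subject:
            best = None
            for subj in sample_subjects.loc[scores.index].unique():
                y = (sample_subjects.loc[scores.index] == subj).to_numpy(float)
                if y.std() == 0:
                    continue
                r, p = _pearson(x, y)
                if best is None or abs(r) > abs(best[0]):
                    best = (r, p)
            if best is not None:
                rows.append(
                    dict(component=comp, covariate="subject", r=best[0], p=best[1],
                         method="point_biserial_max", significant=bool(best[1] < alpha))
                )
    return pd.DataFrame(rows)


@dataclass
class GroupEllipse:
    label: object
    center: tuple[float, float]
    semi_axes: tuple[float, float]


def group_ellipses(scores: pd.DataFrame, groups: pd.Series) -> list[GroupEllipse]:
    """Axis-aligned 95% ellipses in the PC1/PC2 plane, one per group.

    Center = group mean; semi-axes = 1.96 x within-group sample SD per axis.
    """
    pc1, pc2 = scores.columns[0], scores.columns[1]
    ellipses = []
    for label, group in scores.groupby(groups.loc[scores.index]):
        if len(group) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        ellipses.append(
            GroupEllipse(
                label=label,
                center=(float(group[pc1].mean()), float(group[pc2].mean())),
                semi_axes=(
                    1.96 * float(group[pc1].std(ddof=1)),
                    1.96 * float(group[pc2].std(ddof=1)),
                ),
            )
        )
    return ellipses


def ellipses_frame(ellipses: list[GroupEllipse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": e.label,
                "center_pc1": e.center[0],
                "center_pc2": e.center[1],
                "semi_axis_pc1": e.semi_axes[0],
                "semi_axis_pc2": e.semi_axes[1],
            }
            for e in ellipses
        ]
    )


def feno_association_flag(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    sample_subjects: pd.Series,
    n_components: int = 3,
    alpha: float = 0.05,
) -> bool:
    """Subject-level test: does any leading PC track FeNO?

    Collapses scores to per-subject means (one independent observation per
    subject, avoiding the repeated-measures inflation of the sample-level
    grid), correlates each of the first ``n_components`` PCs with FeNO by
    Pearson's r, and applies a Holm correction across the component family so
    the flag's false-positive rate stays at ``alpha`` regardless of how many
    components are screened.
    """
    subj_scores = scores.groupby(sample_subjects.loc[scores.index]).mean()
    feno = clinical.set_index("subject_id")["feno_ppb"].loc[subj_scores.index].to_numpy(float)
    comps = list(subj_scores.columns[: n_components])
    pvals = np.array([_pearson(subj_scores[c].to_numpy(float), feno)[1] for c in comps])
    # "any component significant" under Holm reduces to its first step:
    # reject iff the smallest p clears alpha/m
    return bool(pvals.min() < alpha / len(pvals))
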