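"""Batch correction, log transform and min-max scaling.

The public pipeline order is batch-correct -> log -> min-max.  Batch
correction is a parametric empirical-Bayes location/scale adjustment (ComBat)
applied internally on the log scale — location/scale adjustment of log-normal
abundances is only well-posed there — and exponentiated back, so the
corrected matrix stays on the positive abundance scale that the variance
profiling reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix


@dataclass
class NormalizationRecord:
    """Audit trail of the normalisation: what was done to each feature/batch."""

    batch_corrected: bool = False
    # per-batch mean log-scale location adjustment actually applied
    batch_location_adjustments: pd.Series | None = None
    log_epsilon: pd.Series | None = None
    scale_min: pd.Series | None = None
    scale_max: pd.Series | None = None
    constant_features: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        parts = {}
        if self.log_epsilon is not None:
            parts["log_epsilon"] = self.log_epsilon
        if self.scale_min is not None:
            parts["scale_min"] = self.scale_min
            parts["scale_max"] = self.scale_max
        frame = pd.DataFrame(parts)
        frame["constant"] = frame.index.isin(self.constant_features)
        return frame


def batch_correct(matrix: AbundanceMatrix, record: NormalizationRecord | None = None) -> AbundanceMatrix:
    """Remove analytical-batch location/scale effects (parametric ComBat).

    With a single shared batch the correction is a no-op and the input is
    returned unchanged (copied).  Requires strictly positive values and at
    least two samples per batch.
    """
    values = matrix.values
    if values.isna().to_numpy().any():
        raise ValueError("batch correction requires a complete matrix")
    if (values.to_numpy() <= 0).any():
        raise ValueError("batch correction requires strictly positive abundances")
    batches = matrix.sample_meta["batch"]
    if batches.nunique() < 2:
        if record is not None:
            record.batch_corrected = False
        return matrix.copy()
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    import anndata as ad
    import scanpy as sc

    log = np.log(values.to_numpy(float))
    adata = ad.AnnData(log.copy())
    adata.obs["batch"] = pd.Categorical(batches.astype(str).to_numpy())
    sc.pp.combat(adata, key="batch")
    corrected_log = np.asarray(adata.X, float)

    out = matrix.copy()
    out.values.iloc[:, :] = np.exp(corrected_log)
    if record is not None:
        record.batch_corrected = True
        applied = pd.Series(
            [float((log[batches.to_numpy() == b] - corrected_log[batches.to_numpy() == b]).mean())
             for b in sizes.sort_index().index],
            index=sizes.sort_index().index,
            name="location_adjustment",
        )
        record.batch_location_adjustments = applied
    return out


def log_transform(values: pd.DataFrame, record: NormalizationRecord | None = None) -> pd.DataFrame:
    """Natural-log transform, feature-wise zero handling.

    Each cell maps to ln(value + eps) where eps is half the feature's smallest
    positive value when zeros are present, else 0.
    """
    arr = values.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("log transform requires non-negative values")
    eps = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if (col == 0).any():
            positive = col[col > 0]
            if positive.size == 0:
                raise ValueError(
                    f"feature {values.columns[j]!r} is all zeros; cannot pick an epsilon"
                )
            eps[j] = positive.min() / 2.0
    out = pd.DataFrame(np.log(arr + eps[None, :]), index=values.index, columns=values.columns)
    if record is not None:
        record.log_epsilon = pd.Series(eps, index=values.columns, name="log_epsilon")
    return out


def minmax_scale(
    values: pd.DataFrame, record: NormalizationRecord | None = None
) -> pd.DataFrame:
    """Scale each feature to [0, 1]; constant features map to 0 and are flagged."""
    if values.isna().to_numpy().any():
        raise ValueError("min-max scaling requires a complete matrix")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = span.index[span.to_numpy() == 0].tolist()
    safe = span.replace(0, 1.0)
    out = (values - lo) / safe
    out[constant] = 0.0
    if record is not None:
        record.scale_min = lo.rename("scale_min")
        record.scale_max = hi.rename("scale_max")
        record.constant_features = constant
    return out


def normalize_matrix(
    matrix: AbundanceMatrix, do_batch_correct: bool = True
) -> tuple[AbundanceMatrix, pd.DataFrame, NormalizationRecord]:
    """Run the full chain: batch-correct -> log -> min-max.

    Returns (batch-corrected matrix on the abundance scale, fully normalised
    samples x features DataFrame in [0, 1], audit record).  The order is
    fixed; ``do_batch_correct=False`` skips the first step only.
    """
    record = NormalizationRecord()
    corrected = batch_correct(matrix, record) if do_batch_correct else matrix.copy()
    logged = log_transform(corrected.values, record)
    scaled = minmax_scale(logged, record)
    return corrected, scaled, record
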