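"""QC-anchored retention-time alignment and feature-matrix curation.

Retention-time drift between analytical sequences is corrected per QC run: a
monotone piecewise-linear map is fitted through anchor pairs (observed QC
compound retention time, compound-specific median across all QC runs) and
applied to the breath samples analysed immediately after that QC.  Because a
time-axis stretch by local slope ``s`` scales an integrated peak area by
``s``, each mapped peak's area is divided by the local slope to preserve
quantification.

Curation then matches aligned peaks to features by nearest reference
retention time within a tolerance window, fills absent-by-LOD cells with the
feature's baseline minimum value, carries non-LOD missing cells as empty, and
excludes features whose non-LOD missing frequency strictly exceeds 20% of
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    LOD_FILLED,
    NON_LOD_MISSING,
    OBSERVED,
    ROLE_BREATH,
    ROLE_QC,
    AbundanceMatrix,
    PeakTable,
)


class PiecewiseLinearMap:
    """Continuous piecewise-linear monotone map through anchor points.

    Between anchors the map interpolates linearly; beyond the first/last
    anchor it extrapolates with the adjacent segment's slope.  At an interior
    anchor the *left* segment's slope is used for area correction, so the
    slope is defined everywhere.
    """

    def __init__(self, observed: np.ndarray, reference: np.ndarray):
        observed = np.asarray(observed, float)
        reference = np.asarray(reference, float)
        if observed.ndim != 1 or observed.shape != reference.shape:
            raise ValueError("anchors must be two equal-length 1-D arrays")
        if len(observed) < 2:
            raise ValueError("need at least 2 anchors to define a slope")
        if not (np.all(np.diff(observed) > 0) and np.all(np.diff(reference) > 0)):
            raise ValueError(
                "anchors must be strictly increasing in both coordinates "
                "(non-monotone anchors signal QC peak misassignment)"
            )
        self.observed = observed
        self.reference = reference
        self._slopes = np.diff(reference) / np.diff(observed)
        if (self._slopes <= 0).any():
            raise ValueError("non-positive local slope")

    def _segment(self, rt: np.ndarray) -> np.ndarray:
        # left segment at anchor boundaries; terminal segments extend outward
        idx = np.searchsorted(self.observed, rt, side="left") - 1
        return np.clip(idx, 0, len(self._slopes) - 1)

    def transform(self, rt):
        rt_arr = np.asarray(rt, float)
        seg = self._segment(np.atleast_1d(rt_arr))
        out = self.reference[seg] + self._slopes[seg] * (np.atleast_1d(rt_arr) - self.observed[seg])
        return out if rt_arr.ndim else float(out[0])

    def local_slope(self, rt):
        rt_arr = np.asarray(rt, float)
        out = self._slopes[self._segment(np.atleast_1d(rt_arr))]
        return out if rt_arr.ndim else float(out[0])

    @property
    def anchors(self) -> list[tuple[float, float]]:
        return list(zip(self.observed.tolist(), self.reference.tolist()))


# the alignment map *is* a piecewise-linear map; keep the domain name visible
RTAlignmentMap = PiecewiseLinearMap


def compute_qc_reference(qc_tables: list[PeakTable]) -> dict[str, float]:
    """Compound-specific median retention time across all QC runs.

    Even-count medians are the mean of the two middle values (numpy
    convention).
    """
    if not qc_tables:
        raise ValueError("need at least one QC table")
    observed: dict[str, list[float]] = {}
    for table in qc_tables:
        if table.role != ROLE_QC:
            raise ValueError(f"table {table.sample_id!r} is not a QC run")
        for cid, rt in zip(table.peaks["compound_id"], table.peaks["retention_time_min"]):
            if not cid:
                raise ValueError("QC peaks must carry compound ids")
            observed.setdefault(cid, []).append(float(rt))
    return {cid: float(np.median(rts)) for cid, rts in observed.items()}


def build_alignment_map(qc_table: PeakTable, reference: dict[str, float]) -> RTAlignmentMap:
    """Fit the per-QC piecewise-linear correction from shared compounds."""
    if qc_table.role != ROLE_QC:
        raise ValueError("alignment maps are built from QC runs")
    pairs = [
        (float(rt), reference[cid])
        for cid, rt in zip(qc_table.peaks["compound_id"], qc_table.peaks["retention_time_min"])
        if cid in reference
    ]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 compounds shared with the reference; cannot define a slope")
    pairs.sort(key=lambda p: p[0])
    obs, ref = map(np.asarray, zip(*pairs))
    return RTAlignmentMap(obs, ref)


def apply_alignment(table: PeakTable, amap: RTAlignmentMap) -> PeakTable:
    """Map peak retention times and divide areas by the local slope."""
    out = table.copy()
    if len(out.peaks):
        rt = out.peaks["retention_time_min"].to_numpy(float)
        slope = amap.local_slope(rt)
        if (slope <= 0).any():
            raise ValueError("non-positive local slope")
        out.peaks["retention_time_min"] = amap.transform(rt)
        out.peaks["area"] = out.peaks["area"].to_numpy(float) / slope
    return out


def align_sequences(tables: list[PeakTable]) -> tuple[list[PeakTable], dict[int, RTAlignmentMap]]:
    """Align every breath run using the QC of its analytical sequence.

    A QC's map applies to the breath samples analysed immediately after it,
    i.e. the breath runs sharing its ``sequence_index``.  Returns the aligned
    breath tables and the per-sequence maps.
    """
    qcs = [t for t in tables if t.role == ROLE_QC]
    reference = compute_qc_reference(qcs)
    maps = {t.sequence_index: build_alignment_map(t, reference) for t in qcs}
    aligned = []
    for t in tables:
        if t.role != ROLE_BREATH:
            continue
        if t.sequence_index not in maps:
            raise ValueError(f"no QC run for sequence {t.sequence_index}")
        aligned.append(apply_alignment(t, maps[t.sequence_index]))
    return aligned, maps


def nominal_frame_map(reference: dict[str, float], nominal: dict[str, float]) -> RTAlignmentMap:
    """Map nominal (method-defined) retention times into the QC-consensus frame.

    Alignment brings every run into the frame of the compound-specific QC
    medians, which can drift from the nominal positions the chromatographic
    method assigns to the QC compounds.  Feature reference positions stated in
    nominal coordinates must be carried through this map before peak matching.
    """
    shared = sorted(set(reference) & set(nominal), key=lambda c: nominal[c])
    if len(shared) < 2:
        raise ValueError("need at least 2 shared compounds to define the frame")
    nom = np.array([nominal[c] for c in shared])
    ref = np.array([reference[c] for c in shared])
    return RTAlignmentMap(nom, ref)


def assemble_feature_matrix(
    tables: list[PeakTable],
    feature_reference_rt: pd.Series,
    sample_meta: pd.DataFrame,
    rt_tolerance: float = 0.05,
    lod_baseline: float | pd.Series = 0.0,
) -> AbundanceMatrix:
    """Build the samples x features matrix from aligned breath tables.

    Peaks are matched to the nearest feature reference retention time within
    ``rt_tolerance`` minutes.  A feature absent from a sample is taken to be
    below the limit of detection and filled with its baseline minimum value
    (``lod_baseline``, scalar or per-feature).  A matched peak with NaN area
    is an unquantifiable, non-LOD missing cell.
    """
    feature_reference_rt = feature_reference_rt.sort_values()
    feature_ids = feature_reference_rt.index
    ref = feature_reference_rt.to_numpy(float)
    baseline = (
        lod_baseline.reindex(feature_ids)
        if isinstance(lod_baseline, pd.Series)
        else pd.Series(float(lod_baseline), index=feature_ids)
    )

    sample_ids = [t.sample_id for t in tables]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids among breath tables")

    values = pd.DataFrame(
        np.tile(baseline.to_numpy(), (len(tables), 1)),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=feature_ids,
    )
    status = pd.DataFrame(LOD_FILLED, index=values.index, columns=feature_ids)

    for t in tables:
        if t.role != ROLE_BREATH:
            raise ValueError("assemble_feature_matrix expects aligned breath tables only")
        rts = t.peaks["retention_time_min"].to_numpy(float)
        areas = t.peaks["area"].to_numpy(float)
        pos = np.searchsorted(ref, rts)
        left = np.clip(pos - 1, 0, len(ref) - 1)
        right = np.clip(pos, 0, len(ref) - 1)
        nearest = np.where(np.abs(ref[left] - rts) <= np.abs(ref[right] - rts), left, right)
        within = np.abs(ref[nearest] - rts) <= rt_tolerance
        hit_counts = np.bincount(nearest[within], minlength=len(ref))
        if (hit_counts > 1).any():
            dup = feature_ids[np.argmax(hit_counts)]
            raise ValueError(
                f"two peaks match feature {dup!r} in sample {t.sample_id!r}; "
                "matching tolerance too wide"
            )
        for j, area in zip(nearest[within], areas[within]):
            fid = feature_ids[j]
            if np.isnan(area):
                values.loc[t.sample_id, fid] = np.nan
                status.loc[t.sample_id, fid] = NON_LOD_MISSING
            else:
                values.loc[t.sample_id, fid] = area
                status.loc[t.sample_id, fid] = OBSERVED

    meta = sample_meta.loc[values.index]
    return AbundanceMatrix(values, status, meta.copy())


@dataclass
class FilterReport:
    removed_features: list
    non_lod_frequency: pd.Series
    imputed_cells: int


def filter_features(
    matrix: AbundanceMatrix, threshold: float = 0.20
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop features with a high frequency of non-LOD missing cells.

    A feature is excluded when its non-LOD missing frequency strictly exceeds
    ``threshold`` (default 20% of samples; exactly 20% is retained).
    Surviving features' remaining non-LOD missing cells are imputed with the
    feature's minimum non-missing value so downstream PCA sees a complete
    matrix; imputed cells keep their non_lod_missing status for traceability.
    Samples are never removed.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    freq = (matrix.status == NON_LOD_MISSING).mean(axis=0)
    keep = freq.index[freq.to_numpy() <= threshold]
    removed = [f for f in matrix.feature_ids if f not in set(keep)]

    values = matrix.values[keep].copy()
    status = matrix.status[keep].copy()
    imputed = 0
    for fid in keep:
        mask = status[fid] == NON_LOD_MISSING
        if mask.any():
            fill = values.loc[~mask, fid].min()
            values.loc[mask, fid] = fill
            imputed += int(mask.sum())
    out = AbundanceMatrix(
        values,
        status,
        matrix.sample_meta.copy(),
        matrix.feature_meta.loc[keep].copy() if matrix.feature_meta is not None else None,
    )
    report = FilterReport(removed_features=removed, non_lod_frequency=freq, imputed_cells=imputed)
    return out, report
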