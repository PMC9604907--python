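"""Retention-time alignment, matrix assembly and the non-LOD filter."""

import numpy as np
import pandas as pd
import pytest

from vocrepeat.datatypes import LOD_FILLED, NON_LOD_MISSING, OBSERVED, PeakTable
from vocrepeat.pipeline import breath_residual_reduction, qc_residual_reduction
from vocrepeat.preprocess import (
    PiecewiseLinearMap,
    apply_alignment,
    assemble_feature_matrix,
    build_alignment_map,
    compute_qc_reference,
    filter_features,
)
from vocrepeat.simulate import SyntheticConfig, generate_peak_tables


def qc_table(compounds, rts, sample_id="QC_00", seq=0):
    return PeakTable(
        sample_id=sample_id,
        role="qc",
        sequence_index=seq,
        peaks=pd.DataFrame(
            {"compound_id": compounds, "retention_time_min": rts, "area": 1.0}
        ),
    )


def breath_table(rts, areas, sample_id="S01_D1", seq=0):
    return PeakTable(
        sample_id=sample_id,
        role="breath",
        sequence_index=seq,
        peaks=pd.DataFrame(
            {"compound_id": "", "retention_time_min": rts, "area": areas}
        ),
    )


class TestQCReference:
    def test_single_qc_table_is_its_own_reference(self):
        ref = compute_qc_reference([qc_table(["a", "b"], [5.0, 9.0])])
        assert ref == {"a": 5.0, "b": 9.0}

    def test_odd_count_median(self):
        tables = [qc_table(["a"], [rt], sample_id=f"QC_{i}") for i, rt in enumerate([5.0, 5.2, 5.4])]
        assert compute_qc_reference(tables)["a"] == pytest.approx(5.2)

    def test_even_count_median_is_mean_of_middle_pair(self):
        tables = [qc_table(["a"], [rt], sample_id=f"QC_{i}") for i, rt in enumerate([5.0, 5.2])]
        assert compute_qc_reference(tables)["a"] == pytest.approx(5.1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compute_qc_reference([])


class TestAlignmentMap:
    def test_identity_when_observed_equals_reference(self):
        amap = build_alignment_map(qc_table(["a", "b"], [1.0, 2.0]), {"a": 1.0, "b": 2.0})
        assert amap.transform(1.5) == pytest.approx(1.5)
        assert amap.local_slope(1.5) == pytest.approx(1.0)

    def test_linear_interpolation_between_anchors(self):
        amap = PiecewiseLinearMap([1.0, 2.0], [1.1, 2.1])
        assert amap.transform(1.5) == pytest.approx(1.6)

    def test_terminal_slope_extrapolation(self):
        amap = PiecewiseLinearMap([1.0, 2.0], [1.1, 2.1])
        assert amap.transform(0.5) == pytest.approx(0.6)
        assert amap.transform(2.5) == pytest.approx(2.6)

    def test_boundary_uses_left_segment_slope(self):
        amap = PiecewiseLinearMap([0.0, 1.0, 3.0], [0.0, 1.0, 5.0])
        # slopes are 1 then 2; at the shared anchor the left slope applies
        assert amap.local_slope(1.0) == pytest.approx(1.0)
        assert amap.local_slope(1.0001) == pytest.approx(2.0)

    def test_fewer_than_two_shared_compounds_rejected(self):
        with pytest.raises(ValueError):
            build_alignment_map(qc_table(["a", "b"], [1.0, 2.0]), {"a": 1.0})

    def test_non_monotone_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            build_alignment_map(
                qc_table(["a", "b", "c"], [1.0, 2.0, 3.0]), {"a": 1.0, "b": 2.5, "c": 2.2}
            )


class TestApplyAlignment:
    def test_identity_map_leaves_table_unchanged(self):
        t = breath_table([1.5, 2.5], [10.0, 20.0])
        amap = PiecewiseLinearMap([1.0, 3.0], [1.0, 3.0])
        out = apply_alignment(t, amap)
        pd.testing.assert_frame_equal(out.peaks, t.peaks)

    def test_uniform_shift_preserves_areas(self):
        t = breath_table([1.5, 2.5], [10.0, 20.0])
        amap = PiecewiseLinearMap([1.0, 3.0], [1.2, 3.2])
        out = apply_alignment(t, amap)
        assert np.allclose(out.peaks["retention_time_min"], [1.7, 2.7])
        assert np.allclose(out.peaks["area"], [10.0, 20.0])

    def test_slope_two_segment_halves_area(self):
        amap = PiecewiseLinearMap([1.0, 2.0], [1.0, 3.0])
        out = apply_alignment(breath_table([1.5], [10.0]), amap)
        assert out.peaks["area"].iloc[0] == pytest.approx(5.0)

    def test_global_slope_scales_every_area_by_its_inverse(self):
        s = 1.7
        amap = PiecewiseLinearMap([0.5, 10.0], [0.5 * s, 10.0 * s])
        areas = np.array([3.0, 7.0, 11.0])
        out = apply_alignment(breath_table([1.0, 4.0, 9.0], areas), amap)
        assert np.allclose(out.peaks["area"], areas / s)

    def test_alignment_is_idempotent_on_aligned_data(self):
        ref = {"a": 10.0, "b": 30.0, "c": 60.0}
        raw = qc_table(list(ref), [10.4, 30.1, 59.7])
        amap = build_alignment_map(raw, ref)
        aligned_qc = apply_alignment(raw, amap)
        second = build_alignment_map(aligned_qc, ref)
        rts = np.linspace(5, 65, 13)
        assert np.allclose(second.transform(rts), rts, atol=1e-9)


class TestAssemble:
    FEATURES = pd.Series([1.0, 2.0, 3.0], index=["f1", "f2", "f3"], name="reference_rt")
    META = pd.DataFrame(
        {"subject_id": ["A", "A"], "day": [1, 2], "batch": [0, 0]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )

    def test_complete_samples_give_all_observed(self):
        tables = [
            breath_table([1.0, 2.0, 3.0], [5.0, 6.0, 7.0], sample_id="s1"),
            breath_table([1.01, 1.99, 3.0], [8.0, 9.0, 10.0], sample_id="s2"),
        ]
        m = assemble_feature_matrix(tables, self.FEATURES, self.META)
        assert (m.status == OBSERVED).to_numpy().all()
        assert m.values.loc["s2", "f1"] == pytest.approx(8.0)

    def test_absent_feature_becomes_lod_filled_baseline(self):
        tables = [
            breath_table([1.0, 2.0, 3.0], [5.0, 6.0, 7.0], sample_id="s1"),
            breath_table([1.0, 3.0], [8.0, 10.0], sample_id="s2"),
        ]
        m = assemble_feature_matrix(tables, self.FEATURES, self.META, lod_baseline=0.5)
        assert m.status.loc["s2", "f2"] == LOD_FILLED
        assert m.values.loc["s2", "f2"] == pytest.approx(0.5)

    def test_nan_area_marks_non_lod_missing(self):
        tables = [
            breath_table([1.0, 2.0, 3.0], [5.0, np.nan, 7.0], sample_id="s1"),
            breath_table([1.0, 2.0, 3.0], [8.0, 9.0, 10.0], sample_id="s2"),
        ]
        m = assemble_feature_matrix(tables, self.FEATURES, self.META)
        assert m.status.loc["s1", "f2"] == NON_LOD_MISSING
        assert np.isnan(m.values.loc["s1", "f2"])

    def test_two_peaks_on_one_feature_rejected(self):
        tables = [
            breath_table([1.0, 2.0, 2.01, 3.0], [5.0, 6.0, 6.5, 7.0], sample_id="s1"),
            breath_table([1.0, 2.0, 3.0], [8.0, 9.0, 10.0], sample_id="s2"),
        ]
        with pytest.raises(ValueError, match="matching tolerance"):
            assemble_feature_matrix(tables, self.FEATURES, self.META)

    def test_duplicate_sample_ids_rejected(self):
        t = breath_table([1.0], [5.0], sample_id="s1")
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_matrix(
                [t, t],
                self.FEATURES,
                self.META,
            )


class TestFilter:
    def _matrix(self, missing_per_feature):
        """10 samples; each feature gets the requested number of non-LOD cells."""
        n = 10
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        values = pd.DataFrame(
            {f"f{j}": np.linspace(1, 2, n) * (j + 1) for j in range(len(missing_per_feature))},
            index=idx,
        )
        status = pd.DataFrame(OBSERVED, index=idx, columns=values.columns)
        for j, k in enumerate(missing_per_feature):
            values.iloc[:k, j] = np.nan
            status.iloc[:k, j] = NON_LOD_MISSING
        meta = pd.DataFrame({"subject_id": "A", "day": 1, "batch": 0}, index=idx)
        from vocrepeat.datatypes import AbundanceMatrix

        return AbundanceMatrix(values, status, meta)

    def test_strictly_above_20pct_excluded_exactly_20pct_kept(self):
        m = self._matrix([3, 2, 0])  # 30%, 20%, 0%
        out, report = filter_features(m, threshold=0.20)
        assert report.removed_features == ["f0"]
        assert list(out.feature_ids) == ["f1", "f2"]

    def test_row_count_invariant(self):
        m = self._matrix([5, 1, 0])
        out, _ = filter_features(m)
        assert out.n_samples == m.n_samples
        assert out.values.index.equals(m.values.index)

    def test_surviving_missing_cells_imputed_with_feature_minimum(self):
        m = self._matrix([0, 2, 0])
        out, report = filter_features(m)
        observed_min = m.values["f1"].min()
        assert report.imputed_cells == 2
        assert (out.values["f1"].iloc[:2] == observed_min).all()
        assert not out.values.isna().to_numpy().any()

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            filter_features(self._matrix([0]), threshold=1.5)


class TestWarpRecovery:
    def test_qc_anchor_residuals_vanish_after_alignment(self):
        tables, _ = generate_peak_tables(SyntheticConfig(seed=1))
        stats = qc_residual_reduction(tables)
        assert stats["pre_mean_abs"] > 0.01
        assert stats["post_mean_abs"] < 1e-9
        assert stats["reduction"] >= 0.9

    def test_breath_peak_dispersion_reduced_at_least_90pct(self):
        tables, truth = generate_peak_tables(SyntheticConfig(seed=1))
        stats = breath_residual_reduction(tables, truth)
        assert stats["reduction"] >= 0.9
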