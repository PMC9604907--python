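"""PCA, clinical correlation grid, group ellipses and the FeNO diagnostic."""

import numpy as np
import pandas as pd
import pytest

from vocrepeat.exploratory import (
    correlate_pcs,
    feno_association_flag,
    group_ellipses,
    run_pca,
    transform_granulocytes,
)


def frame(arr, prefix="f"):
    return pd.DataFrame(
        np.asarray(arr, float),
        index=[f"s{i}" for i in range(len(arr))],
        columns=[f"{prefix}{j}" for j in range(np.asarray(arr).shape[1])],
    )


class TestPCA:
    def test_collinear_data_loads_entirely_on_pc1(self):
        data = frame([[0, 0], [1, 2], [2, 4], [3, 6]])
        res = run_pca(data)
        assert res.explained_variance_ratio["PC1"] == pytest.approx(1.0)

    def test_explained_ratios_sum_to_one_with_all_components(self):
        rng = np.random.default_rng(0)
        res = run_pca(frame(rng.normal(size=(9, 4))), n_components=8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_ratio.to_numpy()) <= 1e-12).all()

    def test_near_collinear_worked_case(self):
        res = run_pca(frame([[0, 0], [1, 1], [2, 2], [3, 3.1]]))
        assert res.explained_variance_ratio["PC1"] > 0.99

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        res = run_pca(frame(rng.normal(size=(20, 6))), n_components=5)
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(gram, np.eye(5), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        res = run_pca(frame(rng.normal(size=(15, 5))))
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(3)
        data = frame(rng.normal(size=(10, 4)))
        res = run_pca(data, n_components=9)
        pd.testing.assert_frame_equal(res.reconstruct(), data, check_exact=False, atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            run_pca(frame([[1.0, 2.0]]))


class TestGranulocyteTransform:
    def test_pure_log_without_zeros(self):
        out = transform_granulocytes([1.0, np.e, np.e**2])
        assert np.allclose(out, [0.0, 1.0, 2.0])

    def test_zero_handled_by_half_min_positive(self):
        out = transform_granulocytes([0.0, 2.0, 10.0])
        assert out[0] == pytest.approx(0.0)  # ln(0 + 1)

    def test_order_preserved(self):
        x = np.array([0.0, 0.4, 3.0, 40.0, 99.0])
        assert (np.diff(transform_granulocytes(x)) > 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_granulocytes([-1.0, 5.0])


class TestCorrelationGrid:
    def _setup(self):
        rng = np.random.default_rng(0)
        subjects = pd.Series(
            np.repeat([f"S{i}" for i in range(6)], 2),
            index=[f"s{i}" for i in range(12)],
        )
        scores = pd.DataFrame(
            {
                "PC1": np.repeat(rng.normal(size=6), 2) + 0.05 * rng.normal(size=12),
                "PC2": rng.normal(size=12),
            },
            index=subjects.index,
        )
        clinical = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(6)],
                "feno_ppb": np.exp(rng.normal(3.6, 0.4, 6)),
                "sputum_eos_pct": [0.0, 1.0, 2.0, 5.0, 10.0, 40.0],
                "atopy": [0, 1, 0, 1, 1, 0],
                "gord": [1, 1, 1, 1, 1, 1],  # zero variance
            }
        )
        return scores, clinical, subjects

    def test_covariate_equal_to_scores_has_unit_correlation(self):
        scores, clinical, subjects = self._setup()
        clinical["feno_ppb"] = (
            scores.groupby(subjects).mean()["PC1"].loc[clinical["subject_id"]].to_numpy() + 10.0
        )
        scores["PC1"] = np.repeat(
            scores.groupby(subjects).mean()["PC1"].to_numpy(), 2
        )  # make expansion exact
        grid = correlate_pcs(scores, clinical, subjects)
        row = grid[(grid.component == "PC1") & (grid.covariate == "feno_ppb")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-10 and row.significant

    def test_known_pearson_pair(self):
        # x=[1..5], y=[1,3,2,5,4]: r = 0.8, two-sided p ~ 0.104
        subjects = pd.Series([f"S{i}" for i in range(5)], index=[f"s{i}" for i in range(5)])
        scores = pd.DataFrame({"PC1": [1.0, 2, 3, 4, 5]}, index=subjects.index)
        clinical = pd.DataFrame(
            {"subject_id": subjects.to_numpy(), "feno_ppb": [1.0, 3, 2, 5, 4]}
        )
        grid = correlate_pcs(scores, clinical, subjects, include_subject=False)
        row = grid.iloc[0]
        assert row.r == pytest.approx(0.8, abs=1e-12)
        assert row.p == pytest.approx(0.104, abs=0.001)
        assert not row.significant

    def test_binary_covariates_use_point_biserial(self):
        scores, clinical, subjects = self._setup()
        grid = correlate_pcs(scores, clinical, subjects)
        methods = grid.set_index(["component", "covariate"])["method"]
        assert methods.loc[("PC1", "atopy")] == "point_biserial"
        assert methods.loc[("PC1", "feno_ppb")] == "pearson"
        # point-biserial is literally Pearson on the 0/1 coding
        from scipy.stats import pearsonr

        expanded = clinical.set_index("subject_id").loc[subjects]["atopy"].to_numpy(float)
        r_manual = pearsonr(scores["PC1"].to_numpy(), expanded)[0]
        assert grid.set_index(["component", "covariate"]).loc[("PC1", "atopy"), "r"] == pytest.approx(
            r_manual
        )

    def test_zero_variance_covariate_flagged_not_correlated(self):
        scores, clinical, subjects = self._setup()
        grid = correlate_pcs(scores, clinical, subjects)
        row = grid[(grid.component == "PC1") & (grid.covariate == "gord")].iloc[0]
        assert row.method == "skipped_zero_variance"
        assert np.isnan(row.r) and not row.significant

    def test_subject_row_present_with_one_vs_rest_maximum(self):
        scores, clinical, subjects = self._setup()
        grid = correlate_pcs(scores, clinical, subjects)
        assert "subject" in set(grid.covariate)
        sub = grid[grid.covariate == "subject"]
        assert (sub.method == "point_biserial_max").all()


class TestEllipses:
    def _scores(self, pc1, pc2, groups):
        idx = [f"s{i}" for i in range(len(pc1))]
        return (
            pd.DataFrame({"PC1": pc1, "PC2": pc2}, index=idx),
            pd.Series(groups, index=idx),
        )

    def test_identical_points_give_degenerate_ellipse(self):
        scores, groups = self._scores([1.0, 1.0], [2.0, 2.0], ["A", "A"])
        (e,) = group_ellipses(scores, groups)
        assert e.center == (1.0, 2.0)
        assert e.semi_axes == (0.0, 0.0)

    def test_semi_axis_is_1p96_sample_sd(self):
        scores, groups = self._scores([-1.0, 1.0], [0.0, 0.0], ["A", "A"])
        (e,) = group_ellipses(scores, groups)
        assert e.semi_axes[0] == pytest.approx(1.96 * np.sqrt(2), abs=1e-6)

    def test_one_ellipse_per_group(self):
        scores, groups = self._scores([0, 1, 2, 3], [0, 1, 2, 3], ["A", "A", "B", "B"])
        assert {e.label for e in group_ellipses(scores, groups)} == {"A", "B"}

    def test_singleton_group_rejected(self):
        scores, groups = self._scores([0, 1, 2], [0, 1, 2], ["A", "A", "B"])
        with pytest.raises(ValueError):
            group_ellipses(scores, groups)


class TestCohortStructure:
    def test_subject_identity_dominates_leading_component(self, default_run):
        """Between-subject variance of PC1 scores exceeds within-subject."""
        scores = run_pca(default_run["scaled"]).scores
        subjects = default_run["curated"].subjects
        between = scores.groupby(subjects)["PC1"].mean().var()
        within = scores.groupby(subjects)["PC1"].var().mean()
        assert between > within

    def test_sample_level_grid_flags_feno_on_a_leading_pc(self, default_run):
        pca = run_pca(default_run["scaled"])
        grid = correlate_pcs(pca.scores, default_run["clinical"], default_run["curated"].subjects)
        lead = grid[grid.component.isin(["PC1", "PC2", "PC3"]) & (grid.covariate == "feno_ppb")]
        assert lead.significant.any()

    def test_feno_flag_fires_with_planted_t2(self, default_run):
        pca = run_pca(default_run["scaled"])
        assert feno_association_flag(
            pca.scores, default_run["clinical"], default_run["curated"].subjects
        )
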