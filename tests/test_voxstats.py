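import numpy as np
import numpy.linalg as la
import pandas as pd
import pytest
from scipy import stats as sps

from octvbm import (
    GLMSpec,
    GroupStack,
    cluster_filter,
    cluster_table,
    fdr_correct,
    render_overlay,
    voxelwise_glm,
    voxelwise_regression,
)
from octvbm.errors import DegenerateInputError, DesignError


def _stack(data, cov, layer="GCIPL"):
    return GroupStack(layer=layer, data=data, covariates=cov)


class TestVoxelwiseGLM:
    def test_identical_samples_give_t0_p1(self):
        y = np.tile([1.0, 2.0, 3.0], 2)[:, None, None]
        cov = pd.DataFrame({"subject_id": list("abcdef"),
                            "group": ["HC"] * 3 + ["MS"] * 3})
        sms = voxelwise_glm(_stack(y, cov), spec=GLMSpec(covariates=()))
        assert sms.stat[0, 0] == 0.0
        assert sms.p[0, 0] == 1.0

    def test_no_covariate_t_equals_pooled_two_sample_t(self, rng):
        n = 30
        y = rng.normal(100, 8, (n, 6, 7))
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                            "group": ["HC"] * 15 + ["MS"] * 15})
        sms = voxelwise_glm(_stack(y, cov), spec=GLMSpec(covariates=()))
        ref = sps.ttest_ind(y[15:], y[:15], axis=0, equal_var=True)
        np.testing.assert_allclose(sms.stat, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(sms.p, ref.pvalue, atol=1e-10)

    def test_full_design_matches_normal_equations_oracle(self, rng,
                                                         two_group_covariates):
        n = 40
        cov = two_group_covariates(20, rng)
        y = rng.normal(80, 10, (n, 5, 6))
        ret = rng.normal(300, 25, (n, 5, 6))
        sms = voxelwise_glm(_stack(y, cov), _stack(ret, cov, "Retina"),
                            GLMSpec())
        for r in range(5):
            for c in range(6):
                X = np.column_stack([
                    np.ones(n), (cov["group"] == "MS").astype(float),
                    cov["age"], (cov["sex"] == "M").astype(float),
                    ret[:, r, c]])
                beta = la.solve(X.T @ X, X.T @ y[:, r, c])
                assert abs(beta[1] - sms.beta["group[MS]"][r, c]) < 1e-10
                resid = y[:, r, c] - X @ beta
                se = np.sqrt(resid @ resid / (n - 5)
                             * la.inv(X.T @ X)[1, 1])
                assert abs(beta[1] / se - sms.stat[r, c]) < 1e-10

    def test_diff_map_is_raw_group_mean_difference(self, rng,
                                                   two_group_covariates):
        cov = two_group_covariates(10, rng)
        y = rng.normal(80, 10, (20, 4, 4))
        ret = rng.normal(300, 25, (20, 4, 4))
        sms = voxelwise_glm(_stack(y, cov), _stack(ret, cov, "Retina"),
                            GLMSpec())
        expected = y[10:].mean(axis=0) - y[:10].mean(axis=0)
        np.testing.assert_allclose(sms.diff, expected, atol=1e-12)

    def test_omnibus_f_matches_anova_without_covariates(self, rng):
        n = 30
        y = rng.normal(100, 8, (n, 3, 3))
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                            "group": ["HC"] * 10 + ["CIS"] * 10 + ["RMS"] * 10})
        sms = voxelwise_glm(_stack(y, cov),
                            spec=GLMSpec(covariates=(), contrast="omnibus-F"))
        ref = sps.f_oneway(y[:10], y[10:20], y[20:], axis=0)
        np.testing.assert_allclose(sms.stat, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(sms.p, ref.pvalue, atol=1e-10)

    def test_underpowered_voxels_excluded(self, rng, two_group_covariates):
        cov = two_group_covariates(10, rng)
        y = rng.normal(80, 10, (20, 3, 3))
        y[:18, 0, 0] = np.nan       # 2 remaining < p + 1
        sms = voxelwise_glm(_stack(y, cov), spec=GLMSpec(covariates=("age",)))
        assert sms.n_effective[0, 0] == 0
        assert np.isnan(sms.stat[0, 0])

    def test_single_group_rejected(self, rng):
        cov = pd.DataFrame({"subject_id": ["a", "b"], "group": ["HC", "HC"]})
        with pytest.raises(DesignError):
            voxelwise_glm(_stack(np.zeros((2, 2, 2)), cov))


class TestFDR:
    def test_hand_worked_bh_step_up(self):
        p = np.array([[0.01, 0.02], [0.03, 0.04]])
        reject, cutoff = fdr_correct(p, alpha=0.05)
        assert reject.all()          # largest i with p(i) <= i*alpha/m is 4
        assert cutoff == 0.04

    def test_all_ones_reject_nothing(self):
        reject, cutoff = fdr_correct(np.ones((3, 3)), alpha=0.05)
        assert not reject.any()
        assert cutoff == 0.0

    def test_shrinking_alpha_never_adds_rejections(self, rng):
        p = rng.random((10, 10))
        r_large, _ = fdr_correct(p, alpha=0.10)
        r_small, _ = fdr_correct(p, alpha=0.01)
        assert not (r_small & ~r_large).any()

    def test_empty_family_warns(self):
        with pytest.warns(UserWarning):
            reject, cutoff = fdr_correct(np.full((2, 2), np.nan))
        assert not reject.any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DegenerateInputError):
            fdr_correct(np.array([[1.5]]))


class TestClusterFilter:
    def test_default_extent_keeps_3x3_drops_isolated(self):
        sig = np.zeros((10, 10), dtype=bool)
        sig[1:4, 1:4] = True
        sig[8, 8] = True
        filtered, labels = cluster_filter(sig)
        assert filtered[1:4, 1:4].all()
        assert not filtered[8, 8]
        assert labels.max() == 1

    def test_empty_grid(self):
        filtered, labels = cluster_filter(np.zeros((5, 5), dtype=bool))
        assert not filtered.any()
        assert labels.max() == 0

    def test_size_threshold_between_components(self):
        sig = np.zeros((12, 20), dtype=bool)
        sig[1:3, 1:5] = True            # 8 voxels
        sig[6:8, 8:13] = True           # 10 voxels
        filtered, labels = cluster_filter(sig, min_voxels=9, connectivity=8)
        assert not filtered[1:3, 1:5].any()
        assert filtered[6:8, 8:13].all()
        assert labels[6, 8] == 1

    def test_labels_ordered_by_decreasing_size(self):
        sig = np.zeros((20, 20), dtype=bool)
        sig[1:4, 1:4] = True            # 9 voxels
        sig[10:14, 10:14] = True        # 16 voxels
        _, labels = cluster_filter(sig, min_voxels=9)
        assert labels[10, 10] == 1
        assert labels[1, 1] == 2

    def test_connectivity_4_splits_diagonal(self):
        sig = np.zeros((6, 6), dtype=bool)
        sig[0:2, 0:2] = True
        sig[2, 2] = True                # diagonal touch only
        f8, _ = cluster_filter(sig, min_voxels=5, connectivity=8)
        f4, _ = cluster_filter(sig, min_voxels=5, connectivity=4)
        assert f8.sum() == 5
        assert f4.sum() == 0

    def test_raising_min_voxels_never_adds_clusters(self, rng):
        sig = rng.random((30, 30)) < 0.3
        f_small, _ = cluster_filter(sig, min_voxels=4)
        f_large, _ = cluster_filter(sig, min_voxels=10)
        assert not (f_large & ~f_small).any()


class TestVoxelwiseRegression:
    def test_exact_linear_response_has_src_one(self):
        n = 20
        age = np.linspace(20, 60, n)
        y = np.broadcast_to((2 * age)[:, None, None], (n, 3, 3)).copy()
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                            "group": "MS", "age": age})
        sms = voxelwise_regression(_stack(y, cov), "age")
        np.testing.assert_allclose(sms.beta["SRC"], 1.0, atol=1e-10)
        assert (sms.p < 1e-12).all()

    def test_src_equals_pearson_r_without_adjusters(self, rng):
        n = 50
        age = rng.normal(40, 12, n)
        y = rng.normal(80, 10, (n, 4, 5))
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                            "group": "MS", "age": age})
        sms = voxelwise_regression(_stack(y, cov), "age")
        for r in range(4):
            for c in range(5):
                assert sms.beta["SRC"][r, c] == pytest.approx(
                    sps.pearsonr(age, y[:, r, c]).statistic, abs=1e-10)

    def test_independent_covariate_src_near_zero(self, rng):
        n = 200
        edss = rng.uniform(0, 7, n)
        y = rng.normal(80, 10, (n, 8, 8))
        cov = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                            "group": "MS", "edss": edss})
        sms = voxelwise_regression(_stack(y, cov), "edss")
        assert abs(np.nanmean(sms.beta["SRC"])) < 0.05

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"subject_id": ["a", "b", "c"], "group": "MS",
                            "edss": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateInputError):
            voxelwise_regression(_stack(np.zeros((3, 2, 2)), cov), "edss")


class TestClusterTableAndOverlay:
    def _sms(self, rng, two_group_covariates):
        cov = two_group_covariates(15, rng)
        y = rng.normal(80, 3, (30, 10, 12))
        y[15:, 2:6, 2:7] -= 12.0
        return voxelwise_glm(_stack(y, cov), spec=GLMSpec(covariates=()))

    def test_cluster_table_describes_components(self, rng,
                                                two_group_covariates):
        sms = self._sms(rng, two_group_covariates)
        table = cluster_table(sms)
        assert len(table) >= 1
        top = table.iloc[0]
        assert top["size_voxels"] >= 9
        assert top["mean_diff_um"] < 0

    def test_overlay_renders_and_clips(self, rng, two_group_covariates,
                                       tmp_path):
        sms = self._sms(rng, two_group_covariates)
        img = render_overlay(sms, sms.diff, color_range=5.0,
                             path=tmp_path / "o.png")
        assert img.ndim == 3 and img.shape[2] == 4
        assert (tmp_path / "o.png").exists()

    def test_overlay_without_significant_voxels(self, rng,
                                                two_group_covariates):
        cov = two_group_covariates(5, rng)
        y = rng.normal(80, 3, (10, 6, 6))
        sms = voxelwise_glm(_stack(y, cov), spec=GLMSpec(covariates=()))
        img = render_overlay(sms, sms.diff, color_range=5.0)
        assert img.ndim == 3

    def test_sig_implies_p_below_cutoff_and_labelled(self, rng,
                                                     two_group_covariates):
        sms = self._sms(rng, two_group_covariates)
        assert sms.sig.any()
        assert (sms.p[sms.sig] <= sms.q_threshold + 1e-15).all()
        assert (sms.clusters[sms.sig] > 0).all()
        sizes = np.bincount(sms.clusters[sms.clusters > 0])
        assert (sizes[1:] >= sms.min_cluster_voxels).all()
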