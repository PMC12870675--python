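import numpy as np
import pandas as pd
import pytest
from scipy import integrate, ndimage, stats

from fndconn.glm import (
    Z_CAP,
    ModelError,
    apply_cluster_correction,
    cluster_null_distribution,
    estimate_map_smoothness,
    fit_brain_behavior_glm,
    posthoc_covariate_sensitivity,
    t_to_z,
)

# ---- printed n=8 design used for the normal-equations oracle -------------
AGE = np.array([31.0, 45.0, 52.0, 28.0, 60.0, 39.0, 47.0, 33.0])
SEX = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
METRIC = np.array([[12.1, 9.4, 15.2, 8.8, 11.0, 13.7, 10.3, 14.6],
                   [2.0, 2.1, 1.9, 2.4, 2.2, 2.0, 2.3, 1.8]]).T
OUTCOME = np.array([-3.0, 1.0, -6.0, 2.5, 0.0, -4.0, 1.5, -5.0])
COVS = pd.DataFrame({"age": AGE, "sex": SEX})


def oracle_t(metric_col, y, covs):
    """Explicit (X'X)^-1 X'y least squares; t = beta / SE."""
    X = np.column_stack([np.ones(len(y)), metric_col,
                         covs["age"] - covs["age"].mean(), covs["sex"]])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    return beta[1] / se, df


class TestBrainBehaviorGlm:
    def test_metric_t_matches_normal_equations_oracle(self):
        res = fit_brain_behavior_glm(
            (METRIC, np.zeros((2, 3), dtype=int)), OUTCOME, COVS,
            covariate_columns=["age", "sex"],
        )
        for v in range(METRIC.shape[1]):
            t_ref, df_ref = oracle_t(METRIC[:, v], OUTCOME, COVS)
            assert res.t[v] == pytest.approx(t_ref, abs=1e-8)
            assert res.df == df_ref

    def test_swapping_outcome_and_metric_roles_preserves_t(self):
        """Partial-correlation symmetry: the t of the term of interest is
        identical when the metric is regressed on the outcome."""
        res_fwd = fit_brain_behavior_glm(
            (METRIC, np.zeros((2, 3), dtype=int)), OUTCOME, COVS,
            covariate_columns=["age", "sex"],
        )
        swapped = np.tile(OUTCOME[:, None], (1, 2))
        res_rev = fit_brain_behavior_glm(
            (swapped, np.zeros((2, 3), dtype=int)), METRIC[:, 0], COVS,
            covariate_columns=["age", "sex"],
        )
        assert res_rev.t[0] == pytest.approx(res_fwd.t[0], abs=1e-8)

    def test_perfect_fit_is_capped_and_flagged(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((12, 2))
        y = 2.0 * M[:, 0]  # exact linear function of voxel 0
        covs = pd.DataFrame({"age": rng.uniform(20, 60, 12),
                             "sex": rng.integers(0, 2, 12).astype(float)})
        res = fit_brain_behavior_glm((M, np.zeros((2, 3), int)), y, covs,
                                     covariate_columns=["age", "sex"])
        assert abs(res.z[0]) == Z_CAP
        assert res.saturated[0]

    def test_zero_variance_voxel_masked_out(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((12, 3))
        M[:, 1] = 7.7
        covs = pd.DataFrame({"age": rng.uniform(20, 60, 12),
                             "sex": rng.integers(0, 2, 12).astype(float)})
        with pytest.warns(RuntimeWarning, match="zero metric variance"):
            res = fit_brain_behavior_glm(
                (M, np.zeros((3, 3), int)), rng.standard_normal(12), covs,
                covariate_columns=["age", "sex"])
        assert res.z[1] == 0.0 and res.zero_variance[1]

    def test_collinear_design_names_culprit(self):
        covs = COVS.assign(age2=COVS["age"] * 2.0)
        with pytest.raises(ModelError, match="age2"):
            fit_brain_behavior_glm(
                (METRIC, np.zeros((2, 3), int)), OUTCOME, covs,
                covariate_columns=["age", "age2", "sex"])

    def test_constant_covariate_dropped_with_warning(self):
        covs = COVS.assign(ssri_snri=np.ones(8))
        with pytest.warns(RuntimeWarning, match="constant"):
            res = fit_brain_behavior_glm(
                (METRIC, np.zeros((2, 3), int)), OUTCOME, covs,
                covariate_columns=["age", "sex", "ssri_snri"])
        assert "ssri_snri" not in res.design_columns


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 5) == 0.0

    def test_large_df_limit_is_identity(self):
        assert t_to_z(1.7, 10**6) == pytest.approx(1.7, abs=1e-3)

    def test_matches_quadrature_of_t_density(self):
        t_val, df = 2.5, 10

        def t_pdf(x):
            from math import gamma, pi, sqrt
            return (gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))
                    * (1 + x * x / df) ** (-(df + 1) / 2))

        tail, _ = integrate.quad(t_pdf, t_val, np.inf)
        z_ref = stats.norm.isf(tail)
        assert t_to_z(t_val, df) == pytest.approx(z_ref, abs=1e-8)

    def test_sign_preserving_and_monotone(self):
        ts = np.linspace(-6, 6, 25)
        zs = t_to_z(ts, 8)
        assert np.all(np.diff(zs) > 0)
        assert np.allclose(t_to_z(-ts, 8), -zs)  # odd function

    def test_nonfinite_t_propagates_flagged(self):
        z, sat = t_to_z(np.array([np.inf, -np.inf, np.nan]), 5,
                        return_saturated=True)
        assert z[0] == Z_CAP and z[1] == -Z_CAP
        assert sat[0] and sat[1]
        assert np.isnan(z[2])


class TestSmoothnessEstimator:
    def test_white_noise_estimates_one_voxel(self, rng):
        mask = np.ones((22, 22, 22), dtype=bool)  # ~10^4 voxels
        maps = rng.standard_normal((4, mask.sum()))
        fwhm = estimate_map_smoothness(maps, mask)
        assert np.all(fwhm >= 1.0) and np.all(fwhm <= 1.2)

    def test_known_kernel_recovered(self, rng):
        mask = np.ones((24, 24, 24), dtype=bool)
        sigma = 3.0 / (2 * np.sqrt(2 * np.log(2)))
        vols = ndimage.gaussian_filter(
            rng.standard_normal((3, 24, 24, 24)), sigma=(0, sigma, sigma, sigma))
        maps = vols.reshape(3, -1)
        fwhm = estimate_map_smoothness(maps, mask)
        assert np.all(fwhm >= 2.4) and np.all(fwhm <= 3.6)

    def test_single_voxel_mask_rejected(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError):
            estimate_map_smoothness(np.ones((2, 1)), mask)

    def test_all_constant_maps_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="constant"):
            estimate_map_smoothness(np.ones((3, 64)), mask)


class TestClusterNull:
    def test_same_seed_reproduces_extents(self, space):
        a = cluster_null_distribution(space.grey_mask, 1.0, n_iter=150, seed=3)
        b = cluster_null_distribution(space.grey_mask, 1.0, n_iter=150, seed=3)
        assert np.array_equal(a.max_extents, b.max_extents)

    def test_absurd_threshold_flags_degenerate_null(self, space):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            null = cluster_null_distribution(space.grey_mask, 1.0,
                                             z_thresh=10.0, n_iter=150, seed=0)
        assert null.degenerate
        assert np.all(null.max_extents == 0)

    def test_extent_threshold_monotone_in_fwhm_and_z(self, space):
        thresholds = {}
        for fwhm in (1.0, 2.0, 3.0):
            for z in (1.5, 1.96, 2.5):
                null = cluster_null_distribution(
                    space.grey_mask, fwhm, z_thresh=z, n_iter=800, seed=11)
                thresholds[(fwhm, z)] = null.extent_threshold
        for z in (1.5, 1.96, 2.5):
            assert (thresholds[(1.0, z)] <= thresholds[(2.0, z)]
                    <= thresholds[(3.0, z)])
        for fwhm in (1.0, 2.0, 3.0):
            assert (thresholds[(fwhm, 1.5)] >= thresholds[(fwhm, 1.96)]
                    >= thresholds[(fwhm, 2.5)])

    def test_preconditions(self, space):
        with pytest.raises(ValueError):
            cluster_null_distribution(space.grey_mask, 1.0, z_thresh=-1.0)
        with pytest.raises(ValueError):
            cluster_null_distribution(space.grey_mask, 1.0, n_iter=50)


class TestClusterCorrection:
    def _null(self, space, thr=12):
        null = cluster_null_distribution(space.grey_mask, 1.0, n_iter=150, seed=0)
        null.extent_threshold = thr
        return null

    def test_zero_map_yields_empty_table(self, space):
        null = self._null(space)
        table, sig = apply_cluster_correction(
            np.zeros(space.n), space.grey_mask, null)
        assert len(table) == 0 and not sig.any()

    def test_planted_blob_survives(self, space):
        null = self._null(space, thr=12)
        z = np.zeros(space.n)
        vi = space.grey_index
        blob = (vi[:, 0] >= 3) & (vi[:, 0] <= 6) & (vi[:, 1] >= 3) & \
               (vi[:, 1] <= 6) & (vi[:, 2] >= 3) & (vi[:, 2] <= 5)
        assert blob.sum() >= 45
        z[blob] = 5.0
        table, sig = apply_cluster_correction(z, space.grey_mask, null)
        assert len(table) == 1
        assert table["extent"].iloc[0] == blob.sum()
        assert table["sign"].iloc[0] == "positive"
        assert sig.sum() == blob.sum()

    def test_positive_and_negative_clusters_labeled_separately(self, space):
        null = self._null(space, thr=5)
        z = np.zeros(space.n)
        vi = space.grey_index
        z[(vi[:, 0] <= 3) & (vi[:, 1] <= 2) & (vi[:, 2] <= 2)] = 4.0
        z[(vi[:, 0] >= 8) & (vi[:, 1] >= 8) & (vi[:, 2] >= 6)] = -4.0
        table, _ = apply_cluster_correction(z, space.grey_mask, null)
        assert sorted(table["sign"]) == ["negative", "positive"]

    def test_single_voxel_below_extent_threshold_removed(self, space):
        null = self._null(space, thr=2)
        z = np.zeros(space.n)
        z[17] = 6.0
        table, sig = apply_cluster_correction(z, space.grey_mask, null)
        assert len(table) == 0 and not sig.any()


@pytest.fixture(scope="module")
def primary(space, effect_cohort):
    from fndconn.pipeline import analyze
    return analyze(effect_cohort, "integration", "baseline_predictor",
                   "soms_cd", n_iter=400, seed=5)


class TestCovariateSensitivity:
    def test_noise_covariate_does_not_kill_planted_cluster(
            self, space, effect_cohort, primary):
        assert len(primary["cluster_table"]) >= 1
        cov = primary["covariates"].copy()
        rng = np.random.default_rng(3)
        cov["pure_noise"] = rng.standard_normal(len(cov))
        table = posthoc_covariate_sensitivity(
            (primary["metric_matrix"], primary["voxel_index"]),
            primary["outcome"], cov, {"noise": ["pure_noise"]},
            primary["cluster_table"], primary["sig_mask"], space.iso_mask,
            n_iter=400, seed=5,
        )
        # the planted-region cluster (largest) must be held
        biggest = primary["cluster_table"]["extent"].idxmax()
        cid = int(primary["cluster_table"].loc[biggest, "cluster_id"])
        held = table.query("covariate_set == 'noise' and cluster_id == @cid")
        assert held["held"].iloc[0]

    def test_outcome_as_covariate_absorbs_effect(
            self, space, effect_cohort, primary):
        cov = primary["covariates"].copy()
        cov["outcome_copy"] = primary["outcome"]
        table = posthoc_covariate_sensitivity(
            (primary["metric_matrix"], primary["voxel_index"]),
            primary["outcome"], cov, {"absorb": ["outcome_copy"]},
            primary["cluster_table"], primary["sig_mask"], space.iso_mask,
            n_iter=400, seed=5,
        )
        assert not table["held"].any()

    def test_empty_extra_set_reproduces_primary(self, space, effect_cohort, primary):
        table = posthoc_covariate_sensitivity(
            (primary["metric_matrix"], primary["voxel_index"]),
            primary["outcome"], primary["covariates"], {"none": []},
            primary["cluster_table"], primary["sig_mask"], space.iso_mask,
            n_iter=primary["null"].n_iterations, seed=5,
        )
        assert table["held"].all()
        assert (table["n_overlap"] > 0).all()
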