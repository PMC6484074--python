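import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import sekrige as sk
from sekrige.reml import NestedIndex
from sekrige.validation import CHI2_1_MEDIAN

from conftest import plugin_model


def brute_force_loo(table, model):
    """Explicit per-fold OK solves with the observed-individual target
    covariance (shared household and cluster components included)."""
    idx = NestedIndex.from_table(table)
    C = sk.assemble_covariance(
        idx.cl_codes, idx.hh_codes, model.components, model.matern,
        idx.cluster_coords,
    )
    z = np.log(table["plasma_se"].to_numpy())
    n = len(z)
    preds, s2s = np.empty(n), np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        m = n - 1
        H = np.zeros((m + 1, m + 1))
        H[:m, :m] = C[np.ix_(keep, keep)]
        H[:m, m] = 1.0
        H[m, :m] = 1.0
        c0 = C[keep, i]
        sol = np.linalg.solve(H, np.r_[c0, 1.0])
        preds[i] = sol[:m] @ z[keep]
        s2s[i] = C[i, i] - sol[:m] @ c0 - sol[m]
    return preds, s2s


class TestLooCrossvalidate:
    def test_iid_closed_form(self):
        """Under sigma2_c=sigma2_h=0 the LOO prediction is the mean of the
        other n-1 values with variance sigma2_e (1 + 1/(n-1))."""
        n = 12
        rng = np.random.default_rng(3)
        z = 4.0 + 0.2 * rng.standard_normal(n)
        t = pd.DataFrame(
            {
                "individual_id": np.arange(n),
                "household_id": np.arange(n),
                "cluster_id": np.arange(n),  # distinct clusters, no spatial term
                "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n),
                "urban": False,
                "group": "WRA",
                "wealth_quintile": 3,
                "plasma_se": np.exp(z),
            }
        )
        s2e = 0.04
        params = sk.GenerativeParams(
            mu=4.0,
            components=sk.VarianceComponents(0.0, 0.0, s2e),
            matern=sk.MaternParams(0.5, 39.4),
        )
        cv = sk.loo_crossvalidate(t, plugin_model(params, n))
        expected_s2 = s2e * (1 + 1 / (n - 1))
        for i in range(n):
            others = np.delete(z, i)
            assert cv["predicted"].iloc[i] == pytest.approx(others.mean(), abs=1e-10)
            assert cv["s2"].iloc[i] == pytest.approx(expected_s2, abs=1e-10)
            theta = (z[i] - others.mean()) ** 2 / expected_s2
            assert cv["theta"].iloc[i] == pytest.approx(theta, abs=1e-10)

    def test_translation_invariant_thetas(self, small_table, malawi_params):
        model = plugin_model(malawi_params, len(small_table))
        cv1 = sk.loo_crossvalidate(small_table, model)
        shifted = small_table.copy()
        shifted["plasma_se"] = shifted["plasma_se"] * np.exp(0.9)
        cv2 = sk.loo_crossvalidate(shifted, model)
        assert np.allclose(cv1["theta"], cv2["theta"], atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_folds(self, malawi_params, seed):
        """Bordered-precision shortcut equals explicit per-fold dense OK
        solves (spatial + household target covariance respected)."""
        d = sk.generate_design(4, 0.25, 2, 2, seed=seed)
        t = sk.simulate_survey(d, malawi_params, seed=seed + 40)
        model = plugin_model(malawi_params, len(t))
        cv = sk.loo_crossvalidate(t, model)
        preds, s2s = brute_force_loo(t, model)
        assert np.allclose(cv["predicted"], preds, atol=1e-9)
        assert np.allclose(cv["s2"], s2s, atol=1e-9)

    def test_permutation_invariance(self, small_table, malawi_params):
        model = plugin_model(malawi_params, len(small_table))
        cv1 = sk.loo_crossvalidate(small_table, model).set_index("individual_id")
        rng = np.random.default_rng(5)
        perm = small_table.iloc[rng.permutation(len(small_table))].reset_index(
            drop=True
        )
        cv2 = sk.loo_crossvalidate(perm, model).set_index("individual_id")
        cv2 = cv2.loc[cv1.index]
        assert np.allclose(cv1["theta"], cv2["theta"], atol=1e-8)

    def test_too_few_observations_rejected(self, malawi_params):
        d = sk.generate_design(1, 0.0, 1, 2, seed=1)
        t = sk.simulate_survey(d, malawi_params, seed=2)
        with pytest.raises(ValueError):
            sk.loo_crossvalidate(t, plugin_model(malawi_params, len(t)))


class TestSspeSummary:
    def test_hand_computed_median_and_mean(self):
        rec = pd.DataFrame(
            {"theta": [0.1, 0.4, 0.9], "flagged": [False] * 3}
        )
        s = sk.sspe_summary(rec)
        assert s.median_theta == pytest.approx(0.4)
        assert s.mean_theta == pytest.approx(0.4667, abs=1e-4)

    def test_constant_thetas(self):
        rec = pd.DataFrame({"theta": [0.7] * 5, "flagged": [False] * 5})
        s = sk.sspe_summary(rec)
        assert s.median_theta == s.mean_theta == 0.7

    def test_empty_rejected(self):
        rec = pd.DataFrame({"theta": [1.0], "flagged": [True]})
        with pytest.raises(ValueError):
            sk.sspe_summary(rec)


class TestValidModelCalibration:
    def test_mean_near_one_median_near_chi2_median(self):
        """Simulating from the model itself: mean SSPE ~ 1 and, with weak
        spatial correlation, median SSPE ~ median of chi-square(1)."""
        d = sk.generate_design(
            300, 0.0, 1, 2, region=box(0, 0, 9000, 9000), seed=21
        )
        params = sk.GenerativeParams(
            mu=4.3,
            components=sk.VarianceComponents(0.02, 0.018, 0.028),
            matern=sk.MaternParams(0.5, 39.4),
        )
        t = sk.simulate_survey(d, params, seed=22)
        cv = sk.loo_crossvalidate(t, plugin_model(params, len(t)))
        s = sk.sspe_summary(cv)
        assert s.n_used >= 500
        assert 0.9 <= s.mean_theta <= 1.1
        assert s.median_theta == pytest.approx(CHI2_1_MEDIAN, abs=0.1)


class TestMedianSspeInterval:
    def test_covers_chi2_median_and_observed(self, malawi_params):
        design = sk.generate_design(25, 0.2, 3, 2, seed=31)
        model = plugin_model(malawi_params)
        lo, hi = sk.median_sspe_interval(model, design, n_sim=120, seed=32)
        assert lo < hi
        assert lo < CHI2_1_MEDIAN < hi
        # data simulated from the same model should fall inside
        t = sk.simulate_survey(design, malawi_params, seed=33)
        cv = sk.loo_crossvalidate(t, plugin_model(malawi_params, len(t)))
        med = sk.sspe_summary(cv).median_theta
        assert lo <= med <= hi

    def test_reproducible_for_fixed_seed(self, malawi_params):
        design = sk.generate_design(10, 0.2, 2, 2, seed=34)
        model = plugin_model(malawi_params)
        i1 = sk.median_sspe_interval(model, design, n_sim=30, seed=35)
        i2 = sk.median_sspe_interval(model, design, n_sim=30, seed=35)
        assert i1 == i2

    def test_degenerate_n_sim(self, malawi_params):
        design = sk.generate_design(8, 0.2, 2, 2, seed=36)
        lo, hi = sk.median_sspe_interval(
            plugin_model(malawi_params), design, n_sim=2, seed=37
        )
        assert np.isfinite(lo) and np.isfinite(hi) and lo <= hi
        with pytest.raises(ValueError):
            sk.median_sspe_interval(plugin_model(malawi_params), design, n_sim=1)


class TestNormalityCheck:
    def test_standard_normal_sample(self):
        rng = np.random.default_rng(41)
        n = 10_000
        rec = pd.DataFrame(
            {
                "observed": rng.standard_normal(n),
                "predicted": np.zeros(n),
                "s2": np.ones(n),
                "flagged": np.zeros(n, dtype=bool),
            }
        )
        out = sk.normality_check(rec)
        assert abs(out["skewness"]) < 0.1
        assert abs(out["excess_kurtosis"]) < 0.1
        assert len(out["qq_sample"]) == n

    def test_constant_input_flagged(self):
        rec = pd.DataFrame(
            {
                "observed": np.full(10, 2.0),
                "predicted": np.ones(10),
                "s2": np.ones(10),
                "flagged": np.zeros(10, dtype=bool),
            }
        )
        assert sk.normality_check(rec)["degenerate"]

    def test_symmetric_two_point_sample_has_zero_skew(self):
        rec = pd.DataFrame(
            {
                "observed": np.array([1.0, -1.0] * 5),
                "predicted": np.zeros(10),
                "s2": np.ones(10),
                "flagged": np.zeros(10, dtype=bool),
            }
        )
        out = sk.normality_check(rec)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)
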