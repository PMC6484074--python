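import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

import sekrige as sk
from sekrige.kriging import KrigingSystem
from sekrige.reml import NestedIndex

from conftest import plugin_model


def dense_ok_solve(x0, table, model):
    """Brute-force augmented OK system solve (the linear-algebra oracle)."""
    idx = NestedIndex.from_table(table)
    C = sk.assemble_covariance(
        idx.cl_codes, idx.hh_codes, model.components, model.matern,
        idx.cluster_coords,
    )
    n = C.shape[0]
    H = np.zeros((n + 1, n + 1))
    H[:n, :n] = C
    H[:n, n] = 1.0
    H[n, :n] = 1.0
    d = np.linalg.norm(idx.cluster_coords - np.asarray(x0), axis=1)
    c0 = model.components.sigma2_c * sk.matern_correlation(d, model.matern)
    c0 = c0[idx.cl_codes]
    sol = np.linalg.solve(H, np.r_[c0, 1.0])
    lam, psi = sol[:n], sol[n]
    z = np.log(table["plasma_se"].to_numpy())
    return lam @ z, model.components.total - lam @ c0 - psi, lam


class TestBuildGrid:
    def test_square_cell_centers(self):
        grid = sk.build_grid(box(0, 0, 10, 10), 1.0)
        assert len(grid.nodes) == 100
        assert grid.nodes.min() == pytest.approx(0.5)
        assert grid.nodes.max() == pytest.approx(9.5)

    def test_coarse_resolution_still_one_node(self):
        grid = sk.build_grid(box(0, 0, 3, 3), 50.0)
        assert len(grid.nodes) >= 1

    def test_notch_excluded_from_nonconvex_polygon(self):
        poly = Polygon(
            [(0, 0), (10, 0), (10, 10), (6, 10), (6, 4), (4, 4), (4, 10), (0, 10)]
        )
        grid = sk.build_grid(poly, 1.0)
        in_notch = (
            (grid.nodes[:, 0] > 4) & (grid.nodes[:, 0] < 6) & (grid.nodes[:, 1] > 4)
        )
        assert not in_notch.any()

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            sk.build_grid(box(0, 0, 1, 1), 0.0)


class TestKrigePoint:
    def test_single_observation_forces_weight_one(self, malawi_params):
        d = sk.generate_design(1, 0.0, 1, 1, seed=1)
        t = sk.simulate_survey(d, malawi_params, seed=2)
        model = plugin_model(malawi_params, len(t))
        pred = sk.krige_point([123.0, 456.0], t, model)
        assert pred.m == pytest.approx(float(np.log(t["plasma_se"].iloc[0])))

    def test_zero_nugget_exact_interpolation(self):
        params = sk.GenerativeParams(
            mu=4.3,
            components=sk.VarianceComponents(0.15, 0.0, 0.0),
            matern=sk.MaternParams(0.5, 39.4),
        )
        d = sk.generate_design(6, 0.0, 1, 1, seed=3)
        t = sk.simulate_survey(d, params, seed=4)
        model = plugin_model(params, len(t))
        x0 = t[["x", "y"]].iloc[3].to_numpy()
        pred = sk.krige_point(x0, t, model)
        assert pred.m == pytest.approx(float(np.log(t["plasma_se"].iloc[3])), abs=1e-8)
        assert pred.s2 == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, malawi_params, seed):
        """OK prediction and variance equal a brute-force augmented-system
        solve to 1e-10 on instances with n <= 30."""
        d = sk.generate_design(5, 0.2, 3, 2, seed=seed)
        t = sk.simulate_survey(d, malawi_params, seed=seed + 30)
        model = plugin_model(malawi_params, len(t))
        rng = np.random.default_rng(seed)
        for _ in range(3):
            x0 = rng.uniform([0, 0], [160, 850])
            pred = sk.krige_point(x0, t, model)
            m_o, s2_o, lam = dense_ok_solve(x0, t, model)
            assert pred.m == pytest.approx(m_o, abs=1e-10)
            assert pred.s2 == pytest.approx(s2_o, abs=1e-10)
            assert lam.sum() == pytest.approx(1.0, abs=1e-10)

    def test_nonconverged_model_rejected(self, small_table, malawi_params):
        model = plugin_model(malawi_params)
        model.converged = False
        with pytest.raises(ValueError, match="converged"):
            sk.krige_point([0.0, 0.0], small_table, model)


class TestKrigingWeights:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weights_sum_to_one_on_every_solve(self, malawi_params, seed):
        d = sk.generate_design(6, 0.2, 2, 2, seed=seed)
        t = sk.simulate_survey(d, malawi_params, seed=seed + 60)
        system = KrigingSystem(t, plugin_model(malawi_params, len(t)))
        rng = np.random.default_rng(seed)
        targets = rng.uniform([0, 0], [160, 850], size=(20, 2))
        lam, psi, _ = system.solve_weights(targets)
        assert np.allclose(lam.sum(axis=0), 1.0, atol=1e-10)


class TestKrigeGrid:
    def test_agrees_with_per_node_krige_point(self, small_table, malawi_params):
        model = plugin_model(malawi_params, len(small_table))
        grid = sk.build_grid(box(0, 0, 160, 850), 100.0)
        out = sk.krige_grid(grid, small_table, model)
        for i in [0, len(out) // 2, len(out) - 1]:
            p = sk.krige_point(grid.nodes[i], small_table, model)
            assert out["m"].iloc[i] == pytest.approx(p.m, abs=1e-10)
            assert out["s2"].iloc[i] == pytest.approx(p.s2, abs=1e-10)

    def test_constant_observations_predict_constant(self, malawi_params):
        d = sk.generate_design(8, 0.0, 2, 2, seed=5)
        params = sk.GenerativeParams(
            mu=np.log(80.0),
            components=sk.VarianceComponents(0.0, 0.0, 0.0),
            matern=sk.MaternParams(0.5, 39.4),
        )
        t = sk.simulate_survey(d, params, seed=6)
        model = plugin_model(malawi_params, len(t))  # nonzero covariance params
        grid = sk.build_grid(box(0, 0, 160, 850), 150.0)
        out = sk.krige_grid(grid, t, model)
        assert np.allclose(out["m"], np.log(80.0), atol=1e-8)
        assert np.allclose(out["median_ngml"], 80.0, atol=1e-6)

    def test_variance_independent_of_observed_values(self, small_table, malawi_params):
        """s2 depends only on geometry and parameters: permuting z leaves it
        unchanged."""
        model = plugin_model(malawi_params, len(small_table))
        grid = sk.build_grid(box(0, 0, 160, 850), 120.0)
        out1 = sk.krige_grid(grid, small_table, model)
        rng = np.random.default_rng(1)
        shuffled = small_table.copy()
        shuffled["plasma_se"] = rng.permutation(shuffled["plasma_se"].to_numpy())
        out2 = sk.krige_grid(grid, shuffled, model)
        assert np.allclose(out1["s2"], out2["s2"], atol=1e-10)

    def test_translation_equivariance(self, small_table, malawi_params):
        model = plugin_model(malawi_params, len(small_table))
        grid = sk.build_grid(box(0, 0, 160, 850), 150.0)
        out1 = sk.krige_grid(grid, small_table, model)
        shifted = small_table.copy()
        shifted["plasma_se"] = shifted["plasma_se"] * np.e  # +1 on log scale
        out2 = sk.krige_grid(grid, shifted, model)
        assert np.allclose(out2["m"], out1["m"] + 1.0, atol=1e-8)


class TestBackTransform:
    def test_median_values(self):
        assert sk.back_transform_median(float(np.log(84.9))) == pytest.approx(84.9)
        assert sk.back_transform_median(0.0) == 1.0

    def test_median_not_mean_unbiased(self):
        """exp(m) is the lognormal median; the mean is exp(m + s2/2)."""
        m, s2 = np.log(80.0), 0.25
        rng = np.random.default_rng(7)
        draws = np.exp(rng.normal(m, np.sqrt(s2), 200_000))
        assert np.median(draws) == pytest.approx(np.exp(m), rel=0.01)
        assert draws.mean() == pytest.approx(np.exp(m + s2 / 2), rel=0.01)
        assert draws.mean() > np.exp(m) * 1.05

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sk.back_transform_median(np.inf)
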