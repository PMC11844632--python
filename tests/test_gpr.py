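import numpy as np
import pytest

import threshmap as tm
from threshmap import gpr
from threshmap.kernels import KernelSpec, kernel_matrix

from conftest import manual_map


def dense_posterior(spec, X, y, Xq):
    """Brute-force GP posterior via explicit matrix inverse."""
    K = kernel_matrix(spec, X, include_noise=True) + gpr.JITTER * np.eye(len(y))
    Kinv = np.linalg.inv(K)
    Ks = kernel_matrix(spec, X, Xq)
    mean = Ks.T @ Kinv @ y
    var = spec.signal_variance - np.einsum("ij,ji->i", Ks.T @ Kinv, Ks)
    return mean, var


def dense_lml(spec, X, y):
    n = len(y)
    K = kernel_matrix(spec, X, include_noise=True) + gpr.JITTER * np.eye(n)
    return float(
        -0.5 * y @ np.linalg.inv(K) @ y
        - 0.5 * np.log(np.linalg.det(K))
        - 0.5 * n * np.log(2 * np.pi)
    )


class TestTransform:
    def test_constant_targets_clamp_scale(self):
        m = manual_map([100.0, 100.0])
        with pytest.warns(UserWarning, match="zero spread"):
            z, tr = gpr.transform_targets(m, [0, 1])
        np.testing.assert_allclose(z, [0.0, 0.0])
        assert tr.scale_clamped and tr.scale == 1.0

    def test_log10_then_standardize(self):
        # one decade apart: log10 values one unit either side of their mean,
        # so standardization (population sd) maps them to (-1, +1)
        m3 = manual_map([50.0, 500.0])
        z, tr = gpr.transform_targets(m3, [0, 1])
        expected_mean = np.log10([50.0, 500.0]).mean()
        np.testing.assert_allclose(z, [-1.0, 1.0], atol=1e-12)
        assert tr.mean == pytest.approx(expected_mean)

    def test_round_trip_identity(self):
        m = manual_map([60.0, 150.0, 400.0])
        z, tr = gpr.transform_targets(m, [0, 1, 2])
        np.testing.assert_allclose(
            tr.inverse(z), [60.0, 150.0, 400.0], rtol=1e-12
        )


class TestLogMarginalLikelihood:
    def test_single_point_closed_form_zero_target(self):
        spec = KernelSpec("rbf", signal_variance=0.9, noise_variance=0.1)
        lml = gpr.log_marginal_likelihood(spec, [[0.0, 0.0]], [0.0])
        assert lml == pytest.approx(-0.9189385332046727, abs=1e-9)

    def test_single_point_closed_form_nonzero_target(self):
        spec = KernelSpec("rbf", signal_variance=0.9, noise_variance=0.1)
        lml = gpr.log_marginal_likelihood(spec, [[0.0, 0.0]], [2.0])
        assert lml == pytest.approx(-2.9189385332046727, abs=1e-9)

    @pytest.mark.parametrize("family", tm.KERNEL_FAMILIES)
    def test_agrees_with_dense_oracle(self, family, argus_grid):
        rng = np.random.default_rng(3)
        X = argus_grid.positions[rng.choice(60, 7, replace=False)]
        y = rng.standard_normal(7)
        spec = KernelSpec(family, signal_variance=1.7, length_scale=2.5,
                          length_scale_rbf=1.5, length_scale_matern=4.0,
                          mix_weight=0.4, noise_variance=0.05)
        assert gpr.log_marginal_likelihood(spec, X, y) == pytest.approx(
            dense_lml(spec, X, y), abs=1e-8
        )


class TestPredict:
    @pytest.mark.parametrize("family", tm.KERNEL_FAMILIES)
    def test_matches_dense_oracle(self, family, argus_grid):
        rng = np.random.default_rng(7)
        ids = rng.choice(60, 9, replace=False)
        thr = 10 ** rng.uniform(1.7, 2.7, size=60)
        m = manual_map(thr, grid=argus_grid)
        spec_params = dict(signal_variance=1.3, length_scale=3.0,
                           length_scale_rbf=2.0, length_scale_matern=5.0,
                           mix_weight=0.6, noise_variance=0.02)
        cfg = gpr.GPConfig(optimize=False, init_params=spec_params)
        gp = gpr.fit(m, ids, family, config=cfg)
        query = np.setdiff1d(np.arange(60), ids)[:10]
        pred = gpr.predict(gp, argus_grid, query)
        mean, var = dense_posterior(
            gp.kernel_spec, gp.X_train, gp.y_train, argus_grid.positions_of(query)
        )
        np.testing.assert_allclose(pred.mean_transformed, mean, atol=1e-8)
        np.testing.assert_allclose(pred.std_transformed**2, var, atol=1e-8)
        np.testing.assert_allclose(
            pred.mean_uA, gp.transform.inverse(mean), rtol=1e-10
        )

    def test_two_point_closed_form(self):
        # hand-solved 2x2 system
        m = manual_map([100.0, 400.0])
        spec_params = dict(signal_variance=1.0, length_scale=1.0,
                           noise_variance=0.5)
        cfg = gpr.GPConfig(optimize=False, init_params=spec_params)
        gp = gpr.fit(m, [0, 1], "rbf", config=cfg)
        pred = gpr.predict(gp, m.grid, [0])
        k = np.exp(-0.5)
        K = np.array([[1.5, k], [k, 1.5]])
        kstar = np.array([1.0, k])
        y = gp.y_train
        mean = kstar @ np.linalg.solve(K, y)
        var = 1.0 - kstar @ np.linalg.solve(K, kstar)
        assert pred.mean_transformed[0] == pytest.approx(mean, abs=1e-8)
        assert pred.std_transformed[0] ** 2 == pytest.approx(var, abs=1e-8)

    def test_cross_check_against_sklearn(self, argus_grid):
        sk = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, Matern

        rng = np.random.default_rng(11)
        ids = rng.choice(60, 10, replace=False)
        thr = 10 ** rng.uniform(1.7, 2.7, size=60)
        m = manual_map(thr, grid=argus_grid)
        for family, sk_kernel in [
            ("rbf", RBF(length_scale=2.0)),
            ("matern15", Matern(length_scale=2.0, nu=1.5)),
        ]:
            cfg = gpr.GPConfig(
                optimize=False,
                init_params=dict(signal_variance=1.0, length_scale=2.0,
                                 noise_variance=0.1),
            )
            gp = gpr.fit(m, ids, family, config=cfg)
            skm = GaussianProcessRegressor(
                kernel=sk_kernel, alpha=0.1, optimizer=None, normalize_y=False
            )
            skm.fit(gp.X_train, gp.y_train)
            query = np.setdiff1d(np.arange(60), ids)
            mu, sd = skm.predict(argus_grid.positions_of(query), return_std=True)
            pred = gpr.predict(gp, argus_grid, query)
            np.testing.assert_allclose(pred.mean_transformed, mu, atol=1e-7)
            np.testing.assert_allclose(pred.std_transformed, sd, atol=1e-6)

    def test_near_interpolation_at_tiny_noise(self, tiny_map):
        cfg = gpr.GPConfig(
            optimize=False,
            init_params=dict(signal_variance=1.0, length_scale=2.0,
                             noise_variance=1e-5),
        )
        gp = gpr.fit(tiny_map, tiny_map.grid.active_ids, "matern15", config=cfg)
        pred = gpr.predict(gp, tiny_map.grid, tiny_map.grid.active_ids)
        np.testing.assert_allclose(
            pred.mean_uA, tiny_map.thresholds_uA, rtol=5e-3
        )

    def test_prior_reversion_far_from_training(self):
        # a long 1-row array puts queries far beyond the length-scale bound
        grid = tm.build_grid(1, 120)
        thr = np.full(120, 100.0)
        thr[:5] = [100, 120, 90, 110, 105]
        m = tm.ThresholdMap(grid=grid, thresholds_uA=thr,
                            censored=np.zeros(120, bool))
        cfg = gpr.GPConfig(
            optimize=False,
            init_params=dict(signal_variance=1.0, length_scale=2.0,
                             noise_variance=1e-5),
        )
        gp = gpr.fit(m, [0, 1, 2, 3, 4], "rbf", config=cfg)
        pred = gpr.predict(gp, grid, [119])  # distance 115 >> 50
        assert abs(pred.mean_transformed[0]) < 1e-3
        sigma = np.sqrt(1.0 + 1e-5)
        assert pred.std_transformed[0] == pytest.approx(sigma, abs=1e-3)

    def test_posterior_variance_bounded_by_noise_at_training_points(self, tiny_map):
        cfg = gpr.GPConfig(
            optimize=False,
            init_params=dict(signal_variance=2.0, length_scale=3.0,
                             noise_variance=0.05),
        )
        gp = gpr.fit(tiny_map, tiny_map.grid.active_ids, "rbf", config=cfg)
        pred = gpr.predict(gp, tiny_map.grid, tiny_map.grid.active_ids)
        assert (pred.std_transformed**2 <= 0.05 + 1e-8).all()

    def test_variance_shrinks_with_more_data(self, tiny_map):
        cfg = gpr.GPConfig(
            optimize=False,
            init_params=dict(signal_variance=1.0, length_scale=2.0,
                             noise_variance=0.1),
        )
        gp4 = gpr.fit(tiny_map, [0, 2, 4, 6], "matern15", config=cfg)
        gp5 = gpr.fit(tiny_map, [0, 2, 4, 6, 8], "matern15", config=cfg)
        q = [1, 3, 5, 7, 9]
        v4 = gpr.predict(gp4, tiny_map.grid, q).std_transformed
        v5 = gpr.predict(gp5, tiny_map.grid, q).std_transformed
        assert (v5 <= v4 + 1e-10).all()

    def test_empty_query(self, tiny_map):
        cfg = gpr.GPConfig(optimize=False)
        gp = gpr.fit(tiny_map, [0, 1], "rbf", config=cfg)
        pred = gpr.predict(gp, tiny_map.grid, [])
        assert pred.mean_uA.size == 0


class TestFit:
    def test_deterministic_under_fixed_seed(self, smooth_map):
        ids = smooth_map.trainable_ids()[:15]
        cfg = gpr.GPConfig(n_restarts=3)
        a = gpr.fit(smooth_map, ids, "matern15", config=cfg, seed=5)
        b = gpr.fit(smooth_map, ids, "matern15", config=cfg, seed=5)
        assert a.kernel_spec == b.kernel_spec
        assert a.lml == b.lml

    def test_optimization_never_worsens_objective(self, smooth_map):
        ids = smooth_map.trainable_ids()[:20]
        cfg = gpr.GPConfig(n_restarts=2)
        gp = gpr.fit(smooth_map, ids, "rbf", config=cfg, seed=1)
        init = gpr.fit(smooth_map, ids, "rbf",
                       config=gpr.GPConfig(optimize=False), seed=1)
        assert gp.lml >= init.lml - 1e-9

    def test_optimized_parameters_respect_bounds(self, smooth_map):
        ids = smooth_map.trainable_ids()[:25]
        gp = gpr.fit(smooth_map, ids, "hybrid", config=gpr.GPConfig(n_restarts=3))
        s = gp.kernel_spec
        for name in s.param_names():
            lo, hi = s.bounds[name]
            assert lo - 1e-9 <= getattr(s, name) <= hi + 1e-9

    def test_single_training_point_flagged(self, tiny_map):
        with pytest.warns(UserWarning, match="single electrode"):
            gpr.fit(tiny_map, [0], "rbf", config=gpr.GPConfig(optimize=False))

    def test_scale_equivariance_with_log_transform(self, argus_grid):
        rng = np.random.default_rng(2)
        thr = 10 ** rng.uniform(1.7, 2.5, size=60)
        c = 1.3
        m1 = manual_map(thr, grid=argus_grid)
        m2 = manual_map(c * thr, grid=argus_grid)
        ids = rng.choice(60, 20, replace=False)
        cfg = gpr.GPConfig(n_restarts=2)
        g1 = gpr.fit(m1, ids, "matern15", config=cfg, seed=0)
        g2 = gpr.fit(m2, ids, "matern15", config=cfg, seed=0)
        q = np.setdiff1d(np.arange(60), ids)
        p1 = gpr.predict(g1, argus_grid, q)
        p2 = gpr.predict(g2, argus_grid, q)
        np.testing.assert_allclose(
            p1.mean_transformed, p2.mean_transformed, atol=1e-6
        )
        np.testing.assert_allclose(p2.mean_uA, c * p1.mean_uA, rtol=1e-5)

    def test_json_round_trip_preserves_predictions(self, tmp_path, tiny_map):
        gp = gpr.fit(tiny_map, [0, 2, 5, 8], "hybrid",
                     config=gpr.GPConfig(n_restarts=2), seed=3)
        path = tmp_path / "fit.json"
        gp.to_json(path)
        back = gpr.GPFit.from_json(path)
        q = [1, 3, 4]
        np.testing.assert_allclose(
            gpr.predict(gp, tiny_map.grid, q).mean_uA,
            gpr.predict(back, tiny_map.grid, q).mean_uA,
            rtol=1e-12,
        )
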