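"""Simulators: manifold membership, Lorenz integration, data drops, UKF."""

import numpy as np
import pytest

from dfine.ldm import kalman_filter
from dfine.simulate import (TORUS_R_MAJOR, TORUS_R_MINOR, DropConfig,
                            LorenzConfig, ManifoldConfig,
                            UnscentedKalmanFilter, apply_data_drop,
                            embed_manifold, lorenz_derivative,
                            make_observations, simulate_lorenz_session,
                            simulate_manifold_session, ukf_one_step_predict)

from conftest import random_stable_ldm


class TestManifoldSessions:
    def test_default_session_shape(self):
        sess, truth = simulate_manifold_session(ManifoldConfig(seed=0))
        assert sess.y.shape == (250, 200, 40)
        assert truth.traj3d.shape == (250, 200, 3)

    def test_noiseless_identity_observations(self):
        cfg = ManifoldConfig(manifold="torus", obs_noise_sd=0.0, n_trials=5,
                             T=50, seed=1)
        sess, truth = simulate_manifold_session(cfg)
        assert np.allclose(sess.y[..., :3], truth.traj3d, atol=1e-12)

    def test_torus_points_satisfy_implicit_equation(self):
        cfg = ManifoldConfig(manifold="torus", n_trials=4, T=60, seed=2)
        _, truth = simulate_manifold_session(cfg)
        x, y, z = truth.traj3d[..., 0], truth.traj3d[..., 1], truth.traj3d[..., 2]
        lhs = (np.sqrt(x**2 + y**2) - TORUS_R_MAJOR) ** 2 + z**2
        assert np.abs(lhs - TORUS_R_MINOR**2).max() < 1e-10

    def test_ring_radius_and_swiss_roll_bounds(self):
        _, ring = simulate_manifold_session(
            ManifoldConfig(manifold="ring", n_trials=3, T=80, seed=3))
        r = np.linalg.norm(ring.traj3d[..., :2], axis=-1)
        assert np.abs(r - 1.0).max() < 1e-10
        _, sw = simulate_manifold_session(
            ManifoldConfig(manifold="swiss_roll", n_trials=3, T=80, seed=3))
        u, h = sw.intrinsic[..., 0], sw.intrinsic[..., 1]
        # jitter may push marginally past the reflected boundary
        assert u.min() > 1.5 * np.pi - 0.5 and u.max() < 4.5 * np.pi + 0.5
        assert h.min() > -1.0 and h.max() < 21.0

    def test_seeded_reproducibility(self):
        a = simulate_manifold_session(ManifoldConfig(n_trials=3, T=20, seed=9))
        b = simulate_manifold_session(ManifoldConfig(n_trials=3, T=20, seed=9))
        assert np.array_equal(a[0].y, b[0].y)

    def test_unknown_manifold_rejected(self):
        with pytest.raises(ValueError):
            ManifoldConfig(manifold="sphere")


class TestMakeObservations:
    def test_identity_padded_emission(self, rng):
        traj = rng.normal(0, 1, (30, 3))
        E = np.zeros((10, 3))
        y, E_out = make_observations(traj, E, noise_sd=0.0, identity_first3=True)
        assert np.allclose(y[:, :3], traj)
        assert np.all(y[:, 3:] == 0.0)

    def test_noise_moments(self, rng):
        traj = np.zeros((20000, 3))
        y, _ = make_observations(traj, 0, noise_sd=0.7, identity_first3=False,
                                 rng=rng, n_y=5)
        assert np.abs(y.std(axis=0) - 0.7).max() < 0.02

    def test_bad_width_rejected(self, rng):
        with pytest.raises(ValueError):
            make_observations(rng.normal(0, 1, (10, 2)), 0, 0.1)


class TestDataDrop:
    def test_full_ratio_keeps_everything(self):
        mask = apply_data_drop(200, DropConfig(observed_ratio=1.0, seed=0))
        assert mask.all() and mask.shape == (200,)

    def test_exact_block_counts(self):
        mask = apply_data_drop(np.zeros((6, 200, 4)),
                               DropConfig(observed_ratio=0.2, seed=1))
        assert mask.shape == (6, 200)
        assert (~mask).sum() == 6 * 160
        for i in range(6):
            assert (~mask[i, :100]).sum() == 80
            assert (~mask[i, 100:]).sum() == 80

    def test_positions_vary_across_seeds(self):
        m1 = apply_data_drop(100, DropConfig(observed_ratio=0.5, seed=0))
        m2 = apply_data_drop(100, DropConfig(observed_ratio=0.5, seed=1))
        assert m1.sum() == m2.sum() == 50
        assert not np.array_equal(m1, m2)

    def test_invalid_ratio_rejected(self):
        for rho in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                DropConfig(observed_ratio=rho)


class TestLorenz:
    def test_equilibrium_is_fixed_point(self):
        cfg = LorenzConfig(q_var=0.0, n_trials=1, T=20, burn_in=0, seed=0)
        eq = np.array([np.sqrt(cfg.beta * (cfg.rho - 1)),
                       np.sqrt(cfg.beta * (cfg.rho - 1)), cfg.rho - 1])
        assert np.abs(lorenz_derivative(eq, cfg.sigma, cfg.rho, cfg.beta)).max() < 1e-12

    def test_deterministic_trajectory_matches_independent_euler(self):
        cfg = LorenzConfig(q_var=0.0, n_trials=2, T=50, seed=4)
        _, truth = simulate_lorenz_session(cfg)
        # independently coded Euler integration of the Lorenz equations
        rng = np.random.default_rng(4)
        s = rng.standard_normal((2, 3))
        for _ in range(cfg.burn_in + 0):
            x1, x2, x3 = s[:, 0], s[:, 1], s[:, 2]
            s = s + 0.01 * np.stack([10.0 * (x2 - x1),
                                     28.0 * x1 - x1 * x3 - x2,
                                     x1 * x2 - (8 / 3) * x3], axis=1)
        ref = np.empty((2, 50, 3))
        for t in range(50):
            ref[:, t] = s
            x1, x2, x3 = s[:, 0], s[:, 1], s[:, 2]
            s = s + 0.01 * np.stack([10.0 * (x2 - x1),
                                     28.0 * x1 - x1 * x3 - x2,
                                     x1 * x2 - (8 / 3) * x3], axis=1)
        assert np.abs(ref - truth.traj3d).max() < 1e-10

    def test_noise_sweep_endpoints_accepted(self):
        for q in (1e-4, 1.0):
            sess, _ = simulate_lorenz_session(
                LorenzConfig(q_var=q, n_trials=2, T=10, burn_in=10, seed=0))
            assert np.isfinite(sess.y).all()

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            LorenzConfig(dt=0.0)


class TestUKF:
    def test_equals_kalman_filter_on_linear_model(self, rng):
        ldm = random_stable_ldm(rng, n_x=2, n_a=3)

        class LinearGen:
            state_transition = staticmethod(lambda s: s @ ldm.A.T)
            observation = staticmethod(lambda s: s @ ldm.C.T)
            Q, R_obs = ldm.W, ldm.R
            init_mean, init_cov = ldm.mu0, ldm.Lambda0

        a_seq = rng.normal(0, 1, (15, 3))
        y_pred = ukf_one_step_predict(LinearGen(), a_seq)
        filt = kalman_filter(ldm, a_seq)
        ref = filt.x_pred @ ldm.C.T
        assert np.abs(y_pred - ref).max() < 1e-8

    def test_unscented_transform_exact_for_linear_map(self, rng):
        M = rng.normal(0, 1, (3, 3))
        ukf = UnscentedKalmanFilter(lambda s: s @ M.T, lambda s: s,
                                    Q=np.zeros((3, 3)), R=np.zeros((3, 3)))
        mean = rng.normal(0, 1, 3)
        cov_half = rng.normal(0, 1, (3, 3))
        cov = cov_half @ cov_half.T + 0.5 * np.eye(3)
        pts, wm, wc = ukf._sigma_points(mean, cov)
        fp = pts @ M.T
        out_mean, out_cov = ukf._moments(fp, wm, wc)
        assert np.abs(out_mean - M @ mean).max() < 1e-8
        assert np.abs(out_cov - M @ cov @ M.T).max() < 1e-8

    def test_true_model_beats_chance_on_manifold_session(self):
        from dfine.evaluate import nrmse
        cfg = ManifoldConfig(manifold="ring", n_trials=2, T=100, seed=5)
        sess, truth = simulate_manifold_session(cfg)
        preds = ukf_one_step_predict(truth.trial_generator(0), sess.y[0])
        assert nrmse(sess.y[0][1:], preds[1:]) < 1.0
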