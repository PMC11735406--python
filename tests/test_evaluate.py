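"""Metrics: NRMSE, CC, classification features/AUC, latent recovery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfine.evaluate import (behavior_regression_eval, classification_auc,
                            classification_features, lorenz_recovery_cc,
                            nrmse, pearson_cc)


class TestNRMSE:
    def test_mean_predictor_scores_exactly_one(self, rng):
        y = rng.normal(0, 3, (100, 5))
        pred = np.broadcast_to(y.mean(axis=0), y.shape)
        assert nrmse(y, pred) == pytest.approx(1.0, abs=1e-14)

    def test_perfect_predictor_scores_zero(self, rng):
        y = rng.normal(0, 1, (50, 3))
        assert nrmse(y, y) == 0.0

    def test_hand_computed_value(self):
        # 1-D: errors (0, 1, 0); deviations from mean 2: (-1, 0, 1)
        assert nrmse(np.array([1.0, 2, 3]), np.array([1.0, 1, 3])) == \
            pytest.approx(1 / np.sqrt(2), abs=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(deadline=None, max_examples=25)
    def test_per_dimension_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, (40, 2))
        p = rng.normal(0, 1, (40, 2))
        assert nrmse(a * y + b, a * p + b) == pytest.approx(nrmse(y, p), rel=1e-9)

    def test_constant_dimension_skipped_with_warning(self, rng):
        y = rng.normal(0, 1, (20, 2))
        y[:, 1] = 4.0
        p = rng.normal(0, 1, (20, 2))
        with pytest.warns(UserWarning):
            val = nrmse(y, p)
        assert val == pytest.approx(nrmse(y[:, :1], p[:, :1]))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            nrmse(rng.normal(0, 1, (5, 2)), rng.normal(0, 1, (5, 3)))


class TestPearson:
    def test_fixed_points(self, rng):
        u = rng.normal(0, 1, 30)
        assert pearson_cc(u, u) == pytest.approx(1.0)
        assert pearson_cc(u, -u) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_cc(np.array([1.0, 2, 3]), np.array([1.0, 2, 4])) == \
            pytest.approx(0.9819805, abs=1e-6)

    def test_multivariate_averages_dimensions(self, rng):
        u = rng.normal(0, 1, (50, 2))
        v = np.stack([u[:, 0], -u[:, 1]], axis=1)
        assert pearson_cc(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc(np.ones(10), np.arange(10.0))


class TestClassificationFeatures:
    def test_feature_length_is_samples_times_latent_dim(self, rng):
        traj = rng.normal(0, 1, (137, 16))
        assert classification_features(traj).shape == (160,)

    def test_constant_trajectory_gives_identical_samples(self):
        feats = classification_features(np.full((57, 2), 3.0))
        assert np.all(feats.reshape(10, 2) == 3.0)

    def test_length_400_trial_samples_every_40th_point(self, rng):
        traj = rng.normal(0, 1, (400, 1))
        feats = classification_features(traj)
        # 1-based indices 40, 80, ..., 400 -> 0-based 39, 79, ..., 399
        assert np.allclose(feats, traj[39::40, 0])

    def test_single_point_trial_rejected(self):
        with pytest.raises(ValueError):
            classification_features(np.ones((1, 3)))


class TestClassificationAUC:
    def test_separable_classes_reach_perfect_auc(self, rng):
        X = np.concatenate([rng.normal(-5, 0.2, (30, 4)),
                            rng.normal(5, 0.2, (30, 4))])
        y = np.repeat([0, 1], 30)
        assert classification_auc(X, y, seed=0) == pytest.approx(1.0)

    def test_shuffled_labels_center_at_half(self, rng):
        X = rng.normal(0, 1, (60, 4))
        aucs = [classification_auc(X, rng.permutation(np.repeat([0, 1], 30)),
                                   seed=s) for s in range(12)]
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_eight_classes_mean_over_28_pairs(self, rng):
        centers = rng.normal(0, 30, (8, 3))
        X = np.concatenate([c + rng.normal(0, 0.1, (12, 3)) for c in centers])
        y = np.repeat(np.arange(8), 12)
        assert classification_auc(X, y, seed=1) == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            classification_auc(rng.normal(0, 1, (10, 2)), np.zeros(10))


class TestBehaviorRegression:
    def test_linear_target_is_recovered(self, rng):
        lat_tr = rng.normal(0, 1, (400, 3))
        lat_te = rng.normal(0, 1, (200, 3))
        M = rng.normal(0, 1, (3, 2))
        cc = behavior_regression_eval(lat_tr, lat_tr @ M, lat_te, lat_te @ M,
                                      seed=0)
        assert cc > 0.95

    def test_independent_noise_gives_no_correlation(self, rng):
        ccs = []
        for s in range(3):
            lat_tr = rng.normal(0, 1, (300, 3))
            lat_te = rng.normal(0, 1, (150, 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ccs.append(behavior_regression_eval(
                    lat_tr, rng.normal(0, 1, (300, 1)),
                    lat_te, rng.normal(0, 1, (150, 1)), seed=s))
        assert abs(np.mean(ccs)) < 0.2


class TestLorenzRecovery:
    def test_identity_and_similarity_invariance(self, rng):
        tr = rng.normal(0, 1, (300, 3))
        te = rng.normal(0, 1, (100, 3))
        assert lorenz_recovery_cc(tr, tr, te, te) == pytest.approx(1.0)
        Q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        S = Q * np.array([2.0, 0.5, 3.0])
        assert lorenz_recovery_cc(tr @ S, tr, te @ S, te) == pytest.approx(1.0)

    def test_rank_deficient_falls_back_to_ridge(self, rng):
        tr = np.tile(rng.normal(0, 1, (300, 1)), (1, 3))  # rank-1 latents
        te = np.tile(rng.normal(0, 1, (100, 1)), (1, 3))
        with pytest.warns(UserWarning):
            cc = lorenz_recovery_cc(tr, rng.normal(0, 1, (300, 2)),
                                    te, rng.normal(0, 1, (100, 2)))
        assert np.isfinite(cc)
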