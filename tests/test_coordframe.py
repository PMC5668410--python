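"""Rotation model, common decoder, error curve and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frameindex import generate_dataset
from frameindex.coordframe import (
    CoordinateFrameModel,
    default_grid,
    encode_direction,
    encode_directions,
    error_curve,
    estimate_coordinate_index,
    fit_common_decoder,
    fit_participants,
    group_coordinate_index,
    rotation_matrix,
)
from frameindex.data import TrialDataset
from frameindex.exceptions import CrossValidationError, DesignError, SizeError

from conftest import small_config


class TestRotation:
    def test_identity(self):
        np.testing.assert_allclose(rotation_matrix(0.0), np.eye(2), atol=1e-15)

    def test_quarter_turn(self):
        np.testing.assert_allclose(
            rotation_matrix(90.0) @ [1.0, 0.0], [0.0, 1.0], atol=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-720, 720), b=st.floats(-720, 720))
    def test_group_property(self, a, b):
        np.testing.assert_allclose(
            rotation_matrix(a) @ rotation_matrix(b), rotation_matrix(a + b), atol=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-720, 720))
    def test_orthogonal_unit_determinant(self, a):
        r = rotation_matrix(a)
        np.testing.assert_allclose(r @ r.T, np.eye(2), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


class TestEncode:
    @pytest.mark.parametrize(
        "label,expected",
        [
            (0.0, (1.0, 0.0)),
            (90.0, (0.0, 1.0)),
            (225.0, (-np.sqrt(2) / 2, -np.sqrt(2) / 2)),
        ],
    )
    def test_examples(self, label, expected):
        np.testing.assert_allclose(encode_direction(label), expected, atol=1e-12)


class TestCommonDecoder:
    @pytest.mark.parametrize("delta", [0.0, 45.0, 90.0])
    def test_noiseless_training_mse(self, delta):
        ds = generate_dataset(small_config(delta_theta_true=delta))
        dec = fit_common_decoder(ds, delta, alpha=1e-9)
        pred = dec.predict_extrinsic(ds.responses, ds.posture)
        mse_true = float(((pred - encode_directions(ds.direction_deg)) ** 2).sum(axis=1).mean())
        assert mse_true < 1e-6
        dec_bad = fit_common_decoder(ds, delta + 180.0, alpha=1e-9)
        pred_bad = dec_bad.predict_extrinsic(ds.responses, ds.posture)
        mse_bad = float(((pred_bad - encode_directions(ds.direction_deg)) ** 2).sum(axis=1).mean())
        assert mse_bad > mse_true + 0.1

    def test_zero_features_predict_intercept(self, noiseless_extrinsic):
        ds = noiseless_extrinsic
        ds.responses = np.zeros_like(ds.responses)
        dec = fit_common_decoder(ds, 0.0, alpha=1.0)
        np.testing.assert_allclose(dec.w, 0.0, atol=1e-12)
        pred = dec.predict(ds.responses)
        np.testing.assert_allclose(
            pred, np.broadcast_to(dec.intercept, pred.shape), atol=1e-12
        )

    def test_single_posture_rejected(self, noiseless_extrinsic):
        with pytest.raises(DesignError):
            fit_common_decoder(noiseless_extrinsic.for_posture("Pro"), 0.0)

    def test_matches_least_squares_oracle(self):
        """On a tiny dense problem the ridge solution at vanishing
        regularization equals the brute-force OLS solve of the
        rearranged rotation model."""
        rng = np.random.default_rng(7)
        n, p = 16, 4
        x = rng.normal(size=(n, p))
        labels = np.tile(np.arange(0, 360, 45.0), 2)
        posture = np.array(["Pro"] * 8 + ["Mid"] * 8, dtype=object)
        ds = TrialDataset(
            responses=x,
            direction_deg=labels,
            posture=posture,
            run_id=np.tile(np.repeat([1, 2], 4), 2),
            participant_id=np.zeros(n, dtype=int),
        )
        delta = 58.8
        dec = fit_common_decoder(ds, delta, alpha=1e-12)
        v = encode_directions(labels)
        y = v.copy()
        y[8:] = y[8:] @ rotation_matrix(delta)
        design = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(dec.w, coef[:p].T, atol=1e-9)
        np.testing.assert_allclose(dec.intercept, coef[p], atol=1e-9)


class TestErrorCurve:
    @pytest.mark.parametrize("delta", [0.0, 90.0])
    def test_noiseless_minimum_at_truth(self, delta):
        ds = generate_dataset(small_config(delta_theta_true=delta))
        res = error_curve(ds, alphas=[1e-6])
        assert res.delta_theta_hat == pytest.approx(delta)
        assert not res.uninformative

    def test_deterministic(self):
        ds = generate_dataset(small_config(noise_sd=0.8, seed=9))
        a = error_curve(ds)
        b = error_curve(ds)
        np.testing.assert_array_equal(a.error_curve, b.error_curve)
        assert a.delta_theta_hat == b.delta_theta_hat

    def test_periodicity(self):
        ds = generate_dataset(small_config(noise_sd=0.5, delta_theta_true=45.0, seed=3))
        g = default_grid()
        a = error_curve(ds, grid=g, alphas=[1.0])
        b = error_curve(ds, grid=g + 360.0, alphas=[1.0])
        np.testing.assert_allclose(a.error_curve, b.error_curve, rtol=1e-9, atol=1e-12)

    def test_equivariance_under_extra_rotation(self):
        """Rotating the Mid generative frame by an extra 45 degrees moves
        the recovered index by 45 degrees."""
        base = error_curve(
            generate_dataset(small_config(delta_theta_true=45.0)), alphas=[1e-6]
        ).delta_theta_hat
        extra = error_curve(
            generate_dataset(small_config(delta_theta_true=90.0)), alphas=[1e-6]
        ).delta_theta_hat
        assert extra - base == pytest.approx(45.0, abs=5.0)

    def test_lasso_estimator_agrees_at_small_scale(self):
        ds = generate_dataset(
            small_config(n_voxels=20, n_neurons_per_voxel=4, delta_theta_true=90.0)
        )
        res = error_curve(ds, grid=np.arange(-45.0, 316.0, 45.0), estimator="lasso", alphas=[1e-4])
        assert res.delta_theta_hat == pytest.approx(90.0)

    def test_needs_three_runs_per_posture(self):
        ds = generate_dataset(small_config(runs_per_posture=2))
        with pytest.raises(CrossValidationError):
            error_curve(ds)

    def test_summary_mentions_estimate(self):
        ds = generate_dataset(small_config(delta_theta_true=90.0))
        res = error_curve(ds, alphas=[1e-6])
        assert "delta_theta_hat" in res.summary()
        assert "90.0" in res.summary()


class TestEstimateIndex:
    def test_unique_minimum(self):
        grid = default_grid()
        curve = np.ones_like(grid)
        curve[grid == 55.0] = 0.5
        dt, flag = estimate_coordinate_index(grid, curve)
        assert (dt, flag) == (55.0, False)

    def test_flat_curve_flagged(self):
        grid = default_grid()
        dt, flag = estimate_coordinate_index(grid, np.full_like(grid, 0.7))
        assert flag and np.isnan(dt)

    def test_tie_prefers_positive(self):
        grid = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        curve = np.array([1.0, 0.2, 0.9, 0.2, 1.0])
        dt, flag = estimate_coordinate_index(grid, curve)
        assert (dt, flag) == (5.0, False)

    def test_tie_prefers_small_magnitude(self):
        grid = np.array([-10.0, 0.0, 25.0])
        curve = np.array([0.2, 0.9, 0.2])
        dt, _ = estimate_coordinate_index(grid, curve)
        assert dt == -10.0


class TestGroup:
    def test_all_zero_estimates(self):
        g = group_coordinate_index([0.0] * 6, n_boot=2000, seed=0)
        assert g.mean_deg == pytest.approx(0.0)
        assert g.ci_halfwidth == pytest.approx(0.0, abs=1e-6)
        assert g.tests[0.0].p_value > 0.5
        assert g.tests[90.0].p_value < 0.01

    def test_minimum_participants(self):
        with pytest.raises(SizeError):
            group_coordinate_index([0.0, 5.0])

    def test_fit_participants_splits(self):
        cfg = small_config(seed=4)
        cfg.n_participants = 2
        ds = generate_dataset(cfg)
        results = fit_participants(ds, alphas=[1e-6])
        assert [r.participant_id for r in results] == [0, 1]
        with pytest.raises(DesignError):
            CoordinateFrameModel(ds)
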