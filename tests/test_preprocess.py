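"""Signal-conditioning chain: unit behavior and round-trip recovery."""

import numpy as np
import pytest

from frameindex import generate_dataset
from frameindex.exceptions import BoundaryError, ConfigurationError, DegenerateBaselineError, SizeError
from frameindex.preprocess import (
    RunSeries,
    detrend_linear,
    extract_trial_patterns,
    normalize_baseline,
    shift_hemodynamic,
    zscore_volumes,
)
from frameindex.synthetic import generate_timeseries

from conftest import small_config


def _rest_series(volumes):
    """A series with no task blocks (all volumes are rest)."""
    return RunSeries(
        volumes=volumes,
        block_onsets=np.empty(0),
        direction_deg=np.empty(0),
        posture="Pro",
        run_id=1,
    )


def _one_run(cfg=None, **ts_kw):
    cfg = cfg or small_config(runs_per_posture=1)
    ds = generate_dataset(cfg)
    runs = generate_timeseries(ds, cfg, **ts_kw)
    return ds, runs


class TestShift:
    def test_four_seconds_is_two_volumes(self):
        vols = np.arange(40, dtype=float).reshape(20, 2)
        s = _rest_series(vols)
        out = shift_hemodynamic(s, 4.0)
        np.testing.assert_array_equal(out.volumes, vols[2:])

    def test_zero_delay_identity(self):
        vols = np.random.default_rng(0).normal(size=(15, 3))
        out = shift_hemodynamic(_rest_series(vols), 0.0)
        np.testing.assert_array_equal(out.volumes, vols)

    def test_non_multiple_delay_rejected(self):
        with pytest.raises(ConfigurationError):
            shift_hemodynamic(_rest_series(np.ones((15, 1))), 3.0)

    def test_shift_realigns_injected_patterns(self):
        """The generator injects a 4 s delay; after the shift the block
        onset volumes carry the patterns."""
        ds, runs = _one_run()
        s = shift_hemodynamic(runs[0], 4.0)
        sub = ds.select((ds.posture == s.posture) & (ds.run_id == s.run_id))
        start = int(round(s.block_onsets[0] / s.tr_seconds))
        np.testing.assert_allclose(
            s.volumes[start] - 100.0, sub.responses[0], atol=1e-9
        )


class TestNormalize:
    def test_constant_series_becomes_ones(self):
        out = normalize_baseline(_rest_series(np.full((12, 4), 5.0)))
        np.testing.assert_allclose(out.volumes, 1.0)

    def test_rest_two_task_three(self):
        vols = np.full((12, 1), 2.0)
        vols[10:] = 3.0
        out = normalize_baseline(_rest_series(vols))
        assert out.volumes[11, 0] == pytest.approx(1.5)

    def test_scale_equivariance(self):
        vols = np.random.default_rng(1).uniform(1, 2, size=(30, 5))
        a = normalize_baseline(_rest_series(vols)).volumes
        b = normalize_baseline(_rest_series(vols * 7.3)).volumes
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_degenerate_baseline_names_voxel(self):
        vols = np.ones((12, 3))
        vols[:10, 1] = 0.0
        with pytest.raises(DegenerateBaselineError, match="1"):
            normalize_baseline(_rest_series(vols))


class TestDetrend:
    def test_pure_line_gives_constant(self):
        t = np.arange(20, dtype=float)
        vols = (2.0 + 0.5 * t)[:, None]
        out = detrend_linear(_rest_series(vols))
        expected = 2.0 + 0.5 * t.mean()
        np.testing.assert_allclose(out.volumes, expected, rtol=1e-12)

    def test_white_noise_slope_within_3se(self):
        rng = np.random.default_rng(5)
        vols = rng.normal(size=(109, 1))
        out = detrend_linear(_rest_series(vols))
        t = np.arange(109, dtype=float)
        design = np.column_stack([np.ones(109), t])
        coef, res, *_ = np.linalg.lstsq(design, out.volumes[:, 0], rcond=None)
        sigma2 = res[0] / (109 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[1, 1])
        assert abs(coef[1]) < 3 * se

    def test_idempotent(self):
        ds, runs = _one_run(drift_per_volume=0.02)
        once = detrend_linear(runs[0])
        twice = detrend_linear(once)
        np.testing.assert_allclose(once.volumes, twice.volumes, atol=1e-10)

    def test_too_short(self):
        with pytest.raises(SizeError):
            detrend_linear(_rest_series(np.ones((2, 1))))


class TestZscore:
    def test_two_point_row(self, noiseless_extrinsic):
        ds = noiseless_extrinsic.select([0, 1])
        ds.responses = np.array([[1.0, 3.0], [0.0, 2.0]])
        out = zscore_volumes(ds)
        np.testing.assert_allclose(out.responses[0], [-1.0, 1.0])

    def test_constant_row_zeroed_with_warning(self, noiseless_extrinsic):
        ds = noiseless_extrinsic.select([0, 1])
        ds.responses = np.array([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = zscore_volumes(ds)
        np.testing.assert_array_equal(out.responses[0], 0.0)

    def test_contract(self, noiseless_extrinsic):
        out = zscore_volumes(noiseless_extrinsic)
        assert np.abs(out.responses.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(out.responses.std(axis=1), 1.0, atol=1e-12)


class TestExtract:
    def test_sample_counts(self):
        ds, runs = _one_run()
        s = shift_hemodynamic(runs[0], 4.0)
        assert len(extract_trial_patterns(s, samples="volume")) == 96
        assert len(extract_trial_patterns(s, samples="trial")) == 32

    def test_block_past_end(self):
        vols = np.ones((12, 2))
        s = RunSeries(
            volumes=vols,
            block_onsets=np.array([20.0]),
            direction_deg=np.array([0.0]),
            posture="Pro",
            run_id=1,
        )
        with pytest.raises(BoundaryError):
            extract_trial_patterns(s)


class TestNiftiIO:
    def test_write_read_round_trip(self, tmp_path):
        ds, runs = _one_run(small_config(runs_per_posture=1, n_voxels=6, n_neurons_per_voxel=2))
        series = runs[0]
        nifti = tmp_path / "run1.nii.gz"
        sidecar = tmp_path / "run1.tsv"
        from frameindex.preprocess import read_nifti_run, write_nifti_run

        write_nifti_run(series, nifti, sidecar)
        back = read_nifti_run(nifti, sidecar)
        np.testing.assert_allclose(back.volumes, series.volumes, rtol=1e-6)
        np.testing.assert_array_equal(back.direction_deg, series.direction_deg)
        assert back.posture == series.posture
        assert back.tr_seconds == pytest.approx(series.tr_seconds)


class TestRoundTrip:
    @pytest.mark.parametrize("drift", [0.0, 0.01])
    def test_recovers_patterns(self, drift):
        """shift -> normalize -> detrend -> extract recovers the injected
        trial patterns to within 1e-6 relative error."""
        cfg = small_config(runs_per_posture=1, n_voxels=15, n_neurons_per_voxel=4)
        ds, runs = _one_run(cfg, baseline_level=100.0, drift_per_volume=drift)
        for series in runs:
            sh = shift_hemodynamic(series, 4.0)
            rest_scale = sh.volumes[:10].mean(axis=0)
            de = detrend_linear(normalize_baseline(sh))
            rest_level = de.volumes[:10].mean(axis=0)
            ex = extract_trial_patterns(de, samples="trial")
            sub = ds.select((ds.posture == series.posture) & (ds.run_id == series.run_id))
            recovered = (ex.responses - rest_level) * rest_scale
            np.testing.assert_allclose(recovered, sub.responses, rtol=1e-6, atol=1e-9)
            np.testing.assert_array_equal(ex.direction_deg, sub.direction_deg)
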