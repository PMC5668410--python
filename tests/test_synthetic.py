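"""Generator contracts: determinism, design bookkeeping, frame property."""

import numpy as np
import pandas as pd
import pytest

from frameindex import SyntheticConfig, generate_dataset, generate_emg, generate_population, generate_trials
from frameindex.data import EmgDataset
from frameindex.exceptions import ConfigurationError, SizeError
from frameindex.synthetic import NeuronPopulation, generate_timeseries
from frameindex.tuning import muscle_frame_summary

from conftest import small_config


class TestPopulation:
    def test_degenerate_single_unit(self):
        cfg = small_config(n_voxels=1, n_neurons_per_voxel=1)
        pop = generate_population(cfg, participant_seed=0)
        assert pop.n_units == 1
        assert pop.mixing_matrix().shape == (1, 1)
        assert pop.mixing_matrix().sum() == pytest.approx(1.0)

    def test_determinism(self):
        cfg = small_config()
        a = generate_population(cfg, participant_seed=42)
        b = generate_population(cfg, participant_seed=42)
        for name in ("pd", "amplitude", "baseline", "weights"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_pd_uniformity(self):
        """Pooled PDs pass a Rayleigh uniformity check in >= 95/100 seeds
        and their resultant length stays small."""
        import pingouin as pg

        cfg = small_config(n_voxels=50, n_neurons_per_voxel=20)
        rejections = 0
        small_resultant = 0
        for seed in range(100):
            pds = generate_population(cfg, participant_seed=seed).preferred_directions
            assert pds.size == 1000
            assert np.all((0 <= pds) & (pds < 360))
            rad = np.deg2rad(pds)
            r = np.hypot(np.cos(rad).mean(), np.sin(rad).mean())
            small_resultant += r < 0.1
            _, p = pg.circ_rayleigh(rad)
            rejections += p < 0.01
        assert rejections <= 5
        assert small_resultant >= 95

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="noise_sd"):
            generate_population(small_config(noise_sd=-1.0), participant_seed=0)
        with pytest.raises(ConfigurationError, match="trials_per_run"):
            generate_population(small_config(trials_per_run=30), participant_seed=0)


class TestTrials:
    def test_rotation_by_zero_matches_postures(self, noiseless_extrinsic):
        ds = noiseless_extrinsic
        pro, mid = ds.for_posture("Pro"), ds.for_posture("Mid")
        for theta in np.arange(0, 360, 45.0):
            a = pro.responses[pro.direction_deg == theta][0]
            b = mid.responses[mid.direction_deg == theta][0]
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_exact_frame_shift_single_unit(self):
        cfg = small_config(n_voxels=1, n_neurons_per_voxel=1, delta_theta_true=90.0)
        pop = NeuronPopulation(
            pd=np.array([[0.0]]),
            amplitude=np.array([[1.0]]),
            baseline=np.array([[0.5]]),
            weights=np.array([[1.0]]),
        )
        ds = generate_trials(pop, cfg)
        pro, mid = ds.for_posture("Pro"), ds.for_posture("Mid")
        pro_at_0 = pro.responses[pro.direction_deg == 0.0][0]
        mid_at_90 = mid.responses[mid.direction_deg == 90.0][0]
        np.testing.assert_allclose(mid_at_90, pro_at_0, atol=1e-12)

    @pytest.mark.parametrize("delta", [45.0, 90.0, 135.0])
    def test_frame_property_on_lattice(self, delta):
        """Noiseless Mid responses equal Pro responses with labels
        remapped by -delta_theta_true."""
        ds = generate_dataset(small_config(delta_theta_true=delta))
        pro, mid = ds.for_posture("Pro"), ds.for_posture("Mid")
        for theta in np.arange(0, 360, 45.0):
            a = pro.responses[pro.direction_deg == (theta - delta) % 360][0]
            b = mid.responses[mid.direction_deg == theta][0]
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_design_bookkeeping_and_balance(self):
        cfg = SyntheticConfig(n_participants=2, n_voxels=10, n_neurons_per_voxel=2, seed=1)
        ds = generate_dataset(cfg)
        assert len(ds) == 2 * 2 * cfg.runs_per_posture * cfg.trials_per_run
        df = pd.DataFrame(
            {
                "pid": ds.participant_id,
                "posture": ds.posture,
                "run": ds.run_id,
                "dir": ds.direction_deg,
            }
        )
        counts = df.groupby(["pid", "posture", "run"])["dir"].value_counts()
        assert (counts == cfg.trials_per_run // cfg.n_directions).all()
        per_run_dirs = df.groupby(["pid", "posture", "run"])["dir"].nunique()
        assert (per_run_dirs == 8).all()

    def test_determinism_byte_identical(self):
        cfg = small_config(noise_sd=0.7, pd_rotation_jitter_sd=5.0)
        a = generate_dataset(cfg).to_frame().to_csv()
        b = generate_dataset(cfg).to_frame().to_csv()
        assert a == b

    def test_size_mismatch(self):
        pop = generate_population(small_config(), participant_seed=0)
        with pytest.raises(SizeError):
            generate_trials(pop, small_config(n_voxels=7))


class TestEmg:
    def test_zero_shift_identical_postures(self):
        emg = generate_emg([30.0, 200.0], pd_shift=0.0, noise_sd=0.0)
        pro = emg.table[emg.table.posture == "Pro"].reset_index(drop=True)
        mid = emg.table[emg.table.posture == "Mid"].reset_index(drop=True)
        np.testing.assert_allclose(pro["activation"], mid["activation"])

    def test_cosine_values(self):
        emg = generate_emg([0.0], pd_shift=0.0, amplitude=1.0, baseline=2.0, noise_sd=0.0, n_trials=1)
        pro = emg.for_muscle("muscle1", "Pro").set_index("direction_deg")["activation"]
        assert pro[0.0] == pytest.approx(3.0)
        assert pro[180.0] == pytest.approx(1.0)

    def test_shift_recovered_downstream(self):
        emg = generate_emg(
            [30.0, 100.0, 170.0, 240.0, 310.0, 20.0],
            pd_shift=58.8,
            amplitude=2.0,
            baseline=5.0,
            noise_sd=0.1,
            n_trials=10,
            seed=3,
        )
        _, summary = muscle_frame_summary(emg)
        assert summary.mean_angle == pytest.approx(58.8, abs=5.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_emg([0.0], pd_shift=0.0, noise_sd=-0.1)

    def test_design_complete(self):
        emg = generate_emg([10.0, 20.0], pd_shift=30.0, noise_sd=0.05, seed=0)
        counts = emg.table.groupby(["muscle_id", "posture"])["direction_deg"].nunique()
        assert (counts == 8).all()
        assert isinstance(emg, EmgDataset)


class TestTimeseries:
    def test_run_length(self, noiseless_extrinsic):
        cfg = small_config()
        runs = generate_timeseries(noiseless_extrinsic, cfg)
        assert all(r.n_volumes == 109 for r in runs)
        assert len(runs) == 2 * cfg.runs_per_posture
        np.testing.assert_allclose(runs[0].block_onsets[:3], [20.0, 26.0, 32.0])
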