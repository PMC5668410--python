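import numpy as np
import pytest

from frameindex import SyntheticConfig, generate_dataset
from frameindex.preprocess import zscore_volumes


def small_config(**overrides) -> SyntheticConfig:
    """A fast single-participant configuration for unit tests."""
    base = dict(
        n_participants=1,
        n_voxels=40,
        n_neurons_per_voxel=8,
        delta_theta_true=0.0,
        pd_rotation_jitter_sd=0.0,
        noise_sd=0.0,
        runs_per_posture=3,
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def noiseless_extrinsic():
    """One participant, no noise/jitter, no frame rotation."""
    return generate_dataset(small_config())


@pytest.fixture
def noiseless_joint():
    """One participant, no noise/jitter, 90-degree frame rotation."""
    return generate_dataset(small_config(delta_theta_true=90.0))


def zscored_study(delta_theta_true: float, seed: int, n_participants: int = 12) -> "TrialDataset":
    """A full-scale simulated study, z-scored, at the default conditions."""
    cfg = SyntheticConfig(
        n_participants=n_participants, delta_theta_true=delta_theta_true, seed=seed
    )
    return zscore_volumes(generate_dataset(cfg))
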