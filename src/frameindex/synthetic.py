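"""Synthetic population-code datasets with a known reference-frame rotation.

The generator emulates the statistical structure the downstream analyses
assume: each voxel pools a private subpopulation of cosine-tuned units
(``response = b + k cos(theta - pd)``) through nonnegative, row-normalized
mixing weights, with i.i.d. Gaussian trial noise on top.  Between the Pro
and Mid postural conditions every unit's preferred direction moves by
``delta_theta_true`` plus a unit-specific jitter, so the ground-truth
coordinate index of the simulated region is known exactly.  Direction
labels are always expressed in the task (extrinsic) frame.

Trials are organized into runs of ``trials_per_run`` trials (default 32:
8 directions x 4 repetitions, randomized order per run) with
``runs_per_posture`` runs per posture, mirroring the block design of a
slow event-related acquisition.  An EMG-table generator and a raw
time-series renderer (the inverse of the preprocessing chain) round out
the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .angles import wrap_360
from .data import EmgDataset, TrialDataset
from .exceptions import ConfigurationError, SizeError
from .preprocess import RunSeries

__all__ = [
    "SyntheticConfig",
    "NeuronPopulation",
    "generate_population",
    "generate_trials",
    "generate_dataset",
    "generate_emg",
    "generate_timeseries",
]


@dataclass
class SyntheticConfig:
    """Generative parameters of the simulated experiment.

    Angles are degrees.  ``delta_theta_true`` is the ground-truth frame
    rotation: from Pro to Mid every unit's preferred direction moves by
    ``delta_theta_true`` (plus ``pd_rotation_jitter_sd`` jitter) along the
    task's direction-label axis, so 0 simulates an extrinsic region and 90
    a joint-like one.  ``noise_sd`` is additive Gaussian noise per trial
    and voxel, in the same response units as the unit tuning amplitudes.
    """

    n_participants: int = 12
    n_voxels: int = 200
    n_neurons_per_voxel: int = 20
    delta_theta_true: float = 0.0
    pd_rotation_jitter_sd: float = 10.0
    tuning_amplitude_range: tuple[float, float] = (0.5, 1.5)
    baseline_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.2
    runs_per_posture: int = 8
    trials_per_run: int = 32
    n_directions: int = 8
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_participants",
            "n_voxels",
            "n_neurons_per_voxel",
            "runs_per_posture",
            "trials_per_run",
            "n_directions",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.pd_rotation_jitter_sd < 0:
            raise ConfigurationError(
                f"pd_rotation_jitter_sd must be >= 0, got {self.pd_rotation_jitter_sd!r}"
            )
        for name in ("tuning_amplitude_range", "baseline_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name} must be (low, high) with low <= high")
        if self.trials_per_run % self.n_directions != 0:
            raise ConfigurationError(
                "trials_per_run must be divisible by n_directions so every "
                f"direction repeats equally often (got {self.trials_per_run} "
                f"/ {self.n_directions})"
            )

    @property
    def directions(self) -> np.ndarray:
        """The direction-label lattice, degrees."""
        return np.arange(self.n_directions) * (360.0 / self.n_directions)


@dataclass
class NeuronPopulation:
    """Cosine-tuned units grouped per voxel.

    ``pd``, ``amplitude`` and ``baseline`` have shape
    (n_voxels, n_neurons_per_voxel); ``weights`` holds each voxel's
    nonnegative mixing weights over its own units, normalized to sum to 1
    per voxel so the expected response scale is comparable across voxels.
    """

    pd: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.pd, self.amplitude, self.baseline, self.weights)}
        if len(shapes) != 1 or self.pd.ndim != 2:
            raise SizeError("population arrays must share one 2-D shape")
        if np.any(self.weights < 0):
            raise SizeError("mixing weights must be nonnegative")
        if np.any(self.weights.sum(axis=1) <= 0):
            raise SizeError("every voxel needs at least one nonzero mixing weight")

    @property
    def n_voxels(self) -> int:
        return self.pd.shape[0]

    @property
    def n_units(self) -> int:
        return self.pd.size

    @property
    def preferred_directions(self) -> np.ndarray:
        """All unit PDs, flattened, degrees in [0, 360)."""
        return self.pd.ravel()

    def mixing_matrix(self) -> np.ndarray:
        """Dense (n_voxels x n_units) block-diagonal mixing matrix."""
        n_v, n_u = self.pd.shape
        m = np.zeros((n_v, n_v * n_u))
        for v in range(n_v):
            m[v, v * n_u : (v + 1) * n_u] = self.weights[v]
        return m


def generate_population(config: SyntheticConfig, participant_seed) -> NeuronPopulation:
    """Draw one participant's unit population.

    Unit preferred directions are uniform on the circle, amplitudes and
    baselines uniform within their configured ranges, and mixing weights
    uniform nonnegative, normalized per voxel.
    """
    config.validate()
    rng = np.random.default_rng(participant_seed)
    shape = (config.n_voxels, config.n_neurons_per_voxel)
    pd_ = rng.uniform(0.0, 360.0, size=shape)
    amp = rng.uniform(*config.tuning_amplitude_range, size=shape)
    base = rng.uniform(*config.baseline_range, size=shape)
    w = rng.uniform(0.0, 1.0, size=shape)
    # guard against an all-zero draw (probability 0, but keep the invariant)
    w[w.sum(axis=1) == 0, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return NeuronPopulation(pd=pd_, amplitude=amp, baseline=base, weights=w)


def _voxel_tuning_coefficients(
    population: NeuronPopulation, pd_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mixed-voxel response to direction theta is B + A cos(theta) + C sin(theta).

    Cosine tuning is closed under nonnegative mixing, so each voxel's
    noiseless response is itself a (possibly weak) cosine in theta.
    """
    rad = np.deg2rad(pd_deg)
    wk = population.weights * population.amplitude
    a = (wk * np.cos(rad)).sum(axis=1)
    c = (wk * np.sin(rad)).sum(axis=1)
    b = (population.weights * population.baseline).sum(axis=1)
    return b, a, c


def _run_direction_sequence(config: SyntheticConfig, rng) -> np.ndarray:
    reps = config.trials_per_run // config.n_directions
    seq = np.tile(config.directions, reps)
    return rng.permutation(seq)


def generate_trials(
    population: NeuronPopulation,
    config: SyntheticConfig,
    participant_id: int = 0,
    seed=None,
) -> TrialDataset:
    """Render one participant's full two-posture trial dataset.

    Pro-posture unit responses follow ``b + k cos(theta - pd)``; for Mid
    trials each unit's preferred direction is first moved by
    ``delta_theta_true`` plus its private jitter.  Voxel responses are the
    weight-mixed unit responses plus Gaussian noise, organized into
    ``runs_per_posture`` runs per posture with a randomized direction
    order per run.  Pro runs get ids 1..R, Mid runs R+1..2R.
    """
    config.validate()
    if population.n_voxels != config.n_voxels or population.pd.shape[1] != config.n_neurons_per_voxel:
        raise SizeError(
            "population shape "
            f"{population.pd.shape} does not match config "
            f"({config.n_voxels}, {config.n_neurons_per_voxel})"
        )
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, participant_id, 1])

    jitter = (
        rng.normal(0.0, config.pd_rotation_jitter_sd, size=population.pd.shape)
        if config.pd_rotation_jitter_sd > 0
        else np.zeros_like(population.pd)
    )
    coeffs = {
        "Pro": _voxel_tuning_coefficients(population, population.pd),
        "Mid": _voxel_tuning_coefficients(
            population, population.pd + config.delta_theta_true + jitter
        ),
    }

    parts = []
    run_id = 0
    for posture in ("Pro", "Mid"):
        b, a, c = coeffs[posture]
        for _ in range(config.runs_per_posture):
            run_id += 1
            theta = _run_direction_sequence(config, rng)
            rad = np.deg2rad(theta)
            clean = b[None, :] + np.outer(np.cos(rad), a) + np.outer(np.sin(rad), c)
            noise = (
                rng.normal(0.0, config.noise_sd, size=clean.shape)
                if config.noise_sd > 0
                else 0.0
            )
            n = theta.size
            parts.append(
                TrialDataset(
                    responses=clean + noise,
                    direction_deg=theta,
                    posture=np.asarray([posture] * n, dtype=object),
                    run_id=np.full(n, run_id, dtype=int),
                    participant_id=np.full(n, participant_id, dtype=int),
                )
            )
    return TrialDataset.concatenate(parts)


def generate_dataset(config: SyntheticConfig) -> TrialDataset:
    """All participants of a simulated study, concatenated.

    Per-participant populations and trial noise derive deterministically
    from ``config.seed`` and the participant index.
    """
    config.validate()
    parts = []
    for pid in range(config.n_participants):
        population = generate_population(config, participant_seed=[config.seed, pid, 0])
        parts.append(
            generate_trials(population, config, participant_id=pid, seed=config.seed)
        )
    return TrialDataset.concatenate(parts)


def generate_emg(
    true_pd_pro,
    pd_shift,
    amplitude=1.0,
    baseline=2.0,
    noise_sd=0.0,
    n_trials: int = 10,
    seed: int = 0,
    muscle_ids: Sequence | None = None,
    n_directions: int = 8,
) -> EmgDataset:
    """Cosine-tuned trial-mean muscle activations in two postures.

    Pro-posture means follow ``b + k cos(theta - mu)`` with
    ``mu = true_pd_pro``; Mid trials use ``mu = true_pd_pro - pd_shift``
    (a positive ``pd_shift`` is a clockwise PD rotation, the convention in
    which empirical muscle rotations are quoted).  Gaussian noise is added
    per trial.  Scalar arguments broadcast over muscles.
    """
    if n_trials < 1:
        raise ConfigurationError(f"n_trials must be >= 1, got {n_trials}")
    if np.any(np.asarray(noise_sd) < 0):
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd!r}")
    mu_pro = np.atleast_1d(np.asarray(true_pd_pro, dtype=float))
    n_muscles = mu_pro.size
    shift = np.broadcast_to(np.asarray(pd_shift, dtype=float), (n_muscles,))
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), (n_muscles,))
    base = np.broadcast_to(np.asarray(baseline, dtype=float), (n_muscles,))
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_muscles,))
    if muscle_ids is None:
        muscle_ids = [f"muscle{i + 1}" for i in range(n_muscles)]
    if len(muscle_ids) != n_muscles:
        raise ConfigurationError("muscle_ids length must match true_pd_pro")

    rng = np.random.default_rng(seed)
    directions = np.arange(n_directions) * (360.0 / n_directions)
    rows = []
    for m in range(n_muscles):
        for posture, mu in (("Pro", mu_pro[m]), ("Mid", mu_pro[m] - shift[m])):
            for theta in directions:
                mean = base[m] + amp[m] * np.cos(np.deg2rad(theta - mu))
                acts = mean + (
                    rng.normal(0.0, sd[m], size=n_trials) if sd[m] > 0 else 0.0
                )
                for t in range(n_trials):
                    rows.append(
                        (
                            muscle_ids[m],
                            posture,
                            theta,
                            t + 1,
                            acts[t] if np.ndim(acts) else float(acts),
                        )
                    )
    table = pd.DataFrame(
        rows, columns=["muscle_id", "posture", "direction_deg", "trial", "activation"]
    )
    return EmgDataset(table)


def generate_timeseries(
    dataset: TrialDataset,
    config: SyntheticConfig,
    baseline_level: float = 100.0,
    drift_per_volume: float = 0.0,
    noise_sd: float = 0.0,
    delay: float = 4.0,
    tr_seconds: float = 2.0,
    rest_duration: float = 20.0,
    block_duration: float = 6.0,
    terminal_rest: float = 6.0,
    seed: int = 0,
) -> list[RunSeries]:
    """Render trial patterns as raw per-run volume series.

    Each run is an initial ``rest_duration`` baseline, then one
    ``block_duration`` block per trial whose pattern-carrying volumes are
    delayed by ``delay`` seconds, then a short terminal rest; the voxel
    baseline is ``baseline_level`` with an optional linear drift
    (relative units per volume).  This is the inverse of the
    preprocessing chain up to noise: shift/normalize/detrend/extract on
    the output recovers the input patterns.
    """
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd!r}")
    rng = np.random.default_rng(seed)
    per_block = int(round(block_duration / tr_seconds))
    delay_vols = int(round(delay / tr_seconds))
    rest_vols = int(round(rest_duration / tr_seconds))
    out = []
    keys = pd.DataFrame(
        {
            "participant_id": dataset.participant_id,
            "posture": dataset.posture,
            "run_id": dataset.run_id,
        }
    )
    for (pid, posture, run), idx in keys.groupby(
        ["participant_id", "posture", "run_id"], sort=True
    ).groups.items():
        idx = np.asarray(idx)
        patterns = dataset.responses[idx]
        labels = dataset.direction_deg[idx]
        n_trials = idx.size
        n_vol = int(
            round((rest_duration + n_trials * block_duration + terminal_rest) / tr_seconds)
        )
        t = np.arange(n_vol, dtype=float)
        volumes = np.tile(
            baseline_level * (1.0 + drift_per_volume * t)[:, None],
            (1, dataset.n_features),
        )
        onsets = rest_duration + block_duration * np.arange(n_trials)
        for j in range(n_trials):
            start = rest_vols + per_block * j + delay_vols
            volumes[start : start + per_block] += patterns[j]
        if noise_sd > 0:
            volumes += rng.normal(0.0, noise_sd, size=volumes.shape)
        out.append(
            RunSeries(
                volumes=volumes,
                block_onsets=onsets,
                direction_deg=labels,
                posture=str(posture),
                run_id=int(run),
                participant_id=int(pid),
                tr_seconds=tr_seconds,
                rest_duration=rest_duration,
                block_duration=block_duration,
            )
        )
    return out
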