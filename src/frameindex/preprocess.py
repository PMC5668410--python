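"""Signal conditioning from per-run time series to trial patterns.

The pipeline mirrors a standard block-design conditioning chain and is
applied in a fixed order:

    shift_hemodynamic -> normalize_baseline -> detrend_linear
        -> extract_trial_patterns -> zscore_volumes

Each run starts with a 20 s rest period used as the normalization
baseline, followed by 6 s task blocks (one trial each) and a short
terminal rest.  Signals are acquired every ``tr_seconds`` (2 s) and are
shifted 4 s earlier to compensate for the hemodynamic delay before any
other step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import TrialDataset
from .exceptions import (
    BoundaryError,
    ConfigurationError,
    DegenerateBaselineError,
    SizeError,
)

__all__ = [
    "RunSeries",
    "shift_hemodynamic",
    "normalize_baseline",
    "detrend_linear",
    "extract_trial_patterns",
    "zscore_volumes",
    "preprocess_run",
    "write_nifti_run",
    "read_nifti_run",
]


@dataclass
class RunSeries:
    """One acquisition run: volumes-by-voxels samples plus block timing."""

    volumes: np.ndarray            # (n_volumes, n_voxels)
    block_onsets: np.ndarray       # seconds, one per trial, series clock
    direction_deg: np.ndarray      # one per trial
    posture: str
    run_id: int
    participant_id: int = 0
    tr_seconds: float = 2.0
    rest_duration: float = 20.0
    block_duration: float = 6.0

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.block_onsets = np.asarray(self.block_onsets, dtype=float)
        self.direction_deg = np.asarray(self.direction_deg, dtype=float)
        if self.volumes.ndim != 2:
            raise SizeError("volumes must be a 2-D time x voxels matrix")
        if self.block_onsets.shape != self.direction_deg.shape:
            raise SizeError("block_onsets and direction_deg must align")
        if not np.all(np.isfinite(self.volumes)):
            raise SizeError("volumes contain non-finite values")
        duration = self.volumes.shape[0] * self.tr_seconds
        if np.any(self.block_onsets < 0) or np.any(self.block_onsets >= duration):
            raise BoundaryError("block onsets fall outside the series")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.volumes.shape[1]

    def _volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_seconds

    def task_volume_indices(self) -> np.ndarray:
        """Indices of volumes falling inside any task block."""
        idx = []
        per_block = int(round(self.block_duration / self.tr_seconds))
        for onset in self.block_onsets:
            start = int(round(onset / self.tr_seconds))
            idx.extend(range(start, start + per_block))
        idx = np.asarray(sorted(set(i for i in idx if 0 <= i < self.n_volumes)), dtype=int)
        return idx


def shift_hemodynamic(series: RunSeries, delay: float = 4.0) -> RunSeries:
    """Attribute signals to events ``delay`` seconds earlier.

    The delay must be a whole number of TRs; the first ``delay / TR``
    volumes are dropped so that block onsets line up with the
    pattern-carrying volumes.
    """
    ratio = delay / series.tr_seconds
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"delay ({delay} s) must be a multiple of the TR ({series.tr_seconds} s)"
        )
    k = int(round(ratio))
    if k == 0:
        return replace(series, volumes=series.volumes.copy())
    if k >= series.n_volumes:
        raise SizeError("delay exceeds the series duration")
    return replace(series, volumes=series.volumes[k:].copy())


def _rest_volume_count(series: RunSeries) -> int:
    return int(round(series.rest_duration / series.tr_seconds))


def normalize_baseline(series: RunSeries) -> RunSeries:
    """Divide every voxel by its mean over the initial rest period."""
    n_rest = _rest_volume_count(series)
    if series.n_volumes < n_rest:
        raise SizeError("series shorter than the rest period")
    rest_mean = series.volumes[:n_rest].mean(axis=0)
    floor = 1e-12 * max(np.abs(series.volumes).mean(), 1e-300)
    bad = np.flatnonzero(np.abs(rest_mean) < floor)
    if bad.size:
        raise DegenerateBaselineError(
            f"rest-period mean is degenerate for voxel(s) {bad.tolist()[:10]}"
        )
    return replace(series, volumes=series.volumes / rest_mean)


def detrend_linear(series: RunSeries) -> RunSeries:
    """Remove a per-voxel linear trend; the run mean is preserved.

    The slope is estimated from the task-free volumes (the initial rest
    period plus any terminal rest), so that block-related signal cannot
    leak into the trend estimate, and the fitted slope is then removed
    across the entire run.  Falls back to all volumes when fewer than two
    task-free volumes exist.
    """
    if series.n_volumes < 3:
        raise SizeError("need at least 3 volumes to detrend")
    t = np.arange(series.n_volumes, dtype=float)
    task = set(series.task_volume_indices().tolist())
    rest = np.asarray([i for i in range(series.n_volumes) if i not in task], dtype=int)
    if rest.size < 2:
        rest = np.arange(series.n_volumes)
    design = np.column_stack([np.ones(rest.size), t[rest]])
    coef, *_ = np.linalg.lstsq(design, series.volumes[rest], rcond=None)
    slope = coef[1]
    detrended = series.volumes - np.outer(t - t.mean(), slope)
    return replace(series, volumes=detrended)


def extract_trial_patterns(series: RunSeries, samples: str = "volume") -> TrialDataset:
    """Collect the pattern-carrying volumes of each block into samples.

    samples="volume" emits one sample per task volume (3 per 6 s block at
    TR = 2 s); samples="trial" averages the block's volumes into a single
    sample.  Each sample inherits its block's direction label.
    """
    if samples not in ("volume", "trial"):
        raise ConfigurationError(f"samples must be 'volume' or 'trial', got {samples!r}")
    per_block = int(round(series.block_duration / series.tr_seconds))
    rows, labels = [], []
    for onset, direction in zip(series.block_onsets, series.direction_deg):
        start = int(round(onset / series.tr_seconds))
        stop = start + per_block
        if stop > series.n_volumes:
            raise BoundaryError(
                f"block at {onset} s extends past the end of the series"
            )
        block = series.volumes[start:stop]
        if samples == "trial":
            rows.append(block.mean(axis=0))
            labels.append(direction)
        else:
            rows.extend(block)
            labels.extend([direction] * per_block)
    n = len(labels)
    return TrialDataset(
        responses=np.asarray(rows),
        direction_deg=np.asarray(labels),
        posture=np.asarray([series.posture] * n, dtype=object),
        run_id=np.full(n, series.run_id, dtype=int),
        participant_id=np.full(n, series.participant_id, dtype=int),
    )


def zscore_volumes(patterns: TrialDataset) -> TrialDataset:
    """Standardize each sample across its features (mean 0, sd 1).

    Every sample's feature vector is z-transformed on its own, which
    equalizes overall activation magnitude between postural conditions.
    The population (ddof=0) standard deviation is used.  Zero-variance
    samples are replaced by zeros and reported through ``warnings``.
    """
    if patterns.n_samples < 2:
        raise SizeError("need at least 2 samples per stratum to z-score")
    x = patterns.responses
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance sample(s) replaced by zeros: "
            f"rows {flat.tolist()[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[flat] = 0.0
    out = patterns.select(np.arange(patterns.n_samples))
    out.responses = z
    return out


def preprocess_run(
    series: RunSeries, delay: float = 4.0, samples: str = "volume"
) -> TrialDataset:
    """shift -> normalize -> detrend -> extract for one run (no z-score).

    Z-scoring is applied once patterns from all runs are concatenated,
    via :func:`zscore_volumes`.
    """
    s = shift_hemodynamic(series, delay)
    s = normalize_baseline(s)
    s = detrend_linear(s)
    return extract_trial_patterns(s, samples=samples)


# -- NIfTI export/import ------------------------------------------------

def write_nifti_run(series: RunSeries, nifti_path, onsets_path) -> None:
    """Write one run as a 4-D NIfTI (voxels on the first axis) plus a TSV
    sidecar of block onsets and labels."""
    import nibabel as nib
    import pandas as pd

    data = series.volumes.T[:, None, None, :]  # voxels x 1 x 1 x time
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_seconds))
    nib.save(img, str(nifti_path))
    pd.DataFrame(
        {
            "onset": series.block_onsets,
            "duration": series.block_duration,
            "direction_deg": series.direction_deg,
            "posture": series.posture,
            "run_id": series.run_id,
            "participant_id": series.participant_id,
        }
    ).to_csv(onsets_path, sep="\t", index=False)


def read_nifti_run(nifti_path, onsets_path) -> RunSeries:
    import nibabel as nib
    import pandas as pd

    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    volumes = data.reshape(-1, data.shape[-1]).T
    tr = float(img.header.get_zooms()[-1]) or 2.0
    onsets = pd.read_csv(onsets_path, sep="\t")
    return RunSeries(
        volumes=volumes,
        block_onsets=onsets["onset"].to_numpy(float),
        direction_deg=onsets["direction_deg"].to_numpy(float),
        posture=str(onsets["posture"].iloc[0]),
        run_id=int(onsets["run_id"].iloc[0]),
        participant_id=int(onsets["participant_id"].iloc[0]),
        tr_seconds=tr,
        block_duration=float(onsets["duration"].iloc[0]),
    )
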