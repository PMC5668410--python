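"""Trial-level data containers and delimited-text I/O.

The primary exchange format of the package is the trial-by-feature response
matrix with per-trial metadata (aiming-direction label, posture, run,
participant).  On disk this is a TSV with the metadata columns first and
feature columns ``v0001`` ... ``vNNNN`` after them, one row per trial
(or per retained task volume when patterns are extracted per volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, SizeError

POSTURES = ("Pro", "Mid")

META_COLUMNS = ["participant_id", "run_id", "posture", "direction_deg"]


def feature_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"v{i + 1:0{width}d}" for i in range(n)]


@dataclass
class TrialDataset:
    """Samples-by-features responses plus per-sample task metadata.

    Attributes
    ----------
    responses : (n_samples, n_features) float array
        Multi-voxel (or multi-channel) activity pattern of each trial.
    direction_deg : (n_samples,) float array
        Instructed aiming direction, degrees on the 45-degree lattice,
        expressed in the task (extrinsic) frame under both postures.
    posture : (n_samples,) str array
        ``"Pro"`` or ``"Mid"``.
    run_id, participant_id : (n_samples,) int arrays
    """

    responses: np.ndarray
    direction_deg: np.ndarray
    posture: np.ndarray
    run_id: np.ndarray
    participant_id: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise SizeError("responses must be a 2-D samples x features matrix")
        n = self.responses.shape[0]
        self.direction_deg = np.asarray(self.direction_deg, dtype=float)
        self.posture = np.asarray(self.posture, dtype=object)
        self.run_id = np.asarray(self.run_id, dtype=int)
        self.participant_id = np.asarray(self.participant_id, dtype=int)
        for name in ("direction_deg", "posture", "run_id", "participant_id"):
            if getattr(self, name).shape != (n,):
                raise SizeError(f"{name} must have one entry per sample (expected {n})")
        bad = set(np.unique(self.posture)) - set(POSTURES)
        if bad:
            raise DesignError(f"unknown posture labels: {sorted(bad)}")

    # -- basic protocol ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.responses.shape[0]

    @property
    def n_features(self) -> int:
        return self.responses.shape[1]

    def __len__(self) -> int:
        return self.n_samples

    def select(self, mask) -> "TrialDataset":
        """Row subset (boolean mask or index array)."""
        mask = np.asarray(mask)
        return TrialDataset(
            responses=self.responses[mask],
            direction_deg=self.direction_deg[mask],
            posture=self.posture[mask],
            run_id=self.run_id[mask],
            participant_id=self.participant_id[mask],
        )

    def for_posture(self, posture: str) -> "TrialDataset":
        return self.select(self.posture == posture)

    def for_participant(self, participant_id: int) -> "TrialDataset":
        return self.select(self.participant_id == int(participant_id))

    def runs(self, posture: str | None = None) -> np.ndarray:
        """Sorted unique run ids, optionally within one posture."""
        if posture is None:
            return np.unique(self.run_id)
        return np.unique(self.run_id[self.posture == posture])

    def participants(self) -> np.ndarray:
        return np.unique(self.participant_id)

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "run_id": self.run_id,
                "posture": self.posture,
                "direction_deg": self.direction_deg,
            }
        )
        feats = pd.DataFrame(self.responses, columns=feature_names(self.n_features))
        return pd.concat([df, feats], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialDataset":
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"missing metadata columns: {missing}")
        feat_cols = [c for c in df.columns if c not in META_COLUMNS]
        return cls(
            responses=df[feat_cols].to_numpy(dtype=float),
            direction_deg=df["direction_deg"].to_numpy(dtype=float),
            posture=df["posture"].to_numpy(dtype=object),
            run_id=df["run_id"].to_numpy(dtype=int),
            participant_id=df["participant_id"].to_numpy(dtype=int),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TrialDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @staticmethod
    def concatenate(parts: Iterable["TrialDataset"]) -> "TrialDataset":
        parts = list(parts)
        if not parts:
            raise SizeError("nothing to concatenate")
        return TrialDataset(
            responses=np.vstack([p.responses for p in parts]),
            direction_deg=np.concatenate([p.direction_deg for p in parts]),
            posture=np.concatenate([p.posture for p in parts]),
            run_id=np.concatenate([p.run_id for p in parts]),
            participant_id=np.concatenate([p.participant_id for p in parts]),
        )


@dataclass
class EmgDataset:
    """Per-trial mean muscle activations for the isometric aiming task.

    A thin wrapper over a long-format DataFrame with columns
    ``muscle_id, posture, direction_deg, trial, activation``; activations
    are expressed relative to the pre-movement rest level.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ["muscle_id", "posture", "direction_deg", "trial", "activation"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DesignError(f"EMG table missing columns: {missing}")
        if not np.all(np.isfinite(self.table["activation"].to_numpy(float))):
            raise DesignError("EMG activations must be finite")

    def muscles(self) -> list:
        return sorted(self.table["muscle_id"].unique().tolist())

    def for_muscle(self, muscle_id, posture: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["muscle_id"] == muscle_id]
        if posture is not None:
            sub = sub[sub["posture"] == posture]
        return sub

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "EmgDataset":
        return cls(pd.read_csv(path, sep="\t"))
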