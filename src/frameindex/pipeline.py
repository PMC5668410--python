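"""End-to-end experiment orchestration.

``run_experiment`` drives the full staged analysis on a synthetic study:

    simulate -> (optional time-series render + preprocessing) -> z-score
        -> label decoding / generalization profiles -> asymmetry contrast
        -> coordinate-index estimation -> group circular statistics

and writes every intermediate table (TSV), a JSON results manifest and a
seed/version log into the configured output directory.  The whole run is
deterministic given the configuration.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coordframe import fit_participants, group_coordinate_index
from .data import TrialDataset
from .exceptions import ConfigurationError
from .labeldecode import (
    GeneralizationProfile,
    OFFSET_BINS,
    across_posture_profile,
    asymmetry_contrast,
    asymmetry_index,
    generalization_profile,
)
from .preprocess import preprocess_run, zscore_volumes
from .synthetic import SyntheticConfig, generate_dataset, generate_timeseries

__all__ = ["RunConfig", "ResultBundle", "run_experiment", "make_report"]

_SYNTH_FIELDS = set(SyntheticConfig.__dataclass_fields__)


@dataclass
class RunConfig:
    """Validated single-file configuration of an end-to-end run."""

    seed: int
    output_dir: str = "frameindex-results"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    use_timeseries: bool = False
    zscore: bool = True
    classifier_c: float = 1.0
    grid_start: float = -45.0
    grid_stop: float = 315.0
    grid_step: float = 5.0
    estimator: str = "ridge"
    alphas: list | None = None
    references: tuple = (0.0, 90.0)
    n_comparisons: int = 9
    n_boot: int = 10000
    write_intermediates: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigurationError("config root must be a mapping")
        if "seed" not in raw:
            raise ConfigurationError("config.seed is required")
        raw = dict(raw)
        synth_raw = raw.pop("synthetic", {})
        unknown = set(synth_raw) - _SYNTH_FIELDS
        if unknown:
            raise ConfigurationError(f"config.synthetic: unknown field(s) {sorted(unknown)}")
        for key in ("tuning_amplitude_range", "baseline_range"):
            if key in synth_raw:
                synth_raw[key] = tuple(synth_raw[key])
        synth_raw.setdefault("seed", raw["seed"])
        synth = SyntheticConfig(**synth_raw)
        synth.validate()
        known = set(cls.__dataclass_fields__) - {"synthetic"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"config: unknown field(s) {sorted(unknown)}")
        cfg = cls(synthetic=synth, **raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("config.seed must be an integer")
        if self.grid_step <= 0:
            raise ConfigurationError("config.grid_step must be > 0")
        if self.grid_stop <= self.grid_start:
            raise ConfigurationError("config.grid_stop must exceed config.grid_start")
        if self.estimator not in ("ridge", "lasso"):
            raise ConfigurationError("config.estimator must be 'ridge' or 'lasso'")
        if self.n_comparisons < 1:
            raise ConfigurationError("config.n_comparisons must be >= 1")
        self.synthetic.validate()

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step))
        return self.grid_start + self.grid_step * np.arange(n + 1)


@dataclass
class ResultBundle:
    """Everything one experiment produced, plus the output paths."""

    config: RunConfig
    dataset: TrialDataset
    profiles: dict                 # participant -> {"within": ..., "across": ...}
    asymmetry: object
    frame_results: list
    group: object
    manifest: dict
    output_dir: Path | None = None

    REQUIRED = ("config", "dataset", "profiles", "asymmetry", "frame_results", "group", "manifest")


def _participant_profiles(data: TrialDataset, C: float):
    """Within-posture (LORO, averaged over postures) and aligned
    across-posture profiles for one participant."""
    within_pro = generalization_profile(data, "Pro", "Pro", C=C)
    within_mid = generalization_profile(data, "Mid", "Mid", C=C)
    within = GeneralizationProfile(
        offsets=OFFSET_BINS.copy(),
        fraction=0.5 * (within_pro.fraction + within_mid.fraction),
        train_posture="within",
        test_posture="within",
        n_test=within_pro.n_test + within_mid.n_test,
    )
    across = across_posture_profile(data, C=C, pool=True)
    return within, across


def run_experiment(config: RunConfig) -> ResultBundle:
    """Run the staged pipeline and write all artifacts.

    Returns the in-memory bundle; on disk the output directory holds
    ``patterns.tsv``, ``profiles.tsv``, ``asymmetry.tsv``,
    ``error_curves.tsv``, ``delta_theta_hat.tsv``, ``manifest.json`` and
    ``log.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    if config.write_intermediates:
        out.mkdir(parents=True, exist_ok=True)

    dataset = generate_dataset(config.synthetic)
    if config.use_timeseries:
        runs = generate_timeseries(dataset, config.synthetic, seed=config.seed)
        dataset = TrialDataset.concatenate(
            [preprocess_run(r, samples="trial") for r in runs]
        )
    if config.zscore:
        dataset = zscore_volumes(dataset)
    if config.write_intermediates:
        dataset.to_tsv(out / "patterns.tsv")

    profiles = {}
    within_idx, across_idx = [], []
    for pid in dataset.participants():
        sub = dataset.for_participant(pid)
        within, across = _participant_profiles(sub, C=config.classifier_c)
        profiles[int(pid)] = {"within": within, "across": across}
        within_idx.append(asymmetry_index(within))
        across_idx.append(asymmetry_index(across))
    asymmetry = asymmetry_contrast(within_idx, across_idx, n_comparisons=config.n_comparisons)

    frame_results = fit_participants(
        dataset,
        grid=config.grid(),
        estimator=config.estimator,
        alphas=config.alphas,
    )
    estimates = [r.delta_theta_hat for r in frame_results]
    group = group_coordinate_index(
        estimates,
        references=config.references,
        n_boot=config.n_boot,
        seed=config.seed,
    )

    manifest = {
        "seed": int(config.seed),
        "n_participants": int(dataset.participants().size),
        "delta_theta_true": float(config.synthetic.delta_theta_true),
        "delta_theta_hat_per_participant": [float(e) for e in estimates],
        "group_mean_deg": group.mean_deg,
        "group_ci_halfwidth_deg": group.ci_halfwidth,
        "group_resultant_length": group.summary.resultant_length,
        "reference_tests": {
            f"{ref:g}": t.p_value for ref, t in group.tests.items()
        },
        "asymmetry_within_mean": asymmetry.index_within,
        "asymmetry_across_mean": asymmetry.index_across,
        "asymmetry_difference": asymmetry.difference,
        "asymmetry_p_corrected": asymmetry.p_value,
        "n_comparisons": int(config.n_comparisons),
        "offset_bins_deg": [float(o) for o in OFFSET_BINS],
        "mean_within_profile": list(
            np.mean([p["within"].fraction for p in profiles.values()], axis=0)
        ),
        "mean_across_profile": list(
            np.mean([p["across"].fraction for p in profiles.values()], axis=0)
        ),
    }

    bundle = ResultBundle(
        config=config,
        dataset=dataset,
        profiles=profiles,
        asymmetry=asymmetry,
        frame_results=frame_results,
        group=group,
        manifest=manifest,
        output_dir=out if config.write_intermediates else None,
    )

    if config.write_intermediates:
        prof_rows = []
        for pid, d in profiles.items():
            for kind, prof in d.items():
                for o, frac in zip(prof.offsets, prof.fraction):
                    prof_rows.append((pid, kind, o, frac))
        pd.DataFrame(
            prof_rows, columns=["participant_id", "condition", "offset_deg", "fraction"]
        ).to_csv(out / "profiles.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "participant_id": list(profiles),
                "asymmetry_within": within_idx,
                "asymmetry_across": across_idx,
            }
        ).to_csv(out / "asymmetry.tsv", sep="\t", index=False)
        curves = []
        for r in frame_results:
            df = r.to_frame()
            df.insert(0, "participant_id", r.participant_id)
            curves.append(df)
        pd.concat(curves).to_csv(out / "error_curves.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in frame_results],
                "delta_theta_hat_deg": estimates,
            }
        ).to_csv(out / "delta_theta_hat.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log = {
            "frameindex_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": int(config.seed),
            "synthetic_config": asdict(config.synthetic),
        }
        with open(out / "log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return bundle


def make_report(bundle: ResultBundle) -> str:
    """Human-readable tabulation of a completed result bundle."""
    missing = [
        name for name in ResultBundle.REQUIRED if getattr(bundle, name, None) is None
    ]
    if missing:
        raise ConfigurationError(f"incomplete result bundle; missing: {missing}")
    m = bundle.manifest
    lines = [
        "frameindex experiment report",
        "============================",
        "",
        f"seed                    {m['seed']}",
        f"participants            {m['n_participants']}",
        f"true frame rotation     {m['delta_theta_true']:.1f} deg",
        "",
        "Group coordinate index",
        "----------------------",
        f"mean +/- 95% CI         {m['group_mean_deg']:.1f} +/- {m['group_ci_halfwidth_deg']:.1f} deg",
    ]
    for ref, p in m["reference_tests"].items():
        lines.append(f"test vs {float(ref):>6.1f} deg     p = {p:.4g}")
    lines += [
        "",
        "Asymmetry contrast (across - within)",
        "------------------------------------",
        f"within mean index       {m['asymmetry_within_mean']:+.4f}",
        f"across mean index       {m['asymmetry_across_mean']:+.4f}",
        f"difference              {m['asymmetry_difference']:+.4f}"
        f"   (p = {m['asymmetry_p_corrected']:.4g}, Bonferroni "
        f"x{m.get('n_comparisons', bundle.config.n_comparisons)})",
        "",
        "Mean generalization profiles (fraction per offset bin)",
        "------------------------------------------------------",
        "offset_deg  " + "  ".join(f"{o:>7.0f}" for o in m["offset_bins_deg"]),
        "within      " + "  ".join(f"{f:>7.3f}" for f in m["mean_within_profile"]),
        "across      " + "  ".join(f"{f:>7.3f}" for f in m["mean_across_profile"]),
        "",
        "Per-participant coordinate index (deg)",
        "--------------------------------------",
        "  ".join(f"{e:.1f}" for e in m["delta_theta_hat_per_participant"]),
    ]
    return "\n".join(lines)
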