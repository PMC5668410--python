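"""Direction-label decoding and posture-generalization profiles.

An 8-way linear support-vector classifier is trained on multi-voxel
patterns and its predictions are summarized as a *generalization
profile*: the fraction of predictions landing at each signed offset
(predicted - true, wrapped to (-180, 180]) from the tested direction.
Within-posture profiles use leave-one-run-out cross-validation; an
across-posture profile trains on all runs of one posture and tests on
all runs of the other.

Because the generative convention of this package moves preferred
directions by +delta_theta along the label axis from Pro to Mid, the raw
profile of a Mid-trained decoder tested on Pro peaks at +delta_theta
while the Pro-trained/Mid-tested profile peaks at -delta_theta: both
transfers estimate the same Pro-to-Mid frame rotation with opposite
signs.  :func:`across_posture_profile` therefore maps both transfers onto
the common coordinate-index axis (Pro->Mid offsets are negated) before
pooling, so a frame rotation of +delta_theta appears as a mode at
+delta_theta regardless of the transfer direction.

The asymmetry index of a profile is the mean fraction over offsets
{+45, +90, +135} minus the mean over {-45, -90, -135}; 0 and 180 are
excluded.  A symmetric profile scores 0, a clockwise-rotated frame
scores positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .angles import wrap_180
from .data import POSTURES, TrialDataset
from .exceptions import CrossValidationError, DesignError, PairingError

__all__ = [
    "GeneralizationProfile",
    "AsymmetryResult",
    "train_classifier",
    "generalization_profile",
    "across_posture_profile",
    "asymmetry_index",
    "asymmetry_contrast",
]

OFFSET_BINS = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])


@dataclass
class GeneralizationProfile:
    """Fraction of predictions per signed offset from the true direction."""

    offsets: np.ndarray       # degrees, the 8-point lattice
    fraction: np.ndarray      # sums to 1
    train_posture: str
    test_posture: str
    n_test: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.offsets.shape != self.fraction.shape:
            raise DesignError("offsets and fractions must align")
        if self.n_test > 0 and abs(self.fraction.sum() - 1.0) > 1e-9:
            raise DesignError("profile fractions must sum to 1")

    def modal_offset(self) -> float:
        """Offset with the highest fraction (ties: smallest |offset|,
        positive preferred)."""
        best = self.fraction.max()
        tied = self.offsets[self.fraction >= best - 1e-12]
        order = sorted(tied, key=lambda a: (abs(a), -np.sign(a)))
        return float(order[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_deg": self.offsets,
                "fraction": self.fraction,
                "train_posture": self.train_posture,
                "test_posture": self.test_posture,
                "n_test": self.n_test,
            }
        )


@dataclass
class AsymmetryResult:
    """Paired within/across asymmetry-index contrast over participants."""

    index_within: float
    index_across: float
    difference: float
    per_participant_within: np.ndarray
    per_participant_across: np.ndarray
    t_statistic: float
    p_value: float            # Bonferroni-corrected, capped at 1
    p_value_uncorrected: float
    n_comparisons: int
    degenerate: bool = False  # zero within-pair variance, p reported as 0 or 1


def train_classifier(
    train: TrialDataset, C: float = 1.0, expected_labels=None
) -> LinearSVC:
    """Fit the 8-way linear SVM (one-vs-rest, fixed C, deterministic).

    Ties between classes resolve to the lowest direction label because
    class columns are ordered by ascending angle and argmax takes the
    first maximum.  When ``expected_labels`` is given, every one of them
    must be present in the training data.
    """
    labels = np.unique(train.direction_deg)
    if labels.size < 2:
        raise DesignError("need at least two direction labels to train")
    if expected_labels is not None:
        missing = sorted(set(np.asarray(expected_labels, float)) - set(labels))
        if missing:
            raise DesignError(f"direction labels missing from training data: {missing}")
    clf = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6, max_iter=20000)
    clf.fit(train.responses, train.direction_deg)
    return clf


def _offset_fractions(predicted: np.ndarray, true: np.ndarray) -> np.ndarray:
    offs = wrap_180(np.asarray(predicted, float) - np.asarray(true, float))
    counts = np.array([np.count_nonzero(offs == o) for o in OFFSET_BINS], dtype=float)
    total = counts.sum()
    if total != offs.size:
        raise DesignError("prediction offsets fell outside the 45-degree lattice")
    return counts / max(total, 1.0)


def generalization_profile(
    data: TrialDataset,
    train_posture: str,
    test_posture: str,
    C: float = 1.0,
) -> GeneralizationProfile:
    """Raw generalization profile for one (train, test) posture pair.

    Within-posture (train == test): leave-one-run-out over that posture's
    runs.  Across-posture: train on every run of ``train_posture``, test
    on every run of ``test_posture``.  Offsets are predicted - true on
    (-180, 180].
    """
    for p in (train_posture, test_posture):
        if p not in POSTURES:
            raise DesignError(f"unknown posture {p!r}")
    preds, trues = [], []
    if train_posture == test_posture:
        sub = data.for_posture(train_posture)
        runs = sub.runs()
        if runs.size < 2:
            raise CrossValidationError(
                f"leave-one-run-out needs >= 2 runs in {train_posture}, got {runs.size}"
            )
        for run in runs:
            train = sub.select(sub.run_id != run)
            test = sub.select(sub.run_id == run)
            clf = train_classifier(train, C=C, expected_labels=np.unique(sub.direction_deg))
            preds.append(clf.predict(test.responses))
            trues.append(test.direction_deg)
    else:
        train = data.for_posture(train_posture)
        test = data.for_posture(test_posture)
        if len(train) == 0 or len(test) == 0:
            raise DesignError("both postures must be present in the dataset")
        clf = train_classifier(train, C=C, expected_labels=np.unique(data.direction_deg))
        preds.append(clf.predict(test.responses))
        trues.append(test.direction_deg)
    predicted = np.concatenate(preds)
    true = np.concatenate(trues)
    return GeneralizationProfile(
        offsets=OFFSET_BINS.copy(),
        fraction=_offset_fractions(predicted, true),
        train_posture=train_posture,
        test_posture=test_posture,
        n_test=true.size,
    )


def _flip_profile(fraction: np.ndarray) -> np.ndarray:
    """Re-bin fractions at offset o onto -o (180 maps to itself)."""
    flipped = np.empty_like(fraction)
    for i, o in enumerate(OFFSET_BINS):
        target = wrap_180(-o)
        flipped[np.flatnonzero(OFFSET_BINS == target)[0]] = fraction[i]
    return flipped


def across_posture_profile(
    data: TrialDataset, C: float = 1.0, pool: bool = True
) -> GeneralizationProfile:
    """Across-posture profile on the coordinate-index axis.

    Offsets of the Mid-trained/Pro-tested transfer are kept as
    predicted - true; offsets of the Pro-trained/Mid-tested transfer are
    negated (both transfers estimate the Pro-to-Mid frame rotation, with
    opposite raw signs).  With ``pool=True`` the two aligned transfers
    are averaged with equal weight.
    """
    mid_to_pro = generalization_profile(data, "Mid", "Pro", C=C)
    if not pool:
        return mid_to_pro
    pro_to_mid = generalization_profile(data, "Pro", "Mid", C=C)
    fraction = 0.5 * (mid_to_pro.fraction + _flip_profile(pro_to_mid.fraction))
    return GeneralizationProfile(
        offsets=OFFSET_BINS.copy(),
        fraction=fraction,
        train_posture="both",
        test_posture="both",
        n_test=mid_to_pro.n_test + pro_to_mid.n_test,
    )


def asymmetry_index(profile: GeneralizationProfile) -> float:
    """Mean fraction at {+45, +90, +135} minus mean at {-45, -90, -135}.

    Summation runs in mirror-matched bin order so that an exactly
    symmetric profile scores exactly 0.0.
    """

    def at(offset):
        return float(profile.fraction[np.flatnonzero(profile.offsets == offset)[0]])

    pos = (at(45.0) + at(90.0) + at(135.0)) / 3.0
    neg = (at(-45.0) + at(-90.0) + at(-135.0)) / 3.0
    return pos - neg


def asymmetry_contrast(
    per_participant_within,
    per_participant_across,
    n_comparisons: int = 1,
) -> AsymmetryResult:
    """Paired t-test of (across - within) asymmetry, Bonferroni-corrected."""
    within = np.asarray(per_participant_within, dtype=float).ravel()
    across = np.asarray(per_participant_across, dtype=float).ravel()
    if within.shape != across.shape:
        raise PairingError(
            f"paired lists differ in length ({within.size} vs {across.size})"
        )
    if within.size < 3:
        raise PairingError("need at least 3 paired participants")
    diffs = across - within
    degenerate = bool(np.allclose(diffs.std(ddof=1), 0.0))
    if degenerate:
        # zero within-pair variance: exact p is 1 (no effect) or -> 0
        p_unc = 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
        t_stat = 0.0 if p_unc == 1.0 else np.inf * np.sign(diffs.mean())
    else:
        t_stat, p_unc = stats.ttest_rel(across, within)
        t_stat, p_unc = float(t_stat), float(p_unc)
    p_corr = min(p_unc * n_comparisons, 1.0)
    return AsymmetryResult(
        index_within=float(within.mean()),
        index_across=float(across.mean()),
        difference=float(diffs.mean()),
        per_participant_within=within,
        per_participant_across=across,
        t_statistic=float(t_stat),
        p_value=p_corr,
        p_value_uncorrected=p_unc,
        n_comparisons=int(n_comparisons),
        degenerate=degenerate,
    )
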