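"""Rotation-parameterized common decoder and the coordinate index.

A single linear map ``w`` (2 x N) is asked to decode the 2-D aiming
vector ``v = (cos theta, sin theta)`` from the multi-voxel pattern ``r``
of *both* postures at once, with the Mid-posture readout rotated by a
candidate angle:

    v = w r_Pro = R(delta_theta) w r_Mid

Rearranged for fitting, Pro samples are paired with target ``v`` and Mid
samples with ``R(-delta_theta) v``; a single penalized linear regression
is fitted on the stacked design.  Sweeping ``delta_theta`` over a grid
(default -45..315 deg in 5 deg steps) and scoring each candidate by the
cross-validated mean squared error of the predicted aiming vector (Mid
predictions rotated back by ``R(delta_theta)`` before comparison) yields
an error curve whose minimizer is the region's coordinate index
``delta_theta_hat``: 0 deg for an extrinsic frame, 90 deg for a
joint-like frame, intermediate values for muscle-like frames.

Cross-validation is nested and run-wise: the outer loop leaves one run
per posture out for testing; the inner loop (leave-one-run-out over the
remaining runs) selects the regularization strength.  Under the default
L2 ("ridge") penalty the fitted map decomposes exactly as
``W(delta_theta) = W_a + W_b R(delta_theta)``, so the whole grid is
evaluated from one eigendecomposition per fold and the per-fold error
curve is exactly ``c0 + c1 cos(delta_theta) + c2 sin(delta_theta)``.  An
L1 ("lasso") penalty is available as a configuration switch and refits
per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import wrap_180, wrap_360
from .data import TrialDataset
from .exceptions import ConfigurationError, CrossValidationError, DesignError, SizeError
from .tuning import CircularSummary, CircularTestResult, circular_mean_ci, circular_one_sample_test

__all__ = [
    "rotation_matrix",
    "encode_direction",
    "encode_directions",
    "CommonDecoder",
    "fit_common_decoder",
    "CoordinateFrameModel",
    "CoordinateFrameResults",
    "error_curve",
    "estimate_coordinate_index",
    "GroupFrameResult",
    "group_coordinate_index",
    "fit_participants",
    "default_grid",
]


def default_grid(start: float = -45.0, stop: float = 315.0, step: float = 5.0) -> np.ndarray:
    """The candidate rotation grid, degrees (both bounds inclusive)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def rotation_matrix(delta_theta_deg: float) -> np.ndarray:
    """Standard 2x2 rotation matrix R(delta_theta), counterclockwise in
    the (cos, sin) encoding: R(a) v(theta) = v(theta + a)."""
    if not np.isfinite(delta_theta_deg):
        raise ConfigurationError(f"rotation angle must be finite, got {delta_theta_deg!r}")
    rad = np.deg2rad(delta_theta_deg)
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, -s], [s, c]])


def encode_direction(label_deg: float) -> np.ndarray:
    """Unit aiming vector (cos theta, sin theta) of a direction label."""
    rad = np.deg2rad(label_deg)
    return np.array([np.cos(rad), np.sin(rad)])


def encode_directions(labels_deg) -> np.ndarray:
    """(n, 2) aiming vectors for an array of direction labels."""
    rad = np.deg2rad(np.asarray(labels_deg, dtype=float))
    return np.column_stack([np.cos(rad), np.sin(rad)])


# ---------------------------------------------------------------------
# single-fit surface


@dataclass
class CommonDecoder:
    """A fitted common decoder at one candidate rotation."""

    w: np.ndarray              # (2, N)
    intercept: np.ndarray      # (2,)
    delta_theta: float
    alpha: float
    estimator: str = "ridge"

    def predict(self, responses: np.ndarray) -> np.ndarray:
        """Raw decoder-space predictions, one 2-vector per row."""
        return np.asarray(responses, float) @ self.w.T + self.intercept

    def predict_extrinsic(self, responses: np.ndarray, posture) -> np.ndarray:
        """Predictions mapped to the extrinsic frame: Mid rows are rotated
        by R(delta_theta)."""
        pred = self.predict(responses)
        mid = np.asarray(posture, object) == "Mid"
        r = rotation_matrix(self.delta_theta)
        pred[mid] = pred[mid] @ r.T
        return pred

    def predicted_direction_deg(self, responses: np.ndarray, posture) -> np.ndarray:
        """Four-quadrant arctangent of the extrinsic-frame prediction."""
        pred = self.predict_extrinsic(responses, posture)
        return wrap_360(np.rad2deg(np.arctan2(pred[:, 1], pred[:, 0])))


def _split_targets(data: TrialDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aiming vectors split by posture: Ya carries Pro rows, Yb Mid rows."""
    v = encode_directions(data.direction_deg)
    is_mid = (data.posture == "Mid").astype(float)[:, None]
    return v * (1.0 - is_mid), v * is_mid, is_mid.ravel().astype(bool)


def fit_common_decoder(
    train: TrialDataset,
    delta_theta: float,
    alpha: float = 1e-3,
    estimator: str = "ridge",
    fit_intercept: bool = True,
) -> CommonDecoder:
    """Fit ``w`` on the stacked two-posture design at one rotation.

    Pro samples are paired with ``v``; Mid samples with
    ``R(-delta_theta) v``.  ``alpha`` is the penalty weight (L2 for
    "ridge", scikit-learn's L1 scaling for "lasso").
    """
    if set(np.unique(train.posture)) != {"Pro", "Mid"}:
        raise DesignError("the common decoder needs training samples from both postures")
    x = train.responses
    ya, yb, _ = _split_targets(train)
    y = ya + yb @ rotation_matrix(delta_theta)  # row form of R(-dt) v
    if estimator == "ridge":
        if fit_intercept:
            x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
        else:
            x_mean, y_mean = np.zeros(x.shape[1]), np.zeros(2)
        xc, yc = x - x_mean, y - y_mean
        g = xc.T @ xc
        g.flat[:: g.shape[0] + 1] += alpha
        w_mat = np.linalg.solve(g, xc.T @ yc)  # (N, 2)
        intercept = y_mean - x_mean @ w_mat
        return CommonDecoder(
            w=w_mat.T, intercept=intercept, delta_theta=float(delta_theta),
            alpha=float(alpha), estimator=estimator,
        )
    if estimator == "lasso":
        from sklearn.linear_model import Lasso

        model = Lasso(alpha=alpha, fit_intercept=fit_intercept, max_iter=50000, tol=1e-8)
        model.fit(x, y)
        return CommonDecoder(
            w=np.atleast_2d(model.coef_),
            intercept=np.atleast_1d(model.intercept_) * np.ones(2),
            delta_theta=float(delta_theta),
            alpha=float(alpha),
            estimator=estimator,
        )
    raise ConfigurationError(f"estimator must be 'ridge' or 'lasso', got {estimator!r}")


# ---------------------------------------------------------------------
# nested-CV error curve (Model / Results)


class _RidgeFoldFit:
    """Eigendecomposition-based ridge fits of one training set, all alphas.

    Exploits W(delta_theta, alpha) = W_a(alpha) + W_b(alpha) R(delta_theta)
    so one eigendecomposition serves every (alpha, delta_theta) pair.
    """

    def __init__(self, x: np.ndarray, ya: np.ndarray, yb: np.ndarray, alphas, fit_intercept: bool):
        self.fit_intercept = fit_intercept
        if fit_intercept:
            self.x_mean = x.mean(axis=0)
            self.sa = ya.sum(axis=0) / x.shape[0]
            self.sb = yb.sum(axis=0) / x.shape[0]
        else:
            self.x_mean = np.zeros(x.shape[1])
            self.sa = np.zeros(2)
            self.sb = np.zeros(2)
        xc = x - self.x_mean
        g = xc.T @ xc
        evals, evecs = np.linalg.eigh(g)
        evals = np.clip(evals, 0.0, None)
        za = evecs.T @ (xc.T @ ya)
        zb = evecs.T @ (xc.T @ yb)
        self.w_a = [evecs @ (za / (evals + a)[:, None]) for a in alphas]
        self.w_b = [evecs @ (zb / (evals + a)[:, None]) for a in alphas]

    def error_terms(self, x, v, is_mid, alpha_index: int):
        """(c0, c1, c2) with MSE(dt) = c0 + c1 cos(dt) + c2 sin(dt)."""
        xc = x - self.x_mean
        p_a = xc @ self.w_a[alpha_index] + self.sa
        p_b = xc @ self.w_b[alpha_index] + self.sb
        a_term = p_a - v * (~is_mid)[:, None]
        b_term = p_b - v * is_mid[:, None]
        n = x.shape[0]
        ss = (a_term**2).sum() + (b_term**2).sum()
        cross = b_term.T @ a_term
        c1 = 2.0 * (cross[0, 0] + cross[1, 1]) / n
        c2 = 2.0 * (cross[1, 0] - cross[0, 1]) / n
        return ss / n, c1, c2


def _sinusoid(grid_deg: np.ndarray, terms) -> np.ndarray:
    c0, c1, c2 = terms
    rad = np.deg2rad(grid_deg)
    return c0 + c1 * np.cos(rad) + c2 * np.sin(rad)


class CoordinateFrameModel:
    """Estimate a region's coordinate index from one participant's trials.

    Parameters
    ----------
    data : TrialDataset
        One participant's two-posture patterns (already preprocessed).
    grid : array-like of degrees, optional
        Candidate rotations; default -45..315 in 5-degree steps.
    estimator : {"ridge", "lasso"}
        Penalty family of the common decoder.
    alphas : array-like, optional
        Regularization path searched on the inner folds.
    select_on : {"outer", "inner"}
        Where ``delta_theta_hat`` is selected: "outer" (default) picks the
        minimizer of the outer-fold test error over the full grid; "inner"
        also records the per-fold rotation chosen on the inner folds only
        (a fully nested, selection-bias-free variant).
    """

    def __init__(
        self,
        data: TrialDataset,
        grid=None,
        estimator: str = "ridge",
        alphas=None,
        fit_intercept: bool = True,
        select_on: str = "outer",
    ):
        if estimator not in ("ridge", "lasso"):
            raise ConfigurationError(f"estimator must be 'ridge' or 'lasso', got {estimator!r}")
        if select_on not in ("outer", "inner"):
            raise ConfigurationError(f"select_on must be 'outer' or 'inner', got {select_on!r}")
        if data.participants().size != 1:
            raise DesignError(
                "CoordinateFrameModel works on a single participant; "
                "use fit_participants() for a group"
            )
        self.data = data
        self.grid = np.asarray(default_grid() if grid is None else grid, dtype=float)
        if self.grid.size < 2:
            raise ConfigurationError("grid needs at least 2 candidate rotations")
        self.estimator = estimator
        self.alphas = np.asarray(
            np.logspace(-2, 4, 7) if alphas is None else np.atleast_1d(alphas), dtype=float
        )
        self.fit_intercept = fit_intercept
        self.select_on = select_on

        pro_runs = data.runs("Pro")
        mid_runs = data.runs("Mid")
        if min(pro_runs.size, mid_runs.size) < 3:
            raise CrossValidationError(
                "nested cross-validation needs at least 3 runs per posture "
                f"(got {pro_runs.size} Pro, {mid_runs.size} Mid)"
            )
        # outer folds: the i-th run of each posture is held out together
        self._fold_runs = []
        for i in range(max(pro_runs.size, mid_runs.size)):
            held = []
            if i < pro_runs.size:
                held.append(("Pro", int(pro_runs[i])))
            if i < mid_runs.size:
                held.append(("Mid", int(mid_runs[i])))
            self._fold_runs.append(held)

    # -- helpers -------------------------------------------------------
    def _mask(self, pairs) -> np.ndarray:
        m = np.zeros(len(self.data), dtype=bool)
        for posture, run in pairs:
            m |= (self.data.posture == posture) & (self.data.run_id == run)
        return m

    def _fit_ridge(self):
        data = self.data
        v = encode_directions(data.direction_deg)
        is_mid = data.posture == "Mid"
        ya = v * (~is_mid)[:, None]
        yb = v * is_mid[:, None]
        n_grid = self.grid.size
        per_fold = np.empty((len(self._fold_runs), n_grid))
        inner_choice = np.empty((len(self._fold_runs), n_grid), dtype=int)
        inner_argmin = np.empty(len(self._fold_runs))
        for f, held in enumerate(self._fold_runs):
            test_mask = self._mask(held)
            train_mask = ~test_mask
            inner_folds = [p for j, p in enumerate(self._fold_runs) if j != f]
            if len(self.alphas) > 1:
                inner_err = np.zeros((len(self.alphas), n_grid))
                for pairs in inner_folds:
                    val_mask = self._mask(pairs)
                    fit_mask = train_mask & ~val_mask
                    fold = _RidgeFoldFit(
                        data.responses[fit_mask], ya[fit_mask], yb[fit_mask],
                        self.alphas, self.fit_intercept,
                    )
                    for a in range(len(self.alphas)):
                        terms = fold.error_terms(
                            data.responses[val_mask], v[val_mask], is_mid[val_mask], a
                        )
                        inner_err[a] += _sinusoid(self.grid, terms)
                alpha_idx = inner_err.argmin(axis=0)
                inner_curve = inner_err[alpha_idx, np.arange(n_grid)]
            else:
                alpha_idx = np.zeros(n_grid, dtype=int)
                inner_curve = np.zeros(n_grid)
            outer = _RidgeFoldFit(
                data.responses[train_mask], ya[train_mask], yb[train_mask],
                self.alphas, self.fit_intercept,
            )
            outer_err = np.empty((len(self.alphas), n_grid))
            for a in np.unique(alpha_idx):
                terms = outer.error_terms(
                    data.responses[test_mask], v[test_mask], is_mid[test_mask], a
                )
                outer_err[a] = _sinusoid(self.grid, terms)
            per_fold[f] = outer_err[alpha_idx, np.arange(n_grid)]
            inner_choice[f] = alpha_idx
            inner_argmin[f] = self.grid[int(np.argmin(inner_curve))]
        return per_fold, inner_choice, inner_argmin

    def _fit_generic(self):
        """Slow per-grid-point refit path (used by the lasso estimator)."""
        data = self.data
        v = encode_directions(data.direction_deg)
        is_mid = data.posture == "Mid"
        n_grid = self.grid.size
        per_fold = np.empty((len(self._fold_runs), n_grid))
        inner_choice = np.empty((len(self._fold_runs), n_grid), dtype=int)
        inner_argmin = np.empty(len(self._fold_runs))

        def mse(decoder, mask, dt):
            pred = decoder.predict(data.responses[mask])
            target = v[mask].copy()
            target[is_mid[mask]] = target[is_mid[mask]] @ rotation_matrix(dt)
            return float(((pred - target) ** 2).sum(axis=1).mean())

        for f, held in enumerate(self._fold_runs):
            test_mask = self._mask(held)
            train_mask = ~test_mask
            inner_folds = [p for j, p in enumerate(self._fold_runs) if j != f]
            inner_err = np.zeros((len(self.alphas), n_grid))
            if len(self.alphas) > 1:
                for pairs in inner_folds:
                    val_mask = self._mask(pairs)
                    fit_mask = train_mask & ~val_mask
                    fit_data = self.data.select(fit_mask)
                    for a, alpha in enumerate(self.alphas):
                        for g, dt in enumerate(self.grid):
                            dec = fit_common_decoder(
                                fit_data, dt, alpha=alpha,
                                estimator=self.estimator, fit_intercept=self.fit_intercept,
                            )
                            inner_err[a, g] += mse(dec, val_mask, dt)
                alpha_idx = inner_err.argmin(axis=0)
            else:
                alpha_idx = np.zeros(n_grid, dtype=int)
            train_data = self.data.select(train_mask)
            for g, dt in enumerate(self.grid):
                dec = fit_common_decoder(
                    train_data, dt, alpha=self.alphas[alpha_idx[g]],
                    estimator=self.estimator, fit_intercept=self.fit_intercept,
                )
                per_fold[f, g] = mse(dec, test_mask, dt)
            inner_choice[f] = alpha_idx
            inner_curve = inner_err[alpha_idx, np.arange(n_grid)]
            inner_argmin[f] = self.grid[int(np.argmin(inner_curve))]
        return per_fold, inner_choice, inner_argmin

    def fit(self) -> "CoordinateFrameResults":
        if self.estimator == "ridge":
            per_fold, alpha_choice, inner_argmin = self._fit_ridge()
        else:
            per_fold, alpha_choice, inner_argmin = self._fit_generic()
        curve = per_fold.mean(axis=0)
        dt_hat, uninformative = estimate_coordinate_index(self.grid, curve)
        return CoordinateFrameResults(
            model=self,
            grid=self.grid.copy(),
            error_curve=curve,
            per_fold_errors=per_fold,
            delta_theta_hat=dt_hat,
            uninformative=uninformative,
            alpha_choice_index=alpha_choice,
            inner_selected_delta=inner_argmin,
            participant_id=int(self.data.participants()[0]),
        )


@dataclass
class CoordinateFrameResults:
    """Error curve over the rotation grid and its minimizer."""

    model: CoordinateFrameModel = field(repr=False)
    grid: np.ndarray = field(repr=False)
    error_curve: np.ndarray = field(repr=False)
    per_fold_errors: np.ndarray = field(repr=False)
    delta_theta_hat: float = np.nan
    uninformative: bool = False
    alpha_choice_index: np.ndarray = field(default=None, repr=False)
    inner_selected_delta: np.ndarray = field(default=None, repr=False)
    participant_id: int = 0

    @property
    def min_error(self) -> float:
        return float(self.error_curve.min())

    def inner_delta_theta_hat(self) -> float:
        """Fully nested estimate: circular mean of the per-fold rotations
        selected on the inner folds alone."""
        rad = np.deg2rad(self.inner_selected_delta)
        return float(wrap_180(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_theta_deg": self.grid, "mse": self.error_curve})

    def summary(self) -> str:
        alphas = self.model.alphas[self.alpha_choice_index] if self.alpha_choice_index is not None else []
        lines = [
            "Coordinate-frame estimate (rotation-model common decoder)",
            "---------------------------------------------------------",
            f"participant            {self.participant_id:>10d}",
            f"estimator              {self.model.estimator:>10}",
            f"grid                   {self.grid[0]:.0f}..{self.grid[-1]:.0f} deg, "
            f"{self.grid.size} points",
            f"outer folds            {self.per_fold_errors.shape[0]:>10d}",
            f"delta_theta_hat        "
            + ("uninformative" if self.uninformative else f"{self.delta_theta_hat:>7.1f} deg"),
            f"min CV error           {self.min_error:>10.4f}",
            f"alpha range chosen     {np.min(alphas):>10.3g} .. {np.max(alphas):.3g}",
        ]
        return "\n".join(lines)

    def plot_error_curve(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.error_curve, **kw)
        if not self.uninformative:
            ax.axvline(self.delta_theta_hat, color="r", ls="-", lw=1)
        ax.set_xlabel("rotation angle $\\Delta\\theta$ (deg)")
        ax.set_ylabel("CV mean squared error")
        return ax


def error_curve(data: TrialDataset, grid=None, **kwargs) -> CoordinateFrameResults:
    """Nested-CV error curve for one participant (functional surface)."""
    return CoordinateFrameModel(data, grid=grid, **kwargs).fit()


def estimate_coordinate_index(grid, curve, flat_tol: float = 1e-12) -> tuple[float, bool]:
    """Grid argmin with the documented tie-breaks.

    Returns ``(delta_theta_hat, uninformative)``.  Ties within numerical
    tolerance of the minimum resolve to the angle closest to the
    extrinsic frame (smallest wrapped magnitude), with the positive angle
    preferred at equal magnitude.  A curve that is flat within
    ``flat_tol`` is flagged uninformative (``delta_theta_hat = nan``).
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if grid.shape != curve.shape:
        raise SizeError("grid and error curve must align")
    scale = max(1.0, float(np.abs(curve).max()))
    if curve.max() - curve.min() <= flat_tol * scale:
        return float("nan"), True
    best = curve.min()
    candidates = wrap_180(grid[curve <= best + flat_tol * scale])
    candidates = np.atleast_1d(candidates)
    order = sorted(candidates, key=lambda a: (abs(a), -np.sign(a)))
    return float(order[0]), False


def fit_participants(data: TrialDataset, **kwargs) -> list[CoordinateFrameResults]:
    """Fit a CoordinateFrameModel per participant in a pooled dataset."""
    return [
        CoordinateFrameModel(data.for_participant(pid), **kwargs).fit()
        for pid in data.participants()
    ]


# ---------------------------------------------------------------------
# group statistics


@dataclass
class GroupFrameResult:
    """Group circular summary of per-participant coordinate indices."""

    summary: CircularSummary
    tests: dict
    estimates: np.ndarray

    @property
    def mean_deg(self) -> float:
        """Group mean coordinate index on (-180, 180]."""
        return float(wrap_180(self.summary.mean_angle))

    @property
    def ci_halfwidth(self) -> float:
        return self.summary.ci_halfwidth

    def summary_text(self) -> str:
        lines = [
            "Group coordinate index",
            "----------------------",
            f"participants        {self.summary.n:>8d}",
            f"mean +/- 95% CI     {self.mean_deg:>8.1f} +/- {self.ci_halfwidth:.1f} deg",
            f"resultant length    {self.summary.resultant_length:>8.3f}",
        ]
        for ref, test in self.tests.items():
            lines.append(f"test vs {ref:>6.1f} deg   p = {test.p_value:.4g}")
        return "\n".join(lines)


def group_coordinate_index(
    per_participant,
    references=(0.0, 90.0),
    confidence: float = 0.95,
    n_boot: int = 10000,
    seed: int = 0,
) -> GroupFrameResult:
    """Circular mean, CI, and one-sample tests of per-participant indices.

    References default to the extrinsic (0 deg) and joint (90 deg)
    frames; pass an empirical muscle angle to test against it as well.
    """
    estimates = np.asarray(per_participant, dtype=float).ravel()
    if estimates.size < 3:
        raise SizeError(f"need at least 3 participants, got {estimates.size}")
    if np.any(~np.isfinite(estimates)):
        raise SizeError("per-participant estimates contain non-finite values")
    summary = circular_mean_ci(estimates, confidence=confidence, n_boot=n_boot, seed=seed)
    tests = {
        float(ref): circular_one_sample_test(estimates, ref, n_boot=n_boot, seed=seed)
        for ref in references
    }
    return GroupFrameResult(summary=summary, tests=tests, estimates=estimates)
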