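"""Epistemic/aleatoric decomposition of GP predictive variance.

The GP predictive variance

    Σ*²(x*) = k(x*,x*) + σ²_test − k(x*,X)[K(X,X)+Σ²_train]⁻¹k(X,x*)

never touches the observations y.  Writing the kernel through its feature
map z(·) (k(x1,x2) = z(x1)·z(x2)) and taking the SVD of Σ⁻¹_train·Z(X) =
U·S·Vᵀ collapses it to a quadratic form plus a constant,

    Σ*²(x*) = z(x*)·V·[I − Sᵀ(SSᵀ+I)⁻¹S]·Vᵀ·z(x*)ᵀ + σ²_test,

with V and S fixed by the training inputs alone: the GP variance is purely
*epistemic* (finite-data) uncertainty plus assumed observation noise.  A
normative model instead needs the *aleatoric* conditional variability
Var(y|x), so a usable total variance is

    Var(y*|x*) = Σ*²(x*) + Σ²_aleatoric(x*),

and z-scores (y − y_reference)/√variance are normalized deviations only
when the denominator tracks Var(y|x).  This module provides the SVD
quadratic form as a numerical oracle, the linear-kernel closed form
x*²/(σ²+1) + σ²_test, a sliding-window estimator of Σ²_aleatoric, the
decomposition itself, and both the fallacious (GP-variance-only) and the
corrected z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import Dataset
from .gpr import GPRegressor
from .kernels import rbf_feature_map_1d

__all__ = [
    "SVDVarianceForm",
    "svd_variance_form",
    "linear_variance_closed_form",
    "AleatoricEstimate",
    "SlidingWindowAleatoric",
    "estimate_aleatoric_sliding_window",
    "NormativeResult",
    "decompose_uncertainty",
    "z_scores",
]


@dataclass
class SVDVarianceForm:
    """Constant matrices of the SVD form of the GP predictive variance.

    ``V`` holds the right singular vectors of Σ⁻¹_train·Z(X) and
    ``shrinkage`` the diagonal of I − Sᵀ(SSᵀ+I)⁻¹S, i.e. 1/(sᵢ²+1) on the
    first min(n, p) entries and 1 beyond; all of it depends only on the
    training inputs, the noise level and the feature map.
    """

    V: np.ndarray
    singular_values: np.ndarray
    shrinkage: np.ndarray
    feature_map: Callable[[float], np.ndarray]
    feature_dimension: int
    sigma2_test: float

    def __call__(self, xstar: float) -> float:
        """Predictive variance at a scalar test input."""
        z = np.asarray(self.feature_map(float(xstar)), dtype=float)
        w = z @ self.V
        quad = float(np.sum(self.shrinkage * w**2))
        return quad + self.sigma2_test

    def evaluate(self, xstars: np.ndarray) -> np.ndarray:
        return np.array([self(x) for x in np.asarray(xstars, dtype=float).ravel()])


def _resolve_feature_map(
    feature_map: str | Callable[[float], np.ndarray],
    length_scale: float,
    order: int,
) -> Callable[[float], np.ndarray]:
    if callable(feature_map):
        return feature_map
    if feature_map == "linear":
        return lambda x: np.array([float(x)])
    if feature_map == "rbf":
        return lambda x: rbf_feature_map_1d(x, length_scale=length_scale, order=order)
    raise ValueError(f"unknown feature map {feature_map!r}")


def svd_variance_form(
    X: np.ndarray,
    feature_map: str | Callable[[float], np.ndarray] = "linear",
    sigma2_train: float = 1.0,
    sigma2_test: float = 0.0,
    length_scale: float = 1.0,
    order: int = 40,
) -> SVDVarianceForm:
    """Build the SVD quadratic form for 1-D training inputs.

    ``feature_map`` is "linear" (identity map, exact), "rbf" (truncated
    series of order ``order``; the truncation error at |x| ≤ π, l = 1,
    J = 40 is below 1e−10) or any callable x → feature vector.

    The evaluator returns z(x*)·V·[I − Sᵀ(SSᵀ+I)⁻¹S]·Vᵀ·z(x*)ᵀ + σ²_test,
    which equals the GP predictive variance for the corresponding kernel.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("SVD variance form is implemented for 1-D inputs")
        X = X[:, 0]
    if X.size == 0:
        raise ValueError("need at least one training input")
    if not sigma2_train > 0:
        raise ValueError("sigma2_train must be positive")
    if sigma2_test < 0:
        raise ValueError("sigma2_test must be >= 0")
    fmap = _resolve_feature_map(feature_map, length_scale, order)
    Z = np.array([fmap(x) for x in X])
    if not np.all(np.isfinite(Z)):
        raise ValueError("feature map produced non-finite values")
    M = Z / np.sqrt(sigma2_train)
    # full matrices: V must span the whole feature space, including the
    # directions the training data never excite (shrinkage 1 there)
    _, s, Vt = np.linalg.svd(M, full_matrices=True)
    p = Z.shape[1]
    shrink = np.ones(p)
    shrink[: s.size] = 1.0 / (s**2 + 1.0)
    return SVDVarianceForm(
        V=Vt.T,
        singular_values=s,
        shrinkage=shrink,
        feature_map=fmap,
        feature_dimension=p,
        sigma2_test=float(sigma2_test),
    )


def linear_variance_closed_form(
    X: np.ndarray, sigma2_train: float, sigma2_test: float, xstar: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form linear-kernel predictive variance x*²/(σ²+1) + σ²_test.

    For 1-D inputs the identity feature map makes Σ⁻¹_train·X a single
    column, whose sole singular value σ = ‖X‖/σ_train turns the SVD form
    into a scalar quadratic.  The global minimum is always at x* = 0 with
    value σ²_test, regardless of the training data — a direct display of the
    output-independence of the GP variance.
    """
    X = np.asarray(X, dtype=float).ravel()
    if not sigma2_train > 0:
        raise ValueError("sigma2_train must be positive")
    sigma2 = float(np.sum(X**2)) / sigma2_train
    xstar = np.asarray(xstar, dtype=float)
    out = xstar**2 / (sigma2 + 1.0) + sigma2_test
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# aleatoric estimation


@dataclass
class AleatoricEstimate:
    """Pointwise aleatoric-variance estimates with reliability flags.

    ``values`` is NaN wherever fewer than ``min_points`` residuals fell in
    the window; those locations are flagged, never extrapolated.
    """

    x: np.ndarray
    values: np.ndarray
    n_in_window: np.ndarray
    reliable: np.ndarray
    window: float
    min_points: int


class SlidingWindowAleatoric(BaseEstimator):
    """Windowed local-variance estimator of Var(y|x) from residuals.

    At each query location x* the estimator takes the sample variance of the
    residuals whose inputs fall in the half-open window
    [x* − w/2, x* + w/2).  Locations with fewer than ``min_points`` residuals
    in the window are flagged unreliable (NaN) rather than estimated:
    sparse-data regions are exactly where a local variance cannot be trusted.

    Parameters
    ----------
    window : float, optional
        Window width w.  Default: (max(x) − min(x)) / 10 at fit time.
    min_points : int, default 20
        Minimum residual count for a reliable estimate.
    """

    def __init__(self, window: float | None = None, min_points: int = 20):
        self.window = window
        self.min_points = min_points

    def fit(self, X: np.ndarray, residuals: np.ndarray) -> "SlidingWindowAleatoric":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("sliding window is implemented for 1-D inputs")
            x = x[:, 0]
        r = np.asarray(residuals, dtype=float).ravel()
        if x.shape[0] != r.shape[0]:
            raise ValueError("X and residuals must have the same length")
        if self.window is not None and not self.window > 0:
            raise ValueError("window must be positive")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2 (sample variance)")
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        r = r[order]
        self.window_ = (
            float(self.window)
            if self.window is not None
            else (self.x_[-1] - self.x_[0]) / 10.0
        )
        if not self.window_ > 0:
            raise ValueError("degenerate input range; supply an explicit window")
        # prefix sums give O(log n) windowed mean/variance queries
        self._cum1 = np.concatenate([[0.0], np.cumsum(r)])
        self._cum2 = np.concatenate([[0.0], np.cumsum(r**2)])
        return self

    def estimate(self, Xstar: np.ndarray) -> AleatoricEstimate:
        if not hasattr(self, "x_"):
            raise RuntimeError("estimator is not fitted")
        xs = np.asarray(Xstar, dtype=float)
        if xs.ndim == 2:
            xs = xs[:, 0]
        xs = xs.ravel()
        half = self.window_ / 2.0
        lo = np.searchsorted(self.x_, xs - half, side="left")
        hi = np.searchsorted(self.x_, xs + half, side="left")  # half-open right edge
        m = (hi - lo).astype(float)
        s1 = self._cum1[hi] - self._cum1[lo]
        s2 = self._cum2[hi] - self._cum2[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (s2 - s1**2 / m) / (m - 1.0)
        var = np.maximum(var, 0.0)
        reliable = m >= self.min_points
        var[~reliable] = np.nan
        return AleatoricEstimate(
            x=xs,
            values=var,
            n_in_window=(hi - lo),
            reliable=reliable,
            window=self.window_,
            min_points=self.min_points,
        )

    def predict(self, Xstar: np.ndarray) -> np.ndarray:
        """Variance estimates only (NaN where unreliable)."""
        return self.estimate(Xstar).values


def estimate_aleatoric_sliding_window(
    data: Dataset,
    reference_predictions: np.ndarray | None,
    Xstar: np.ndarray,
    window: float | None = None,
    min_points: int = 20,
) -> AleatoricEstimate:
    """Sliding-window Σ²_aleatoric from a dataset and a reference model.

    ``reference_predictions`` are the reference-model values at the training
    inputs (defaults to the dataset's true reference function); residuals
    y − y_reference feed the windowed variance.
    """
    if reference_predictions is None:
        reference_predictions = data.reference_values()
    residuals = data.y - np.asarray(reference_predictions, dtype=float).ravel()
    est = SlidingWindowAleatoric(window=window, min_points=min_points)
    est.fit(data.X, residuals)
    return est.estimate(Xstar)


# ---------------------------------------------------------------------------
# decomposition and z-scores


@dataclass
class NormativeResult:
    """Pointwise variance decomposition and z-scores at scored locations."""

    x: np.ndarray
    y: np.ndarray | None
    y_reference: np.ndarray
    epistemic_var: np.ndarray
    aleatoric_var: np.ndarray
    total_var: np.ndarray
    residuals: np.ndarray | None
    z_gpr_only: np.ndarray | None
    z_corrected: np.ndarray | None
    unreliable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = self.x.shape[0]
        nan = np.full(n, np.nan)
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y if self.y is not None else nan,
                "y_reference": self.y_reference,
                "epistemic_var": self.epistemic_var,
                "aleatoric_var": self.aleatoric_var,
                "total_var": self.total_var,
                "z_gpr_only": self.z_gpr_only if self.z_gpr_only is not None else nan,
                "z_corrected": (
                    self.z_corrected if self.z_corrected is not None else nan
                ),
                "unreliable_flag": self.unreliable.astype(int),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def decompose_uncertainty(
    model: GPRegressor,
    Xstar: np.ndarray,
    aleatoric: AleatoricEstimate | None,
    y: np.ndarray | None = None,
    include_test_noise: bool = True,
) -> NormativeResult:
    """Split predictive uncertainty into epistemic and aleatoric parts.

    The epistemic part is the GP predictive variance at ``Xstar``;
    ``include_test_noise`` controls whether the assumed test-noise σ²_test
    (and any white kernel component) is counted inside it.  Keep the default
    when the noise level is known and genuinely an observation-noise floor;
    set it to False when the noise variance was *optimized*, because the
    likelihood biases it toward the overall residual variance — a global
    aleatoric estimate — and counting it as epistemic would double-count the
    very quantity Σ²_aleatoric measures.

    total_var = epistemic + aleatoric pointwise; with a zero aleatoric term
    and the default flag, total_var equals the GP predictive variance
    exactly.  If ``y`` is given, residuals against the fitted reference
    (posterior mean) and both z-score variants are attached.
    """
    Xs = np.asarray(Xstar, dtype=float)
    if Xs.ndim == 1:
        Xs = Xs[:, None]
    epistemic = model.predict_var(Xs, include_noise=include_test_noise)
    if aleatoric is None:
        aleatoric_var = np.zeros(Xs.shape[0])
        unreliable = np.zeros(Xs.shape[0], dtype=bool)
    else:
        aleatoric_var = np.asarray(aleatoric.values, dtype=float)
        if aleatoric_var.shape[0] != Xs.shape[0]:
            raise ValueError("aleatoric estimate does not cover Xstar")
        finite = aleatoric_var[np.isfinite(aleatoric_var)]
        if np.any(finite < 0):
            raise ValueError("negative aleatoric variance estimate (estimator bug)")
        unreliable = ~np.asarray(aleatoric.reliable, dtype=bool)
    total = epistemic + aleatoric_var
    y_reference = model.predict(Xs)

    residuals = z_gpr = z_corr = None
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != Xs.shape[0]:
            raise ValueError("y must align with Xstar")
        residuals = y - y_reference
        gpr_var = model.predict_var(Xs, include_noise=True)
        if np.any(gpr_var <= 0):
            raise ZeroDivisionError("GP predictive variance vanishes at scored points")
        z_gpr = residuals / np.sqrt(gpr_var)
        with np.errstate(invalid="ignore", divide="ignore"):
            z_corr = residuals / np.sqrt(total)
        z_corr = np.where(total > 0, z_corr, np.nan)
    return NormativeResult(
        x=Xs[:, 0] if Xs.shape[1] == 1 else Xs,
        y=y,
        y_reference=y_reference,
        epistemic_var=epistemic,
        aleatoric_var=aleatoric_var,
        total_var=total,
        residuals=residuals,
        z_gpr_only=z_gpr,
        z_corrected=z_corr,
        unreliable=unreliable,
    )


def z_scores(result: NormativeResult, use: str = "decomposed_total") -> np.ndarray:
    """Extract z-scores from a decomposition.

    ``use="gpr_variance_only"`` normalizes residuals by the raw GP predictive
    standard deviation — the fallacy under study, reproduced deliberately.
    ``use="decomposed_total"`` uses the epistemic + aleatoric total, the
    corrected normative score.
    """
    if result.residuals is None:
        raise ValueError("result carries no observations; refit with y")
    if use == "gpr_variance_only":
        return result.z_gpr_only
    if use == "decomposed_total":
        if np.any(result.total_var[~result.unreliable] <= 0):
            raise ZeroDivisionError("total variance vanishes at scored points")
        return result.z_corrected
    raise ValueError(f"unknown z-score mode {use!r}")
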