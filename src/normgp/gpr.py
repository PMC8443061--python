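"""Exact Gaussian process regression with explicit noise handling.

:class:`GPRegressor` is a scikit-learn style estimator implementing the
standard zero-mean GP posterior.  With training inputs X, observations y,
kernel k and observation-noise variance σ², the predictive distribution at
test inputs X* is Gaussian with

    μ*  = K(X*,X) [K(X,X) + σ²I]⁻¹ y
    Σ*² = K(X*,X*) + σ²I − K(X*,X) [K(X,X) + σ²I]⁻¹ K(X,X*)

The predictive variance Σ*² depends on y in no way: it is a function of the
kernel and of the training-input locations only, i.e. it quantifies
*epistemic* uncertainty (plus the assumed observation noise), not the
conditional variability Var(y|x) of the outcome.  The variance-decomposition
module builds on this fact.

Hyperparameters (kernel weights, length scale, noise variance) can be tuned
by maximizing the log marginal likelihood log N(y; 0, K(X,X) + σ²I) with a
multi-restart quasi-Newton search in log-parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import optimize as sopt
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import Dataset
from .kernels import RBF, HybridKernel, Kernel

__all__ = [
    "GPRegressor",
    "OptimizationRecord",
    "OptimizationResult",
    "fit",
    "predict_mean",
    "predict_var",
    "log_marginal_likelihood",
    "optimize_hyperparameters",
    "DEFAULT_BOUNDS",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# log-uniform search boxes for free hyperparameters; wide on purpose so the
# optimizer can drive kernel weights toward ~0 when the data ask for it
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "w_linear": (1e-8, 1e2),
    "w_rbf": (1e-8, 1e2),
    "length_scale": (1e-8, 1e2),
    "noise_variance": (1e-4, 1e2),
}


def _chol_with_jitter(Ky: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor with escalating diagonal jitter.

    Jitter starts at 1e-12·mean(diag) and doubles up to 1e-6·mean(diag);
    failure past that signals a genuinely ill-conditioned kernel/noise
    combination.
    """
    base = float(np.mean(np.diag(Ky)))
    if base <= 0.0:
        base = 1.0
    jitter = 0.0
    step = 1e-12 * base
    limit = 1e-6 * base
    n = Ky.shape[0]
    while True:
        try:
            L = sla.cholesky(Ky + jitter * np.eye(n), lower=True)
            return L, jitter
        except sla.LinAlgError:
            if jitter == 0.0:
                jitter = step
            else:
                jitter *= 2.0
            if jitter > limit:
                raise np.linalg.LinAlgError(
                    "covariance matrix not positive definite even after "
                    f"jitter escalation to {jitter:.3e}; "
                    "ill-conditioned kernel/noise combination"
                )


class GPRegressor(RegressorMixin, BaseEstimator):
    """Exact GP regression with optional marginal-likelihood optimization.

    Parameters
    ----------
    kernel : Kernel, default RBF(length_scale=1.0)
        Covariance function.  White-noise components inside the kernel
        contribute to the self-covariance diagonal of both the training and
        the test block, and zero to the cross blocks.
    noise_variance : float, default 0.0
        Known observation-noise variance σ², added to the training-covariance
        diagonal and (by the identical-noise assumption) to the predictive
        variance.  Use 0 when the kernel itself carries a white component.
    optimizer : {None, "multistart"}, default None
        If "multistart", ``free_params`` of the kernel are tuned by
        multi-restart L-BFGS-B on the log marginal likelihood.
    free_params : sequence of str, optional
        Kernel parameter names to optimize; defaults to all parameters of a
        :class:`~normgp.kernels.HybridKernel`, else the kernel's full
        parameter list.
    bounds : dict, optional
        Per-parameter (low, high) search boxes; merged over DEFAULT_BOUNDS.
    n_restarts : int, default 10
    random_state : int, optional
        Seed for restart initialization.

    Attributes
    ----------
    kernel_ : fitted (possibly optimized) kernel clone.
    X_train_, y_train_ : training data.
    L_ : lower Cholesky factor of K(X,X) + σ²I (+ jitter).
    alpha_ : [K(X,X)+σ²I]⁻¹ y.
    jitter_ : jitter actually used.
    log_marginal_likelihood_value_ : log p(y|X, θ) at the fitted kernel.
    optimization_result_ : per-restart audit trail (when optimizer is set).
    """

    def __init__(
        self,
        kernel: Kernel | None = None,
        noise_variance: float = 0.0,
        optimizer: str | None = None,
        free_params: Sequence[str] | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.kernel = kernel
        self.noise_variance = noise_variance
        self.optimizer = optimizer
        self.free_params = free_params
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPRegressor":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if float(self.noise_variance) < 0:
            raise ValueError("noise_variance must be >= 0")
        kernel = (self.kernel if self.kernel is not None else RBF(1.0)).clone()

        if self.optimizer is not None:
            if self.optimizer != "multistart":
                raise ValueError(f"unknown optimizer {self.optimizer!r}")
            result = optimize_hyperparameters(
                Dataset(X=X, y=y),
                kernel,
                free_params=self.free_params,
                bounds=self.bounds,
                restarts=self.n_restarts,
                seed=0 if self.random_state is None else int(self.random_state),
                noise_variance=float(self.noise_variance),
            )
            kernel = result.kernel
            self.optimization_result_ = result

        Ky = kernel(X, X, identical=True) + float(self.noise_variance) * np.eye(
            X.shape[0]
        )
        L, jitter = _chol_with_jitter(Ky)
        self.kernel_ = kernel
        self.X_train_ = X
        self.y_train_ = y
        self.L_ = L
        self.jitter_ = jitter
        self.alpha_ = sla.cho_solve((L, True), y)
        n = X.shape[0]
        self.log_marginal_likelihood_value_ = float(
            -0.5 * y @ self.alpha_ - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG_2PI
        )
        return self

    # -- prediction -------------------------------------------------------

    def _check_fitted_X(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "L_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"input dimension mismatch: {X.shape[1]} vs {self.X_train_.shape[1]}"
            )
        return X

    def predict(
        self,
        X: np.ndarray,
        return_std: bool = False,
        return_var: bool = False,
    ):
        """Posterior mean, optionally with predictive std/variance.

        The returned variance is the full predictive variance of an
        observation, including the assumed test-noise σ² (and any white
        kernel component): the quantity a naive normative pipeline would
        divide residuals by.
        """
        X = self._check_fitted_X(X)
        Ks = self.kernel_(X, self.X_train_, identical=False)
        mean = Ks @ self.alpha_
        if not (return_std or return_var):
            return mean
        var = self.predict_var(X)
        if return_var:
            return mean, var
        return mean, np.sqrt(var)

    def predict_var(self, X: np.ndarray, include_noise: bool = True) -> np.ndarray:
        """Diagonal of the posterior predictive covariance.

        ``include_noise=False`` drops the test-noise contribution — both the
        explicit ``noise_variance`` and any white component of the kernel —
        leaving the kernel-only epistemic term
        K(X*,X*) − K(X*,X)[K(X,X)+σ²I]⁻¹K(X,X*).
        """
        X = self._check_fitted_X(X)
        Ks = self.kernel_(X, self.X_train_, identical=False)
        prior = np.array(
            [
                self.kernel_.eval(row, row, identical=include_noise)
                for row in X
            ]
        )
        if include_noise:
            prior = prior + float(self.noise_variance)
        v = sla.solve_triangular(self.L_, Ks.T, lower=True)
        var = prior - np.sum(v**2, axis=0)
        # numerically tiny negatives from cancellation are clipped
        return np.maximum(var, 0.0)


# ---------------------------------------------------------------------------
# marginal likelihood and optimization


@dataclass
class OptimizationRecord:
    """One restart of the likelihood search."""

    theta0: dict[str, float]
    theta: dict[str, float]
    log_likelihood: float
    success: bool
    message: str = ""


@dataclass
class OptimizationResult:
    """Best-of-restarts maximizer with a full audit trail."""

    kernel: Kernel
    theta: dict[str, float]
    log_likelihood: float
    records: list[OptimizationRecord] = field(default_factory=list)


def _lml_from_cov(Ky: np.ndarray, y: np.ndarray) -> float:
    """log N(y; 0, Ky); −inf if Ky is not positive definite."""
    try:
        L, _ = _chol_with_jitter(Ky)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = sla.cho_solve((L, True), y)
    n = y.shape[0]
    return float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG_2PI)


def log_marginal_likelihood(
    data: Dataset,
    kernel: Kernel,
    theta: dict[str, float] | None = None,
    noise_variance: float = 0.0,
) -> float:
    """log p(y | X, θ) under the zero-mean GP prior plus noise.

    ``theta`` optionally overrides kernel parameters (by name) before
    evaluation; the kernel object passed in is not mutated.
    """
    k = kernel.clone()
    if theta:
        k.set_params(**theta)
    X = data.X
    Ky = k(X, X, identical=True) + float(noise_variance) * np.eye(X.shape[0])
    return _lml_from_cov(Ky, data.y)


def _hybrid_objective(X: np.ndarray, y: np.ndarray, free: list[str], template: HybridKernel,
                      noise_variance: float):
    """Negative LML over log-parameters, with cached Gram building blocks."""
    G_lin = X @ X.T
    sq = np.sum(X**2, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * G_lin, 0.0)
    n = X.shape[0]
    eye = np.eye(n)
    fixed = template.get_params()

    def neg_lml(log_theta: np.ndarray) -> float:
        p = dict(fixed)
        p.update({name: float(np.exp(v)) for name, v in zip(free, log_theta)})
        Ky = (
            p["w_linear"] * G_lin
            + p["w_rbf"] * np.exp(-D2 / (2.0 * p["length_scale"] ** 2))
            + (p["noise_variance"] + noise_variance) * eye
        )
        return -_lml_from_cov(Ky, y)

    return neg_lml


def _generic_objective(X: np.ndarray, y: np.ndarray, free: list[str], template: Kernel,
                       noise_variance: float):
    k = template.clone()
    n = X.shape[0]
    eye = np.eye(n)

    def neg_lml(log_theta: np.ndarray) -> float:
        k.set_params(**{name: float(np.exp(v)) for name, v in zip(free, log_theta)})
        Ky = k(X, X, identical=True) + noise_variance * eye
        return -_lml_from_cov(Ky, y)

    return neg_lml


def optimize_hyperparameters(
    data: Dataset,
    template: Kernel,
    free_params: Sequence[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    restarts: int = 10,
    seed: int = 0,
    noise_variance: float = 0.0,
    tie_tol: float = 3.0,
) -> OptimizationResult:
    """Maximize the log marginal likelihood by multi-restart L-BFGS-B.

    All free parameters are optimized in log space with box bounds
    (:data:`DEFAULT_BOUNDS` unless overridden).  The first restart starts at
    the template's own parameter values (clipped into the box); the rest are
    drawn log-uniformly, seeded.  Every restart is recorded for audit.

    The hybrid-kernel likelihood has an exact degeneracy: an RBF component
    whose length scale collapses below the input spacing is indistinguishable
    from white noise, so the observed variance splits arbitrarily between
    w_rbf and the noise term along a likelihood-flat ridge.  Restarts whose
    achieved log-likelihood lies within ``tie_tol`` nats of the maximum are
    therefore treated as likelihood-equivalent, and among them the most
    parsimonious solution — smallest total kernel weight (parameters named
    ``w_*``) — is returned, attributing the ambiguous variance to the
    observation-noise hyperparameter, which is the interpretable estimate.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if free_params is None:
        free_params = list(template._param_names)
    free = list(free_params)
    missing = [p for p in free if p not in template._param_names]
    if missing:
        raise ValueError(f"template has no parameters {missing}")
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    lo = np.array([np.log(box.get(p, (1e-8, 1e2))[0]) for p in free])
    hi = np.array([np.log(box.get(p, (1e-8, 1e2))[1]) for p in free])

    X = data.X
    y = data.y
    if isinstance(template, HybridKernel):
        neg_lml = _hybrid_objective(X, y, free, template, float(noise_variance))
    else:
        neg_lml = _generic_objective(X, y, free, template, float(noise_variance))

    rng = np.random.default_rng(int(seed))
    t0 = np.clip(
        np.log([max(float(template.get_params()[p]), 1e-300) for p in free]), lo, hi
    )
    starts = [t0] + [rng.uniform(lo, hi) for _ in range(restarts - 1)]

    records: list[OptimizationRecord] = []
    best: tuple[float, np.ndarray] | None = None
    for start in starts:
        res = sopt.minimize(
            neg_lml,
            start,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
        )
        ll = -float(res.fun) if np.isfinite(res.fun) else -np.inf
        theta = {p: float(np.exp(v)) for p, v in zip(free, res.x)}
        records.append(
            OptimizationRecord(
                theta0={p: float(np.exp(v)) for p, v in zip(free, start)},
                theta=theta,
                log_likelihood=ll,
                success=bool(res.success) and np.isfinite(ll),
                message=str(res.message),
            )
        )
        if np.isfinite(ll) and (best is None or ll > best[0]):
            best = (ll, res.x)
    if best is None:
        raise RuntimeError(
            "all likelihood-optimization restarts failed; records: "
            + "; ".join(r.message for r in records)
        )
    best_ll = best[0]
    weight_names = [p for p in free if p.startswith("w_")]
    ties = [r for r in records if r.log_likelihood >= best_ll - float(tie_tol)]
    if weight_names and ties:
        chosen = min(ties, key=lambda r: sum(r.theta[p] for p in weight_names))
    else:
        chosen = max(records, key=lambda r: r.log_likelihood)
    ll = chosen.log_likelihood
    theta_hat = dict(chosen.theta)
    kernel = template.clone().set_params(**theta_hat)
    return OptimizationResult(
        kernel=kernel, theta=theta_hat, log_likelihood=ll, records=records
    )


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator


def fit(data: Dataset, kernel: Kernel, noise_variance: float = 0.0) -> GPRegressor:
    """Fit an exact GP posterior on a dataset with a fixed kernel."""
    return GPRegressor(kernel=kernel, noise_variance=noise_variance).fit(
        data.X, data.y
    )


def predict_mean(model: GPRegressor, Xstar: np.ndarray) -> np.ndarray:
    """Posterior mean μ* at test inputs."""
    return model.predict(Xstar)


def predict_var(
    model: GPRegressor, Xstar: np.ndarray, include_noise: bool = True
) -> np.ndarray:
    """Posterior predictive variance Σ*² (diagonal) at test inputs."""
    return model.predict_var(Xstar, include_noise=include_noise)
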