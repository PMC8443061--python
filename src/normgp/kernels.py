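"""Covariance functions for Gaussian process regression.

Kernels are lightweight parameterized callables in the style of
:mod:`sklearn.gaussian_process.kernels`: ``k(X1, X2)`` returns the Gram
matrix, ``k.eval(x1, x2)`` a single covariance.  The white-noise kernel is
special: identically-distributed observation noise contributes only to the
self-covariance of a set of points, never to the cross-covariance between
training and test blocks.  Point identity cannot be decided robustly from
floating-point coordinates, so it is declared by the caller through the
``identical`` flag of :meth:`Kernel.__call__` rather than inferred.

The explicit (truncated) feature map of the RBF kernel,
:func:`rbf_feature_map_1d`, is provided as a verification oracle: the inner
product of two feature vectors converges to the kernel value as the
truncation order grows.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Any

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv as bessel_kv

__all__ = [
    "Kernel",
    "Linear",
    "RBF",
    "Matern",
    "RationalQuadratic",
    "White",
    "WeightedSum",
    "HybridKernel",
    "eval_kernel",
    "gram",
    "rbf_feature_map_1d",
    "kernel_to_dict",
    "kernel_from_dict",
]


def _as_2d(X: Any) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"expected 2-D input array, got ndim={X.ndim}")
    return X


def _check_pair(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X1, X2 = _as_2d(X1), _as_2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"input dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    return X1, X2


def _sq_dists(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0."""
    d = (
        np.sum(X1**2, axis=1)[:, None]
        + np.sum(X2**2, axis=1)[None, :]
        - 2.0 * X1 @ X2.T
    )
    return np.maximum(d, 0.0)


class Kernel(ABC):
    """Base covariance function.

    Subclasses declare their constructor parameters in ``_param_names``;
    ``get_params``/``set_params``/``clone`` follow the sklearn protocol so
    kernels compose with estimator cloning and hyperparameter search.
    """

    _param_names: tuple[str, ...] = ()

    @abstractmethod
    def __call__(
        self, X1: np.ndarray, X2: np.ndarray, identical: bool = False
    ) -> np.ndarray:
        """Gram matrix K(X1, X2).

        ``identical=True`` declares that X1 and X2 are the *same set* of
        points (by identity, not coordinates), activating diagonal
        white-noise contributions.
        """

    def eval(self, x1: Any, x2: Any, identical: bool = False) -> float:
        """Covariance of a single input pair."""
        x1 = np.atleast_1d(np.asarray(x1, dtype=float))
        x2 = np.atleast_1d(np.asarray(x2, dtype=float))
        if x1.shape != x2.shape:
            raise ValueError(f"input dimension mismatch: {x1.shape} vs {x2.shape}")
        return float(self(x1[None, :], x2[None, :], identical=identical)[0, 0])

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params: Any) -> "Kernel":
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r} for {type(self).__name__}")
            setattr(self, name, value)
        self._validate()
        return self

    def clone(self) -> "Kernel":
        return type(self)(**self.get_params())

    def _validate(self) -> None:  # overridden where there is something to check
        pass

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


class Linear(Kernel):
    """Dot-product kernel k(x1, x2) = x1·x2.

    Non-stationary; the feature map is the identity, so the induced
    regression surface is a hyperplane through the origin.
    """

    _param_names = ()

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        return X1 @ X2.T


class RBF(Kernel):
    """Squared-exponential kernel exp(-||x1-x2||² / (2 l²))."""

    _param_names = ("length_scale",)

    def __init__(self, length_scale: float = 1.0):
        self.length_scale = length_scale
        self._validate()

    def _validate(self):
        _check_positive("length_scale", self.length_scale)

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        return np.exp(-_sq_dists(X1, X2) / (2.0 * self.length_scale**2))


class Matern(Kernel):
    """Matérn kernel with smoothness ``nu`` and length scale ``l``.

    Closed forms are used for nu in {0.5, 1.5, 2.5}; the general
    gamma/Bessel expression otherwise.  The r=0 value is pinned to the
    limit 1 to avoid the 0·inf indeterminacy of the Bessel form.
    """

    _param_names = ("length_scale", "nu")

    def __init__(self, length_scale: float = 1.0, nu: float = 1.5):
        self.length_scale = length_scale
        self.nu = nu
        self._validate()

    def _validate(self):
        _check_positive("length_scale", self.length_scale)
        _check_positive("nu", self.nu)

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        r = np.sqrt(_sq_dists(X1, X2)) / self.length_scale
        nu = self.nu
        if nu == 0.5:
            return np.exp(-r)
        if nu == 1.5:
            s = math.sqrt(3.0) * r
            return (1.0 + s) * np.exp(-s)
        if nu == 2.5:
            s = math.sqrt(5.0) * r
            return (1.0 + s + s**2 / 3.0) * np.exp(-s)
        s = math.sqrt(2.0 * nu) * r
        with np.errstate(invalid="ignore", over="ignore"):
            K = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * s**nu * bessel_kv(nu, s)
        K = np.where(s == 0.0, 1.0, K)
        # kv underflows to 0 and s**nu overflows for large nu; the product
        # tends to the RBF value, but NaNs from 0*inf must be cleaned up.
        return np.nan_to_num(K, nan=1.0, posinf=1.0)


class RationalQuadratic(Kernel):
    """(1 + ||x1-x2||²/(2 α l²))^{-α}: a scale mixture of RBF kernels."""

    _param_names = ("length_scale", "alpha")

    def __init__(self, length_scale: float = 1.0, alpha: float = 1.0):
        self.length_scale = length_scale
        self.alpha = alpha
        self._validate()

    def _validate(self):
        _check_positive("length_scale", self.length_scale)
        _check_positive("alpha", self.alpha)

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        d2 = _sq_dists(X1, X2)
        return (1.0 + d2 / (2.0 * self.alpha * self.length_scale**2)) ** (-self.alpha)


class White(Kernel):
    """IID observation-noise kernel.

    Contributes ``noise_variance`` on the diagonal of the self-covariance of
    a point set and zero everywhere else; in particular the train/test
    cross-covariance blocks are exactly zero.
    """

    _param_names = ("noise_variance",)

    def __init__(self, noise_variance: float = 1.0):
        self.noise_variance = noise_variance
        self._validate()

    def _validate(self):
        if float(self.noise_variance) < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        K = np.zeros((X1.shape[0], X2.shape[0]))
        if identical:
            if X1.shape[0] != X2.shape[0]:
                raise ValueError("identical=True requires equally sized point sets")
            np.fill_diagonal(K, self.noise_variance)
        return K

    def eval(self, x1, x2, identical=False):
        return float(self.noise_variance) if identical else 0.0


class WeightedSum(Kernel):
    """Non-negatively weighted sum of kernels; itself a valid kernel."""

    _param_names = ("components",)

    def __init__(self, components: list[tuple[float, Kernel]]):
        self.components = list(components)
        self._validate()

    def _validate(self):
        if not self.components:
            raise ValueError("weighted sum needs at least one component")
        for w, k in self.components:
            if float(w) < 0:
                raise ValueError(f"component weight must be >= 0, got {w}")
            if not isinstance(k, Kernel):
                raise TypeError(f"component {k!r} is not a Kernel")

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        K = np.zeros((X1.shape[0], X2.shape[0]))
        for w, k in self.components:
            K += float(w) * k(X1, X2, identical=identical)
        return K

    def eval(self, x1, x2, identical=False):
        return float(
            sum(float(w) * k.eval(x1, x2, identical=identical) for w, k in self.components)
        )

    def clone(self):
        return WeightedSum([(w, k.clone()) for w, k in self.components])


class HybridKernel(Kernel):
    """Weighted linear + RBF + white-noise kernel.

    k(·,·) = w_linear·k_lin + w_rbf·k_RBF(l) + k_white(σ²_noise)

    This is the kernel used when the observation-noise level is unknown and
    treated as a hyperparameter: the white component carries the noise, so
    the GP covariance of the observations is the hybrid Gram matrix alone.
    All four parameters can be freed for marginal-likelihood optimization.
    """

    _param_names = ("w_linear", "w_rbf", "length_scale", "noise_variance")

    def __init__(
        self,
        w_linear: float = 1.0,
        w_rbf: float = 1.0,
        length_scale: float = 1.0,
        noise_variance: float = 1.0,
    ):
        self.w_linear = w_linear
        self.w_rbf = w_rbf
        self.length_scale = length_scale
        self.noise_variance = noise_variance
        self._validate()

    def _validate(self):
        if float(self.w_linear) < 0 or float(self.w_rbf) < 0:
            raise ValueError("kernel weights must be >= 0")
        _check_positive("length_scale", self.length_scale)
        if float(self.noise_variance) < 0:
            raise ValueError("noise_variance must be >= 0")

    def __call__(self, X1, X2, identical=False):
        X1, X2 = _check_pair(X1, X2)
        K = self.w_linear * (X1 @ X2.T) + self.w_rbf * np.exp(
            -_sq_dists(X1, X2) / (2.0 * self.length_scale**2)
        )
        if identical:
            K[np.diag_indices(min(K.shape))] += self.noise_variance
        return K

    def eval(self, x1, x2, identical=False):
        base = self.w_linear * float(np.dot(np.atleast_1d(x1), np.atleast_1d(x2)))
        r2 = float(np.sum((np.atleast_1d(x1) - np.atleast_1d(x2)) ** 2))
        base += self.w_rbf * math.exp(-r2 / (2.0 * self.length_scale**2))
        if identical:
            base += self.noise_variance
        return base


# ---------------------------------------------------------------------------
# functional surface


def eval_kernel(kernel: Kernel, x1, x2, identical: bool = False) -> float:
    """Evaluate ``kernel`` on a single pair of input vectors."""
    return kernel.eval(x1, x2, identical=identical)


def gram(kernel: Kernel, X1, X2, identical: bool = False) -> np.ndarray:
    """Gram matrix with entry (i, j) = k(X1[i], X2[j])."""
    return kernel(X1, X2, identical=identical)


def rbf_feature_map_1d(x: float, length_scale: float = 1.0, order: int = 40) -> np.ndarray:
    """Truncated explicit feature map of the 1-D RBF kernel.

    Component j (j = 0..order) is

        z_j(x) = exp(-x²/(2l²)) · x^j / (l^j √(j!)),

    the exponential-series factorization of exp(-(x1-x2)²/(2l²)): the inner
    product Σ_j z_j(x1) z_j(x2) converges to the RBF kernel value as the
    truncation order grows (the remainder is the tail of exp(x1·x2/l²)).

    Parameters
    ----------
    x : scalar input.
    length_scale : RBF length scale l.
    order : truncation order J; the returned vector has J+1 components.
    """
    from scipy.special import gammaln

    order = int(order)
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    length_scale = _check_positive("length_scale", length_scale)
    x = float(x)
    j = np.arange(order + 1)
    if x == 0.0:
        z = np.zeros(order + 1)
        z[0] = 1.0
        return z
    # log-space for the factorial to stay finite at large J
    log_mag = j * math.log(abs(x) / length_scale) - 0.5 * gammaln(j + 1)
    sign = np.where(j % 2 == 1, math.copysign(1.0, x), 1.0)
    return sign * np.exp(log_mag - x**2 / (2.0 * length_scale**2))


# ---------------------------------------------------------------------------
# serialization

_KERNEL_KINDS: dict[str, type[Kernel]] = {
    "linear": Linear,
    "rbf": RBF,
    "matern": Matern,
    "rational_quadratic": RationalQuadratic,
    "white": White,
    "weighted_sum": WeightedSum,
    "hybrid": HybridKernel,
}
_KIND_BY_TYPE = {v: k for k, v in _KERNEL_KINDS.items()}


def kernel_to_dict(kernel: Kernel) -> dict[str, Any]:
    """Serialize a kernel to a plain dict (YAML/JSON-safe)."""
    kind = _KIND_BY_TYPE[type(kernel)]
    if isinstance(kernel, WeightedSum):
        return {
            "kind": kind,
            "components": [
                {"weight": float(w), "kernel": kernel_to_dict(k)}
                for w, k in kernel.components
            ],
        }
    return {"kind": kind, **{k: float(v) for k, v in kernel.get_params().items()}}


def kernel_from_dict(spec: dict[str, Any]) -> Kernel:
    """Inverse of :func:`kernel_to_dict`."""
    spec = dict(spec)
    kind = spec.pop("kind")
    if kind not in _KERNEL_KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}")
    cls = _KERNEL_KINDS[kind]
    if cls is WeightedSum:
        comps = [
            (float(c["weight"]), kernel_from_dict(c["kernel"]))
            for c in spec.pop("components")
        ]
        if spec:
            raise ValueError(f"unexpected keys {sorted(spec)} for weighted_sum")
        return WeightedSum(comps)
    return cls(**spec)
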