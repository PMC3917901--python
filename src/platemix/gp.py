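"""Gaussian-process regression with fixed per-point (heteroscedastic) noise.

This is the inference engine behind every smoothing and interpolation step of
the pipeline: media baselines (squared-exponential kernel), the OD-to-density
calibration (squared-exponential + linear), and the autofluorescence emission
ratio as a function of OD (neural-network kernel, whose prior samples are
sigmoid-like).

The model is a zero-mean GP observed through additive Gaussian noise,

    y_i = f(x_i) + eps_i,   eps_i ~ N(0, s_i^2),

with the noise standard deviations ``s_i`` either supplied per point (from an
empirical nearest-neighbour estimate, :func:`empirical_noise`), learned as a
single constant, or learned as a scale factor on a supplied relative profile.
Hyperparameters are chosen by maximizing the log marginal likelihood

    log p(y | x, theta) = -1/2 y^T K_y^{-1} y - 1/2 log|K_y| - n/2 log(2 pi),

with K_y = K + diag(s^2), optimized in log-hyperparameter space with a
truncated Newton method (scipy TNC) plus seeded random restarts. The exact
posterior mean/covariance at query points supports interpolation, pointwise
error bars, and joint sampling of whole functions.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .errors import FitError, NumericalError

_LOG2PI = np.log(2.0 * np.pi)

#: Relative jitter ladder: multiples of the mean covariance diagonal added
#: before Cholesky factorization, escalating until success.
_JITTERS = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)


# --------------------------------------------------------------------------
# Kernels
# --------------------------------------------------------------------------

class Kernel(ABC):
    """Covariance function with log-space hyperparameter access."""

    names: tuple[str, ...]

    @abstractmethod
    def __call__(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Covariance matrix between column inputs x1 (n,) and x2 (m,)."""

    @property
    @abstractmethod
    def theta(self) -> np.ndarray:
        """Hyperparameters in log space (flat vector)."""

    @theta.setter
    @abstractmethod
    def theta(self, value: np.ndarray) -> None: ...

    @abstractmethod
    def clone(self) -> "Kernel": ...

    @property
    def hyperparams(self) -> dict[str, float]:
        return dict(zip(self.names, np.exp(self.theta)))

    def __add__(self, other: "Kernel") -> "Sum":
        return Sum(self, other)


class SquaredExponential(Kernel):
    """k(x, x') = amplitude^2 exp(-(x - x')^2 / (2 lengthscale^2)).

    Prior samples fluctuate smoothly on the scale of ``lengthscale``.
    """

    names = ("amplitude", "lengthscale")

    def __init__(self, amplitude: float = 1.0, lengthscale: float = 1.0):
        if amplitude <= 0 or lengthscale <= 0:
            raise ValueError("kernel hyperparameters must be strictly positive")
        self.amplitude = float(amplitude)
        self.lengthscale = float(lengthscale)

    def __call__(self, x1, x2):
        d = np.subtract.outer(np.asarray(x1, float), np.asarray(x2, float))
        return self.amplitude**2 * np.exp(-0.5 * (d / self.lengthscale) ** 2)

    @property
    def theta(self):
        return np.log([self.amplitude, self.lengthscale])

    @theta.setter
    def theta(self, value):
        self.amplitude, self.lengthscale = np.exp(value)

    def clone(self):
        return SquaredExponential(self.amplitude, self.lengthscale)


class Linear(Kernel):
    """k(x, x') = variance * x * x'  (prior over straight lines through 0)."""

    names = ("variance",)

    def __init__(self, variance: float = 1.0):
        if variance <= 0:
            raise ValueError("kernel hyperparameters must be strictly positive")
        self.variance = float(variance)

    def __call__(self, x1, x2):
        return self.variance * np.outer(np.asarray(x1, float), np.asarray(x2, float))

    @property
    def theta(self):
        return np.log([self.variance])

    @theta.setter
    def theta(self, value):
        (self.variance,) = np.exp(value)

    def clone(self):
        return Linear(self.variance)


class NeuralNetwork(Kernel):
    """Arcsine (one-hidden-layer network limit) covariance, Williams form:

        k(x,x') = amplitude^2 * (2/pi) *
                  asin( 2 (s0^2 + s1^2 x x') /
                        sqrt((1 + 2 (s0^2 + s1^2 x^2)) (1 + 2 (s0^2 + s1^2 x'^2))) )

    with ``bias_scale`` = s0 and ``input_scale`` = s1. Prior samples are
    sigmoid-like, which suits monotone saturating trends such as the
    autofluorescence ratio versus OD.
    """

    names = ("amplitude", "bias_scale", "input_scale")

    def __init__(self, amplitude: float = 1.0, bias_scale: float = 1.0,
                 input_scale: float = 1.0):
        if min(amplitude, bias_scale, input_scale) <= 0:
            raise ValueError("kernel hyperparameters must be strictly positive")
        self.amplitude = float(amplitude)
        self.bias_scale = float(bias_scale)
        self.input_scale = float(input_scale)

    def __call__(self, x1, x2):
        x1 = np.asarray(x1, float)
        x2 = np.asarray(x2, float)
        s0sq, s1sq = self.bias_scale**2, self.input_scale**2
        num = 2.0 * (s0sq + s1sq * np.outer(x1, x2))
        d1 = 1.0 + 2.0 * (s0sq + s1sq * x1**2)
        d2 = 1.0 + 2.0 * (s0sq + s1sq * x2**2)
        arg = num / np.sqrt(np.outer(d1, d2))
        arg = np.clip(arg, -1.0, 1.0)
        return self.amplitude**2 * (2.0 / np.pi) * np.arcsin(arg)

    @property
    def theta(self):
        return np.log([self.amplitude, self.bias_scale, self.input_scale])

    @theta.setter
    def theta(self, value):
        self.amplitude, self.bias_scale, self.input_scale = np.exp(value)

    def clone(self):
        return NeuralNetwork(self.amplitude, self.bias_scale, self.input_scale)


class Sum(Kernel):
    """Sum of two kernels; hyperparameters are the children's, concatenated."""

    def __init__(self, left: Kernel, right: Kernel):
        self.left = left
        self.right = right

    @property
    def names(self):
        return tuple(f"left.{n}" for n in self.left.names) + tuple(
            f"right.{n}" for n in self.right.names
        )

    def __call__(self, x1, x2):
        return self.left(x1, x2) + self.right(x1, x2)

    @property
    def theta(self):
        return np.concatenate([self.left.theta, self.right.theta])

    @theta.setter
    def theta(self, value):
        k = len(self.left.theta)
        self.left.theta = value[:k]
        self.right.theta = value[k:]

    def clone(self):
        return Sum(self.left.clone(), self.right.clone())


_KERNEL_FAMILIES = {
    "squared_exponential": SquaredExponential,
    "linear": Linear,
    "neural_network": NeuralNetwork,
}


def make_kernel(spec) -> Kernel:
    """Build a kernel from a config spec.

    Accepts a Kernel instance, a family name, a ``{"family": ..., <hyper>: ...}``
    mapping, or a list of such specs (summed).
    """
    if isinstance(spec, Kernel):
        return spec.clone()
    if isinstance(spec, str):
        return _KERNEL_FAMILIES[spec]()
    if isinstance(spec, (list, tuple)):
        kernels = [make_kernel(s) for s in spec]
        out = kernels[0]
        for k in kernels[1:]:
            out = Sum(out, k)
        return out
    if isinstance(spec, dict):
        spec = dict(spec)
        family = spec.pop("family")
        return _KERNEL_FAMILIES[family](**spec)
    raise ValueError(f"cannot interpret kernel spec {spec!r}")


# --------------------------------------------------------------------------
# Factorization helpers
# --------------------------------------------------------------------------

def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of K, adding escalating diagonal jitter if needed."""
    scale = max(np.mean(np.diag(K)), np.finfo(float).tiny)
    try:
        return linalg.cholesky(K, lower=True), 0.0
    except linalg.LinAlgError:
        pass
    for j in _JITTERS:
        try:
            return linalg.cholesky(K + j * scale * np.eye(len(K)), lower=True), j * scale
        except linalg.LinAlgError:
            continue
    raise NumericalError(
        f"covariance matrix not positive definite even with jitter up to "
        f"{_JITTERS[-1]:.0e} x mean diagonal"
    )


def log_marginal_likelihood(kernel: Kernel, x, y, noise_var) -> float:
    """Log evidence of y under the zero-mean GP with fixed noise variances."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    K = kernel(x, x) + np.diag(np.asarray(noise_var, float))
    L, _ = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * _LOG2PI
    )


# --------------------------------------------------------------------------
# Posterior container and fitting
# --------------------------------------------------------------------------

@dataclass
class GPPosterior:
    """Fitted GP: training data, optimized kernel, and cached factorization."""

    train_x: np.ndarray
    train_y: np.ndarray
    noise_sd: np.ndarray
    kernel: Kernel
    log_evidence: float
    _L: np.ndarray = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self._L is None:
            K = self.kernel(self.train_x, self.train_x) + np.diag(self.noise_sd**2)
            self._L, _ = _chol_with_jitter(K)
            self._alpha = linalg.cho_solve((self._L, True), self.train_y)

    def predict(self, x_star) -> tuple[np.ndarray, np.ndarray]:
        return gp_predict(self, x_star)

    def sample(self, x_star, n: int, seed) -> np.ndarray:
        return gp_sample(self, x_star, n, seed)


def _init_theta(kernel: Kernel, x: np.ndarray, y: np.ndarray) -> None:
    """Data-scaled initial hyperparameters, set in place."""
    span = max(np.ptp(x), 1e-3)
    ysd = max(np.std(y), 1e-8)
    xsq = max(np.mean(x**2), 1e-6)

    def init_one(k: Kernel):
        if isinstance(k, SquaredExponential):
            k.amplitude, k.lengthscale = ysd, 0.3 * span
        elif isinstance(k, Linear):
            k.variance = ysd**2 / xsq
        elif isinstance(k, NeuralNetwork):
            k.amplitude = ysd
            k.bias_scale = 1.0
            k.input_scale = 2.0 / span
        elif isinstance(k, Sum):
            init_one(k.left)
            init_one(k.right)

    init_one(kernel)


def gp_fit(
    x,
    y,
    noise_sd,
    kernel,
    *,
    optimize_hyperparams: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
    method: str = "TNC",
) -> GPPosterior:
    """Fit a zero-mean GP by maximizing the log marginal likelihood.

    Parameters
    ----------
    noise_sd
        Per-point noise standard deviations (array, all > 0); the string
        ``"learn"`` to optimize a single constant noise sd jointly with the
        kernel hyperparameters; or a tuple ``("learn_scaled", profile)`` to
        optimize one multiplier on the supplied per-point relative profile
        (for noise known up to scale, e.g. multiplicative OD error in a
        dilution series).
    kernel
        Kernel instance or spec (see :func:`make_kernel`); initial
        hyperparameters are rescaled to the data before optimization.
    optimize_hyperparams
        ``False`` evaluates the evidence at the given hyperparameters without
        optimization (requires explicit ``noise_sd``).

    Raises
    ------
    FitError
        If no restart converges to a finite optimum; carries best-so-far state.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    kernel = make_kernel(kernel)

    learn_mode = None
    profile = None
    if isinstance(noise_sd, str):
        if noise_sd != "learn":
            raise ValueError(f"unknown noise mode {noise_sd!r}")
        learn_mode = "constant"
    elif (
        isinstance(noise_sd, tuple)
        and len(noise_sd) == 2
        and noise_sd[0] == "learn_scaled"
    ):
        learn_mode = "scaled"
        profile = np.asarray(noise_sd[1], dtype=float)
        if profile.shape != x.shape or np.any(profile <= 0):
            raise ValueError("learn_scaled profile must be positive, same length as x")
    else:
        noise_sd = np.asarray(noise_sd, dtype=float)
        if noise_sd.shape != x.shape or np.any(noise_sd <= 0):
            raise ValueError("noise_sd must be positive and match x in length")

    if not optimize_hyperparams:
        if learn_mode is not None:
            raise ValueError("noise learning requires hyperparameter optimization")
        lml = log_marginal_likelihood(kernel, x, y, noise_sd**2)
        return GPPosterior(x, y, noise_sd, kernel, lml)

    _init_theta(kernel, x, y)
    theta0 = kernel.theta.copy()
    if learn_mode == "constant":
        theta0 = np.append(theta0, np.log(max(0.1 * np.std(y), 1e-6)))
    elif learn_mode == "scaled":
        theta0 = np.append(theta0, 0.0)
    n_kernel = len(kernel.theta)

    def noise_var_of(theta):
        if learn_mode == "constant":
            return np.full_like(y, np.exp(2 * theta[n_kernel]))
        if learn_mode == "scaled":
            return (np.exp(theta[n_kernel]) * profile) ** 2
        return noise_sd**2

    def neg_lml(theta):
        kernel.theta = theta[:n_kernel]
        try:
            return -log_marginal_likelihood(kernel, x, y, noise_var_of(theta))
        except NumericalError:
            return 1e25

    bounds = [(t - np.log(1e4), t + np.log(1e4)) for t in theta0]
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.uniform(
            -np.log(30.0), np.log(30.0), size=theta0.shape
        )
        try:
            options = {"maxfun": 1000} if method == "TNC" else None
            res = optimize.minimize(
                neg_lml, start, method=method, bounds=bounds, options=options
            )
        except (ValueError, FloatingPointError):
            continue
        if not (np.isfinite(res.fun) and res.fun < 1e24):
            continue
        # TNC status 4 is a stalled line search: no ascent direction left,
        # which at an interior optimum is convergence in all but name
        stalled = method == "TNC" and getattr(res, "status", None) == 4
        any_converged = any_converged or bool(res.success) or stalled
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise FitError(
            "marginal-likelihood optimization failed to converge on all restarts",
            best_state=best,
        )

    kernel.theta = best.x[:n_kernel]
    final_noise = np.sqrt(noise_var_of(best.x))
    return GPPosterior(x, y, final_noise, kernel, float(-best.fun))


def gp_predict(post: GPPosterior, x_star) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and pointwise sd of the latent function at x_star."""
    x_star = np.atleast_1d(np.asarray(x_star, dtype=float))
    k_star = post.kernel(post.train_x, x_star)
    mean = k_star.T @ post._alpha
    v = linalg.solve_triangular(post._L, k_star, lower=True)
    var = np.clip(
        np.diag(post.kernel(x_star, x_star)) - np.sum(v**2, axis=0), 0.0, None
    )
    return mean, np.sqrt(var)


def gp_posterior_cov(post: GPPosterior, x_star) -> np.ndarray:
    """Full posterior covariance of the latent function at x_star."""
    x_star = np.atleast_1d(np.asarray(x_star, dtype=float))
    k_star = post.kernel(post.train_x, x_star)
    v = linalg.solve_triangular(post._L, k_star, lower=True)
    return post.kernel(x_star, x_star) - v.T @ v


def gp_sample(post: GPPosterior, x_star, n: int, seed) -> np.ndarray:
    """Draw n joint posterior function samples at x_star; shape (n, len(x_star))."""
    x_star = np.atleast_1d(np.asarray(x_star, dtype=float))
    mean = gp_predict(post, x_star)[0]
    cov = gp_posterior_cov(post, x_star)
    cov = 0.5 * (cov + cov.T)
    # near-degenerate posteriors (dense noiseless data) need the jitter ladder
    L, _ = _chol_with_jitter(cov + 1e-12 * np.eye(len(x_star)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(x_star)))
    return mean + z @ L.T


def empirical_noise(x, y, k: int) -> np.ndarray:
    """Per-point noise sd from the k nearest points in the x coordinate.

    For each point i, the sample standard deviation (n-1 denominator) of the
    y-values of the k points whose x is closest to x_i — including point i
    itself, ties broken by index order. Floored at 1e-12. This is the
    nearest-neighbour error estimate used for media baselines (k=10) and the
    autofluorescence-ratio fit (k=20).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    out = np.empty(n)
    for i in range(n):
        # stable argsort keeps index order on distance ties
        nearest = np.argsort(np.abs(x - x[i]), kind="stable")[:k]
        out[i] = np.std(y[nearest], ddof=1)
    return np.maximum(out, 1e-12)
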