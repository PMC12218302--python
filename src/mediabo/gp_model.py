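"""Gaussian-process surrogate with fixed, replicate-derived process noise.

The model is y_i = f(x_i) + ε_i with ε_i ~ N(0, σ_i²) and f a zero-mean GP
(after target standardisation) under the mixed categorical-continuous kernel.
The noise variance is estimated from replicate control experiments and held
FIXED while the kernel hyperparameters (length scales θ, categorical scale
σ_cat, mixture weight α) are chosen by maximising the log marginal
likelihood from multiple restarts of bounded L-BFGS-B.

Biological replicates carry substantial measurement noise, so pinning the
noise level to what the controls actually show — rather than letting the
optimiser trade signal for noise — is what keeps the surrogate honest on
small campaign datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky

from .kernels import JITTER, KernelParams, cross_gram, gram, ohe_baseline

logger = logging.getLogger(__name__)

__all__ = ["TrainingSet", "GPModel", "estimate_noise_variance", "fit_gp", "check_convergence"]

THETA_BOUNDS = (1e-3, 1e3)
SIGMA_CAT_BOUNDS = (1e-6, 1e3)
ALPHA_INIT = 0.5
THETA_INIT = 0.5


def estimate_noise_variance(control_measurements: np.ndarray) -> float:
    """Unbiased sample variance of pooled control-experiment measurements.

    Controls from every iteration, including the contemporaneous one, are
    pooled into one vector; the result is on the raw target scale.
    """
    v = np.asarray(control_measurements, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two control measurements")
    return float(np.var(v, ddof=1))


@dataclass
class TrainingSet:
    """Encoded inputs, raw-scale targets and per-point noise variances."""

    x: np.ndarray  # (n, d) scaled continuous/discrete coordinates
    h: np.ndarray  # (n, c) category indices
    y: np.ndarray  # (n,) raw targets
    noise: np.ndarray  # (n,) raw-scale noise variances σ_i²

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.h = np.atleast_2d(np.asarray(self.h, dtype=int))
        if self.h.size == 0:
            self.h = np.zeros((self.x.shape[0], 0), dtype=int)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.noise = np.broadcast_to(
            np.asarray(self.noise, dtype=float), self.y.shape
        ).copy()
        n = self.y.size
        if not (self.x.shape[0] == n and self.h.shape[0] == n):
            raise ValueError("points, targets and noise must have equal lengths")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("training data must be finite")

    @property
    def n(self) -> int:
        return self.y.size

    def extended(self, x: np.ndarray, h: np.ndarray, y: float, noise: float) -> "TrainingSet":
        x = np.atleast_2d(x)
        h = np.atleast_2d(np.asarray(h, dtype=int)) if np.size(h) else np.zeros((1, 0), dtype=int)
        return TrainingSet(
            np.vstack([self.x, x]),
            np.vstack([self.h, h]),
            np.append(self.y, y),
            np.append(self.noise, noise),
        )


class GPModel:
    """Fitted GP posterior over the standardised targets.

    Not constructed directly in normal use — see :func:`fit_gp`.  Holds the
    Cholesky factorisation of the noisy Gram matrix so predictions are cheap.
    """

    def __init__(
        self,
        training: TrainingSet,
        params: KernelParams,
        kernel: str = "mixed",
        n_categories: tuple[int, ...] = (),
        y_mean: float | None = None,
        y_std: float | None = None,
    ) -> None:
        if kernel not in ("mixed", "ohe"):
            raise ValueError("kernel must be 'mixed' or 'ohe'")
        self.training = training
        self.params = params
        self.kernel = kernel
        self.n_categories = tuple(n_categories)
        # standardisation constants; frozen at fit time so light refits
        # (constant-liar lies) keep the same scale
        self.y_mean = float(np.mean(training.y)) if y_mean is None else float(y_mean)
        std = float(np.std(training.y)) if y_std is None else float(y_std)
        self.y_std = std if std > 1e-12 else 1.0
        self._factorize()

    # -- internals ---------------------------------------------------------
    def _cov(self, x1, h1, x2, h2) -> np.ndarray:
        # signal variance scales the whole covariance (amplitude on the
        # standardised scale); the kernel functions themselves stay unit-scale
        if self.kernel == "mixed":
            base = cross_gram(x1, h1, x2, h2, self.params)
        else:
            base = ohe_baseline(x1, h1, x2, h2, self.params.theta, self.params.nu, self.n_categories)
        return self.params.signal_variance * base

    def _cov_diag(self, x: np.ndarray, h: np.ndarray) -> np.ndarray:
        """k(z, z) per point without forming the full Gram matrix; the
        kernels are stationary so the self-covariance is a constant."""
        p = self.params
        n = np.atleast_2d(x).shape[0]
        has_cont = np.atleast_2d(x).shape[1] > 0
        has_cat = np.atleast_2d(h).shape[1] > 0
        if self.kernel == "ohe" or not has_cat:
            k_self = 1.0
        elif not has_cont:
            k_self = p.sigma_cat
        else:
            k_self = p.alpha * p.sigma_cat + (1.0 - p.alpha) * (p.sigma_cat + 1.0)
        return np.full(n, p.signal_variance * k_self)

    def _factorize(self) -> None:
        t = self.training
        noise_std_scale = t.noise / self.y_std**2
        K = self._cov(t.x, t.h, t.x, t.h)
        K = 0.5 * (K + K.T)
        K[np.diag_indices(t.n)] += JITTER + noise_std_scale
        self._ys = (t.y - self.y_mean) / self.y_std
        self._chol = cho_factor(K, lower=True)
        self._alpha_vec = cho_solve(self._chol, self._ys)

    # -- inference ---------------------------------------------------------
    def log_marginal_likelihood(self) -> float:
        n = self.training.n
        L = self._chol[0]
        return float(
            -0.5 * self._ys @ self._alpha_vec
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )

    def predict(self, x: np.ndarray, h: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd of the latent response, raw target scale."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 0:
            return np.zeros(0), np.zeros(0)
        if h is None or np.size(h) == 0:
            h = np.zeros((x.shape[0], 0), dtype=int)
        h = np.atleast_2d(np.asarray(h, dtype=int))
        t = self.training
        Ks = self._cov(x, h, t.x, t.h)
        mean_s = Ks @ self._alpha_vec
        v = cho_solve(self._chol, Ks.T)
        kss = self._cov_diag(x, h)
        var_s = np.maximum(kss - np.sum(Ks * v.T, axis=1), 0.0)
        return self.y_mean + self.y_std * mean_s, self.y_std * np.sqrt(var_s)

    def sample_posterior(
        self, x: np.ndarray, h: np.ndarray | None, n_draws: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Joint posterior sample paths over the given points, raw scale.

        Cost is cubic in the number of query points; used for Thompson
        sampling over a candidate screen.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if h is None or np.size(h) == 0:
            h = np.zeros((x.shape[0], 0), dtype=int)
        h = np.atleast_2d(np.asarray(h, dtype=int))
        t = self.training
        Ks = self._cov(x, h, t.x, t.h)
        mean_s = Ks @ self._alpha_vec
        v = cho_solve(self._chol, Ks.T)
        cov = self._cov(x, h, x, h) - Ks @ v
        cov = 0.5 * (cov + cov.T)
        cov[np.diag_indices(cov.shape[0])] += 1e-10
        L = cholesky(cov, lower=True)
        z = rng.standard_normal((cov.shape[0], n_draws))
        draws_s = mean_s[:, None] + L @ z
        return self.y_mean + self.y_std * draws_s.T  # (n_draws, n_points)

    def prior_sd(self, x: np.ndarray, h: np.ndarray | None = None) -> np.ndarray:
        """Prior predictive sd at the given points, raw target scale."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if h is None or np.size(h) == 0:
            h = np.zeros((x.shape[0], 0), dtype=int)
        return self.y_std * np.sqrt(self._cov_diag(x, np.atleast_2d(h)))

    def training_rmse(self) -> float:
        mean, _ = self.predict(self.training.x, self.training.h)
        return float(np.sqrt(np.mean((mean - self.training.y) ** 2)))

    def with_observation(self, x: np.ndarray, h: np.ndarray, y: float, noise: float = 0.0) -> "GPModel":
        """Light refit: append one observation, keep hyperparameters and
        standardisation constants (used by the constant-liar loop)."""
        return GPModel(
            self.training.extended(x, h, y, noise),
            self.params,
            kernel=self.kernel,
            n_categories=self.n_categories,
            y_mean=self.y_mean,
            y_std=self.y_std,
        )


# ---------------------------------------------------------------------------
# fitting

SIGNAL_VAR_BOUNDS = (1e-4, 1e4)


def _pack_bounds(d: int, c: int, kernel: str, n_ohe: int) -> list[tuple[float, float]]:
    lo, hi = np.log(THETA_BOUNDS[0]), np.log(THETA_BOUNDS[1])
    sv = (np.log(SIGNAL_VAR_BOUNDS[0]), np.log(SIGNAL_VAR_BOUNDS[1]))
    if kernel == "ohe":
        return [(lo, hi)] * n_ohe + [sv]
    bounds = [(lo, hi)] * d
    if c > 0:
        bounds.append((np.log(SIGMA_CAT_BOUNDS[0]), np.log(SIGMA_CAT_BOUNDS[1])))
        bounds.append((0.0, 1.0))
    return bounds + [sv]


def _unpack(vec: np.ndarray, d: int, c: int, nu: float, noise: float, kernel: str) -> KernelParams:
    sv = float(np.exp(vec[-1]))
    vec = vec[:-1]
    if kernel == "ohe" or c == 0:
        return KernelParams(theta=np.exp(vec), nu=nu, noise_variance=noise, signal_variance=sv)
    theta = np.exp(vec[:d]) if d > 0 else np.array([1.0])
    sigma_cat = float(np.exp(vec[d]))
    alpha = float(np.clip(vec[d + 1], 0.0, 1.0))
    return KernelParams(theta=theta, nu=nu, sigma_cat=sigma_cat, alpha=alpha,
                        noise_variance=noise, signal_variance=sv)


def fit_gp(
    training: TrainingSet,
    nu: float | None = None,
    kernel: str = "mixed",
    n_categories: tuple[int, ...] = (),
    n_restarts: int = 10,
    seed: int = 0,
    alpha_init: float = ALPHA_INIT,
) -> GPModel:
    """Maximise the log marginal likelihood over (θ, σ_cat, α).

    The noise variances in ``training`` are never optimised.  The first
    restart starts from the defaults (θ = 0.5 on the scaled axes, α = 0.5);
    the remaining restarts draw log-uniform starting points from the bounds.
    ν defaults to 2.5 when categorical factors are present (the overlap
    kernel pairs with at-least-twice-differentiable continuous kernels) and
    1.5 otherwise.
    """
    if training.n < 2:
        raise ValueError("need at least two training points to fit")
    d = training.x.shape[1]
    c = training.h.shape[1]
    if nu is None:
        nu = 2.5 if c > 0 else 1.5
    if kernel == "ohe" and len(n_categories) != c:
        raise ValueError("ohe kernel needs one category count per categorical dimension")
    n_ohe = d + int(sum(n_categories))

    y_mean = float(np.mean(training.y))
    y_std = float(np.std(training.y)) or 1.0

    def build(params: KernelParams) -> GPModel:
        return GPModel(training, params, kernel=kernel, n_categories=n_categories,
                       y_mean=y_mean, y_std=y_std)

    def negloglik(vec: np.ndarray) -> float:
        try:
            params = _unpack(vec, d, c, nu, 0.0, kernel)
            return -build(params).log_marginal_likelihood()
        except np.linalg.LinAlgError:
            return 1e10

    bounds = _pack_bounds(d, c, kernel, n_ohe)
    n_params = len(bounds)
    rng = np.random.default_rng(seed)

    if kernel == "ohe":
        x0_default = np.full(n_ohe, np.log(THETA_INIT))
    else:
        x0_default = np.full(d, np.log(THETA_INIT))
        if c > 0:
            x0_default = np.append(x0_default, [np.log(1.0), alpha_init])
    x0_default = np.append(x0_default, np.log(1.0))  # unit signal variance
    starts = [x0_default]
    for _ in range(max(0, n_restarts - 1)):
        s = np.array([rng.uniform(max(lo, -3.0), min(hi, 3.0)) for lo, hi in bounds])
        if kernel == "mixed" and c > 0:
            s[-2] = rng.uniform(0.0, 1.0)
        starts.append(s)

    best_vec, best_val = None, np.inf
    init_val = negloglik(x0_default)
    for s in starts:
        res = optimize.minimize(negloglik, s, method="L-BFGS-B", bounds=bounds)
        val = res.fun if np.isfinite(res.fun) else negloglik(res.x)
        if val < best_val:
            best_vec, best_val = res.x, val
    if best_vec is None or best_val >= 1e10:
        raise RuntimeError("hyperparameter optimisation failed on all restarts")
    if best_val > init_val + 1e-9:  # never end below the default start
        best_vec, best_val = x0_default, init_val

    noise_scalar = float(np.mean(training.noise))
    model = build(_unpack(best_vec, d, c, nu, noise_scalar, kernel))
    logger.info(
        "GP fit: lml=%.4f rmse=%.4g theta=%s alpha=%.3f sigma_cat=%.3g",
        -best_val, model.training_rmse(), np.array2string(model.params.theta, precision=3),
        model.params.alpha, model.params.sigma_cat,
    )
    return model


def check_convergence(
    model: GPModel,
    batch: list[tuple[np.ndarray, np.ndarray, float]],
    z_threshold: float = 2.0,
    fraction: float = 0.8,
) -> tuple[bool, np.ndarray]:
    """Agreement between model prediction and experimental observation.

    A batch point agrees when |observation − posterior mean| is within
    ``z_threshold`` times (posterior sd + measurement sd); the campaign is
    declared converged when at least ``fraction`` of the latest batch agrees.
    Returns the verdict and the per-point z-scores.
    """
    if not batch:
        raise ValueError("empty batch")
    zs = []
    noise_sd = float(np.sqrt(np.mean(model.training.noise)))
    for x, h, obs in batch:
        mean, sd = model.predict(np.atleast_2d(x), np.atleast_2d(h) if np.size(h) else None)
        denom = max(sd[0] + noise_sd, 1e-12)
        zs.append(abs(obs - mean[0]) / denom)
    zs = np.asarray(zs, dtype=float)
    return bool(np.mean(zs <= z_threshold) >= fraction), zs
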