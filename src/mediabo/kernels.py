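"""Covariance functions for the mixed categorical-continuous surrogate.

The continuous block uses an ARD Matérn kernel (smoothness ν ∈ {1.5, 2.5},
one length scale per scaled input dimension).  Categorical factors enter
through an overlap kernel, σ/c times the count of matching categories.  The
two are combined as a convex mixture of their product and their sum,

    k(z, z') = α · k_cat·k_cont + (1 − α) · (k_cat + k_cont),

so α interpolates between a multiplicative coupling (category-specific
continuous behaviour) and an additive one (shared continuous trend plus a
category offset).  A one-hot-encoding Matérn baseline is provided for
head-to-head accuracy comparisons, and a fixed-variance white-noise term
carries replicate-derived process noise on the Gram diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as gamma_fn, kv

__all__ = [
    "KernelParams",
    "matern",
    "matern_from_distance",
    "matern_bessel",
    "categorical_overlap",
    "mixed_kernel",
    "gram",
    "cross_gram",
    "ohe_baseline",
    "JITTER",
]

JITTER = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the mixed kernel plus the fixed noise variance.

    theta            per-dimension length scales on the [0,1]-scaled axes
    nu               Matérn smoothness, 1.5 or 2.5
    sigma_cat        scale of the categorical overlap kernel
    alpha            product/sum trade-off in [0, 1]; initialised at 0.5
    noise_variance   white-noise variance, held fixed during fitting
    """

    theta: np.ndarray
    nu: float = 2.5
    sigma_cat: float = 1.0
    alpha: float = 0.5
    noise_variance: float = 0.0
    signal_variance: float = 1.0

    def __post_init__(self) -> None:
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if np.any(th <= 0):
            raise ValueError("theta must be positive elementwise")
        object.__setattr__(self, "theta", th)
        if self.nu not in (1.5, 2.5):
            raise ValueError("nu must be 1.5 or 2.5")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma_cat < 0 or self.noise_variance < 0:
            raise ValueError("sigma_cat and noise_variance must be nonnegative")
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")

    def replace(self, **kw) -> "KernelParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Matérn

def _scaled_dist(x: np.ndarray, x_prime: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Pairwise length-scale-weighted Euclidean distance."""
    a = np.atleast_2d(np.asarray(x, dtype=float))
    b = np.atleast_2d(np.asarray(x_prime, dtype=float))
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if a.shape[1] != b.shape[1] or (a.shape[1] and a.shape[1] != th.size):
        raise ValueError(
            f"dimension mismatch: x has {a.shape[1]}, x' has {b.shape[1]}, theta has {th.size}"
        )
    diff = a[:, None, :] / th - b[None, :, :] / th
    return np.sqrt(np.sum(diff * diff, axis=-1))


def matern_from_distance(r: np.ndarray, nu: float) -> np.ndarray:
    """Closed-form Matérn at scaled distance r, unit variance."""
    r = np.asarray(r, dtype=float)
    if nu == 1.5:
        s = np.sqrt(3.0) * r
        return (1.0 + s) * np.exp(-s)
    if nu == 2.5:
        s = np.sqrt(5.0) * r
        return (1.0 + s + s * s / 3.0) * np.exp(-s)
    raise ValueError("nu must be 1.5 or 2.5")


def matern(x: np.ndarray, x_prime: np.ndarray, theta: np.ndarray, nu: float) -> np.ndarray:
    """ARD Matérn covariance between rows of x and x_prime (scaled inputs)."""
    return matern_from_distance(_scaled_dist(x, x_prime, theta), nu)


def matern_bessel(d: float, theta: float = 1.0, nu: float = 1.5) -> float:
    """General Matérn via Γ and the modified Bessel function K_ν.

    Numerical cross-check for the ν = 1.5 / 2.5 closed forms; returns 1 at
    zero distance by continuity.
    """
    d = abs(float(d)) / float(theta)
    if d == 0.0:
        return 1.0
    s = np.sqrt(2.0 * nu) * d
    return float(2.0 ** (1.0 - nu) / gamma_fn(nu) * s**nu * kv(nu, s))


# ---------------------------------------------------------------------------
# categorical overlap

def categorical_overlap(
    h: np.ndarray, h_prime: np.ndarray, sigma_cat: float, c: int | None = None
) -> np.ndarray:
    """(σ/c) · Σ_i 1(h_i == h'_i) between rows of h and h_prime."""
    a = np.atleast_2d(np.asarray(h, dtype=int))
    b = np.atleast_2d(np.asarray(h_prime, dtype=int))
    if c is None:
        c = a.shape[1]
    if c < 1:
        raise ValueError("overlap kernel undefined without categorical variables (c = 0)")
    if a.shape[1] != c or b.shape[1] != c:
        raise ValueError("category index vectors must have length c")
    matches = np.sum(a[:, None, :] == b[None, :, :], axis=-1)
    return (sigma_cat / c) * matches


# ---------------------------------------------------------------------------
# mixture

def mixed_kernel(
    x: np.ndarray,
    h: np.ndarray,
    x_prime: np.ndarray,
    h_prime: np.ndarray,
    params: KernelParams,
) -> np.ndarray:
    """α·(k_cat·k_cont) + (1−α)·(k_cat + k_cont) over encoded points.

    With no categorical dimensions this reduces to the continuous Matérn;
    with no continuous dimensions, to the overlap kernel.
    """
    h = np.atleast_2d(np.asarray(h, dtype=int))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    has_cont = x.shape[1] > 0
    has_cat = h.shape[1] > 0
    if has_cont and not has_cat:
        return matern(x, x_prime, params.theta, params.nu)
    if has_cat and not has_cont:
        return categorical_overlap(h, h_prime, params.sigma_cat)
    k_cont = matern(x, x_prime, params.theta, params.nu)
    k_cat = categorical_overlap(h, h_prime, params.sigma_cat)
    return params.alpha * (k_cat * k_cont) + (1.0 - params.alpha) * (k_cat + k_cont)


def cross_gram(
    x: np.ndarray, h: np.ndarray, x2: np.ndarray, h2: np.ndarray, params: KernelParams
) -> np.ndarray:
    return mixed_kernel(x, h, x2, h2, params)


def gram(
    x: np.ndarray,
    h: np.ndarray,
    params: KernelParams,
    include_noise: bool = False,
    noise_variances: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric Gram matrix with jitter; optionally the white-noise diagonal.

    ``noise_variances`` overrides the shared ``params.noise_variance`` with a
    per-point vector (controls pooled across iterations can differ).
    """
    K = mixed_kernel(x, h, x, h, params)
    if not np.all(np.isfinite(K)):
        raise ValueError("non-finite kernel entries")
    K = 0.5 * (K + K.T)
    n = K.shape[0]
    K[np.diag_indices(n)] += JITTER
    if include_noise:
        if noise_variances is not None:
            K[np.diag_indices(n)] += np.asarray(noise_variances, dtype=float)
        else:
            K[np.diag_indices(n)] += params.noise_variance
    return K


# ---------------------------------------------------------------------------
# one-hot baseline

def _ohe_concat(x: np.ndarray, h: np.ndarray, n_categories: tuple[int, ...]) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=int))
    blocks = [x]
    for j, m in enumerate(n_categories):
        one_hot = np.zeros((h.shape[0], m))
        one_hot[np.arange(h.shape[0]), h[:, j]] = 1.0
        blocks.append(one_hot)
    return np.hstack(blocks)


def ohe_baseline(
    x: np.ndarray,
    h: np.ndarray,
    x_prime: np.ndarray,
    h_prime: np.ndarray,
    theta_ohe: np.ndarray,
    nu: float,
    n_categories: tuple[int, ...],
) -> np.ndarray:
    """Matérn over [scaled continuous dims | one-hot indicator coordinates].

    ``theta_ohe`` has one length scale per concatenated coordinate
    (n_numeric + sum of category counts).
    """
    a = _ohe_concat(x, h, n_categories)
    b = _ohe_concat(x_prime, h_prime, n_categories)
    return matern(a, b, theta_ohe, nu)
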