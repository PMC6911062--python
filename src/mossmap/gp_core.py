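"""Spatial correlation models, Gaussian-field simulation and kriging.

All distances are planar Euclidean in kilometres; coordinates are
``(easting, northing)`` pairs in a projected CRS.  Two correlation
families are supported:

* Matérn, ``rho(u; phi, kappa) = {2^(kappa-1) Gamma(kappa)}^{-1}
  (u/phi)^kappa K_kappa(u/phi)``, with the smoothness ``kappa`` fixed at
  construction (it is not identifiable from a single realization on a
  bounded domain, so it is never estimated);
* exponential, ``rho(u; psi) = exp(-u/psi)``, the Matérn sub-family with
  ``kappa = 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import kv

__all__ = [
    "MaternParams",
    "ExponentialParams",
    "FieldRealization",
    "matern_correlation",
    "exponential_correlation",
    "build_covariance",
    "simulate_field",
    "conditional_mean_field",
    "conditional_gaussian",
    "pairwise_distances",
    "cholesky_with_jitter",
]

#: relative jitter added to the diagonal when a Cholesky factorization fails
JITTER_FRACTION = 1e-8


@dataclass(frozen=True)
class MaternParams:
    """Matérn correlation parameters: variance sigma^2, scale phi (km), smoothness kappa.

    ``kappa`` defaults to 1 and is treated as fixed; only variance and
    scale are ever estimated.
    """

    variance: float
    scale: float
    smoothness: float = 1.0

    def __post_init__(self) -> None:
        if not (self.variance > 0 and self.scale > 0 and self.smoothness > 0):
            raise ValueError(
                "MaternParams requires variance, scale and smoothness > 0; got "
                f"({self.variance}, {self.scale}, {self.smoothness})"
            )


@dataclass(frozen=True)
class ExponentialParams:
    """Exponential correlation parameters: variance nu^2, scale psi (km).

    In reporting, the variance/scale of these fields also appear on the
    log scale as log(sigma^2) and log(phi); the names here are per-model
    (variance, scale) to avoid the clash.
    """

    variance: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.variance > 0 and self.scale > 0):
            raise ValueError(
                f"ExponentialParams requires variance, scale > 0; got ({self.variance}, {self.scale})"
            )


@dataclass(frozen=True)
class FieldRealization:
    """A Gaussian-field draw: values at planar locations, reproducible from seed."""

    locations: np.ndarray  # (n, 2) km
    values: np.ndarray  # (n,)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.locations):
            raise ValueError("values and locations must have equal length")


def _as_locations(locations) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(locations, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"locations must be (n, 2) planar coordinates, got shape {arr.shape}")
    return arr


def pairwise_distances(a, b=None) -> np.ndarray:
    """Euclidean distance matrix (km) between coordinate arrays."""
    a = _as_locations(a)
    b = a if b is None else _as_locations(b)
    return cdist(a, b)


def matern_correlation(u, params: MaternParams) -> np.ndarray | float:
    """Matérn correlation at distance(s) ``u`` >= 0; equals 1 at u = 0."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("distances must be non-negative")
    kappa, phi = params.smoothness, params.scale
    x = u / phi
    with np.errstate(invalid="ignore"):
        rho = np.where(
            x > 0,
            (2.0 ** (kappa - 1.0) * gamma_fn(kappa)) ** -1
            * np.power(np.maximum(x, np.finfo(float).tiny), kappa)
            * kv(kappa, np.maximum(x, np.finfo(float).tiny)),
            1.0,
        )
    # kv underflows to 0 for very large arguments; that limit is correct
    rho = np.nan_to_num(rho, nan=0.0)
    return rho if rho.ndim else float(rho)


def exponential_correlation(u, params: ExponentialParams) -> np.ndarray | float:
    """Exponential correlation exp(-u/psi) at distance(s) ``u`` >= 0."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("distances must be non-negative")
    rho = np.exp(-u / params.scale)
    return rho if rho.ndim else float(rho)


def _correlation(u: np.ndarray, params) -> np.ndarray:
    if isinstance(params, MaternParams):
        return np.asarray(matern_correlation(u, params))
    if isinstance(params, ExponentialParams):
        return np.asarray(exponential_correlation(u, params))
    raise TypeError(f"unsupported correlation parameters: {type(params).__name__}")


def build_covariance(locations, params, nugget: float = 0.0) -> np.ndarray:
    """Covariance matrix ``variance * rho(||x_i - x_k||) + nugget * 1{i=k}``.

    Duplicate locations are legitimate only with a positive nugget (or
    when the caller deliberately shares one latent value); with
    ``nugget == 0`` the matrix is singular and factorization will fail
    after one jitter retry.
    """
    if nugget < 0:
        raise ValueError("nugget must be >= 0")
    locs = _as_locations(locations)
    u = pairwise_distances(locs)
    cov = params.variance * _correlation(u, params)
    if nugget:
        cov = cov + nugget * np.eye(len(locs))
    return cov


def cholesky_with_jitter(cov: np.ndarray, jitter_scale: float | None = None):
    """Lower Cholesky factor, retrying once with diagonal jitter.

    On the first failure ``JITTER_FRACTION * jitter_scale`` (default: the
    mean diagonal) is added to the diagonal; a second failure raises.
    """
    try:
        return cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(cov))) if jitter_scale is None else jitter_scale
    jitter = JITTER_FRACTION * scale
    try:
        return cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite even after jitter {jitter:g}"
        ) from err


def simulate_field(locations, params, seed, nugget: float = 0.0) -> FieldRealization:
    """Zero-mean Gaussian field draw at ``locations``; identical for identical seed."""
    locs = _as_locations(locations)
    cov = build_covariance(locs, params, nugget=nugget)
    chol = cholesky_with_jitter(cov)
    rng = np.random.default_rng(seed)
    values = chol @ rng.standard_normal(len(locs))
    return FieldRealization(locations=locs, values=values, seed=seed)


def conditional_gaussian(
    observed_locations,
    observed_values,
    targets,
    params,
    nugget: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Kriging mean and variance of the field at ``targets``.

    Conditions a zero-mean Gaussian field (covariance given by ``params``
    plus an optional nugget on the observations) on observed values and
    returns ``(mean, variance)`` at the target locations.  The nugget
    applies to observations only: the target is the noise-free field, so
    with ``nugget == 0`` the mean interpolates the observations exactly.
    """
    obs = _as_locations(observed_locations)
    tgt = _as_locations(targets)
    vals = np.asarray(observed_values, dtype=float)
    if len(vals) != len(obs):
        raise ValueError("observed_values length must match observed_locations")
    cov_oo = build_covariance(obs, params, nugget=nugget)
    cross = params.variance * _correlation(pairwise_distances(tgt, obs), params)
    factor = cho_factor(
        cov_oo + JITTER_FRACTION * params.variance * np.eye(len(obs)), lower=True
    )
    alpha = cho_solve(factor, vals)
    mean = cross @ alpha
    half = solve_triangular(factor[0], cross.T, lower=True)
    var = np.maximum(params.variance - np.sum(half**2, axis=0), 0.0)
    return mean, var


def conditional_mean_field(
    observed: FieldRealization,
    targets,
    params,
    nugget: float = 0.0,
) -> np.ndarray:
    """Conditional (kriging) mean of a zero-mean field at ``targets``.

    Standard conditional-Gaussian formula; far from every observation the
    mean reverts to the prior mean 0.
    """
    mean, _ = conditional_gaussian(observed.locations, observed.values, targets, params, nugget)
    return mean
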