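"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: dense
joint-Gaussian conditioning by explicit block formulas, adaptive
Gauss-Hermite quadrature for small latent-Gaussian Poisson likelihoods,
and the Bessel-integral representation of K_nu.  All drop the Poisson
factorial constant, matching the package's stated convention.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import quad


def bessel_k_integral(nu: float, x: float) -> float:
    """K_nu(x) via the integral representation int_0^inf exp(-x cosh t) cosh(nu t) dt."""
    val, _ = quad(lambda t: np.exp(-x * np.cosh(t)) * np.cosh(nu * t), 0, 30, limit=200)
    return val


def conditional_gaussian_brute(cov: np.ndarray, obs_idx, tgt_idx, obs_values):
    """Conditional mean/cov of a zero-mean Gaussian by the block formula."""
    obs_idx = list(obs_idx)
    tgt_idx = list(tgt_idx)
    Soo = cov[np.ix_(obs_idx, obs_idx)]
    Sto = cov[np.ix_(tgt_idx, obs_idx)]
    Stt = cov[np.ix_(tgt_idx, tgt_idx)]
    sol = np.linalg.solve(Soo, np.asarray(obs_values, float))
    mean = Sto @ sol
    cc = Stt - Sto @ np.linalg.solve(Soo, Sto.T)
    return mean, cc


def gh_poisson_loglik(y, X, offset, sigma, beta, n_nodes: int = 25) -> float:
    """Adaptive Gauss-Hermite log-likelihood of a Poisson log-Gaussian model.

    Centered/scaled at the Laplace mode of p(T | y) (found by plain
    Newton here, independently of the package), product rule over
    ``n_nodes`` probabilists' Hermite nodes per latent dimension.
    Factorial constants dropped.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    sigma = np.asarray(sigma, float)
    n = len(y)
    eta0 = X @ np.atleast_1d(beta) + offset
    sinv = np.linalg.inv(sigma)

    T = np.zeros(n)
    for _ in range(200):
        mu = np.exp(eta0 + T)
        grad = (y - mu) - sinv @ T
        step = np.linalg.solve(sinv + np.diag(mu), grad)
        T = T + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(eta0 + T)
    B = np.linalg.cholesky(np.linalg.inv(sinv + np.diag(mu)))

    nodes, weights = hermegauss(n_nodes)  # weight exp(-z^2/2)
    logw = np.log(weights)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    assert sign > 0
    total = -np.inf
    for idx in product(range(n_nodes), repeat=n):
        z = nodes[list(idx)]
        t = T + B @ z
        lp = (
            y @ (eta0 + t)
            - np.exp(eta0 + t).sum()
            - 0.5 * t @ (sinv @ t)
            - 0.5 * logdet_sigma
            - 0.5 * n * np.log(2 * np.pi)
        )
        total = np.logaddexp(total, logw[list(idx)].sum() + lp + 0.5 * z @ z)
    return float(total + np.log(np.abs(np.linalg.det(B))))
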