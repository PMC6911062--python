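"""Monte Carlo maximum likelihood for Poisson log-Gaussian models.

Shared fitting engine for the log-Gaussian Cox process (discretized to
cell counts) and the geostatistical Poisson richness models.  The model
is

    y_i | T ~ Poisson(exp(x_i' beta + offset_i + T_i)),   T ~ N(0, Sigma(theta)),

with ``Sigma`` from a spatial covariance family parameterized on the log
scale.  Estimation runs in two tiers:

1. the covariance parameters theta maximize a restricted (REML-type)
   Laplace marginal likelihood in which the fixed effects are integrated
   out jointly with the latent field — plain ML variance components from
   a single field realization are biased low, which then understates the
   uncertainty of every spatially structured coefficient;
2. the coefficients beta are then refined by Monte Carlo maximum
   likelihood at the restricted theta estimate: importance samples from
   the Laplace approximation of p(T | y), maximization of the Monte
   Carlo likelihood ratio with analytic gradients, and refreshes of the
   importance density until the relative parameter change drops below
   ``rel_tol`` (at most ``max_refresh`` refreshes; the final refresh
   uses the larger ``info_samples`` size).

Wald confidence intervals use the GLS covariance
(X' (W^-1 + Sigma)^-1 X)^-1 for the coefficients — with sigma-point and
first-order (Kass-Steffey) propagation of the covariance-parameter
uncertainty — and the restricted-likelihood observed information for the
covariance parameters.  The Monte Carlo objective's own curvature is not
used: with a finite importance sample it understates the posterior score
variance and gives overconfident intervals.

Poisson factorial constants (log y!) are dropped everywhere, in the
engine and in any likelihood it is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import kv, logsumexp

from .gp_core import cholesky_with_jitter

_LOG2PI = np.log(2.0 * np.pi)


class NonConvergenceError(RuntimeError):
    """Raised when the MCML optimizer fails; carries the diagnostic report."""


@dataclass
class MCSettings:
    """Monte Carlo and optimizer settings for MCML fitting.

    n_samples: importance samples per refresh (default 2000).
    info_samples: samples for the final information matrix (default: n_samples).
    max_refresh: maximum importance-density refreshes (default 5).
    rel_tol: relative parameter-change threshold to stop refreshing.
    seed: integer seed for the importance draws.
    """

    n_samples: int = 2000
    info_samples: int | None = None
    max_refresh: int = 5
    rel_tol: float = 1e-3
    seed: int = 0
    laplace_maxiter: int = 100
    optimizer_maxiter: int = 200


# ---------------------------------------------------------------------------
# Covariance families (log-scale parameterization, analytic derivatives)


class MaternCovariance:
    """Matérn covariance on fixed locations; theta = (log variance, log scale), kappa fixed.

    Bessel functions are evaluated on the unique distances only (a large
    saving on regular grids) and the matrices for the last theta are
    cached, since the objective needs both the covariance and its
    derivatives at every evaluation.
    """

    param_names = ("log_variance", "log_scale")
    n_params = 2

    def __init__(self, distances: np.ndarray, kappa: float = 1.0):
        u = np.asarray(distances, dtype=float)
        self.shape = u.shape
        self.kappa = float(kappa)
        self.u_unique, self._inv = np.unique(u, return_inverse=True)
        from scipy.special import gamma as gamma_fn

        self._norm = 1.0 / (2.0 ** (self.kappa - 1.0) * gamma_fn(self.kappa))
        self._cache: tuple = (None, None)

    def _tables(self, theta):
        key = tuple(np.asarray(theta, float))
        if self._cache[0] == key:
            return self._cache[1]
        var, scale = np.exp(key)
        x = self.u_unique / scale
        safe = np.maximum(x, np.finfo(float).tiny)
        with np.errstate(invalid="ignore", over="ignore"):
            rho = np.where(x > 0, self._norm * safe**self.kappa * kv(self.kappa, safe), 1.0)
            # d rho / d log(scale) = norm x^(kappa+1) K_{kappa-1}(x), via d/dx[x^k K_k] = -x^k K_{k-1}
            drho = np.where(
                x > 0, self._norm * safe ** (self.kappa + 1.0) * kv(self.kappa - 1.0, safe), 0.0
            )
        rho = np.nan_to_num(rho, nan=0.0)
        drho = np.nan_to_num(drho, nan=0.0)
        base = var * rho[self._inv].reshape(self.shape)
        sigma = base + 1e-8 * var * np.eye(self.shape[0])
        dsigma = [base, var * drho[self._inv].reshape(self.shape)]
        out = (sigma, dsigma)
        self._cache = (key, out)
        return out

    def build(self, theta) -> np.ndarray:
        return self._tables(theta)[0]

    def derivs(self, theta) -> list[np.ndarray]:
        return self._tables(theta)[1]


class ExponentialNuggetCovariance:
    """Exponential + nugget covariance; theta = (log nu^2, log psi, log tau^2)."""

    param_names = ("log_variance", "log_scale", "log_nugget")
    n_params = 3

    def __init__(self, distances: np.ndarray):
        self.u = np.asarray(distances, dtype=float)
        self._cache: tuple = (None, None)

    def _tables(self, theta):
        key = tuple(np.asarray(theta, float))
        if self._cache[0] == key:
            return self._cache[1]
        nu2, psi, tau2 = np.exp(key)
        base = nu2 * np.exp(-self.u / psi)
        eye = np.eye(base.shape[0])
        sigma = base + (tau2 + 1e-8 * nu2) * eye
        out = (sigma, [base, base * (self.u / psi), tau2 * eye])
        self._cache = (key, out)
        return out

    def build(self, theta) -> np.ndarray:
        return self._tables(theta)[0]

    def derivs(self, theta) -> list[np.ndarray]:
        return self._tables(theta)[1]


# ---------------------------------------------------------------------------


@dataclass
class PoissonLGMFit:
    """MCML fit of a Poisson log-Gaussian model."""

    beta: np.ndarray
    theta: np.ndarray  # log-scale covariance parameters
    cov: np.ndarray  # Wald covariance of (beta, theta)
    loglik: float
    latent_mean: np.ndarray  # Laplace posterior mean of T at the estimate
    latent_cov: np.ndarray  # Laplace posterior covariance of T
    n_refresh: int
    converged: bool
    settings: MCSettings
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.theta])

    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov), 0.0))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        se = self.se()
        est = self.params
        return np.column_stack([est - z * se, est + z * se])


def _laplace_mode(y, X, offset, beta, sigma_inv, maxiter=100, tol=1e-9):
    """Newton mode and curvature of p(T | y): returns (m, W=diag weights at mode)."""
    n = len(y)
    eta0 = X @ beta + offset
    T = np.zeros(n)

    def obj(T):
        eta = eta0 + T
        return float(y @ eta - np.exp(eta).sum() - 0.5 * T @ (sigma_inv @ T))

    cur = obj(T)
    for _ in range(maxiter):
        mu = np.exp(eta0 + T)
        grad = (y - mu) - sigma_inv @ T
        H = sigma_inv + np.diag(mu)
        try:
            step = cho_solve(cho_factor(H, lower=True), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H, grad)
        # backtracking keeps the concave objective increasing
        scale = 1.0
        for _ in range(30):
            cand = T + scale * step
            val = obj(cand)
            if val >= cur - 1e-12:
                break
            scale *= 0.5
        T, improved = cand, val - cur
        cur = val
        if np.max(np.abs(grad)) < tol * (1.0 + np.abs(cur)) or abs(improved) < tol * (1.0 + abs(cur)):
            break
    return T, np.exp(eta0 + T)


def _joint_mode(y, X, offset, sigma_inv, beta0, maxiter=100, tol=1e-10):
    """Newton mode of the joint density in z = (beta, T) for fixed theta."""
    n, p = X.shape[::-1] if False else (len(y), X.shape[1])
    beta = beta0.copy()
    m = np.zeros(n)
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset + m, -40, 40)
        mu = np.exp(eta)
        grad = np.concatenate([X.T @ (y - mu), (y - mu) - sigma_inv @ m])
        WX = X * mu[:, None]
        K = np.block([[X.T @ WX, WX.T], [WX, sigma_inv + np.diag(mu)]])
        try:
            step = cho_solve(cho_factor(K, lower=True), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(K, grad, rcond=None)[0]
        beta = beta + step[:p]
        m = m + step[p:]
        if np.max(np.abs(grad)) < tol * (1.0 + abs(y.sum())):
            break
    eta = np.clip(X @ beta + offset + m, -40, 40)
    return beta, m, np.exp(eta)


def reml_loglik_grad(y, X, offset, cov_model, theta, beta0):
    """Restricted (REML-type) Laplace log-likelihood in theta and its gradient.

    The fixed effects are integrated out jointly with the latent field
    under a flat prior (Laplace approximation over z = (beta, T)), which
    removes the downward bias of plain ML variance-component estimates.
    Returns (loglik, grad, beta_hat, m_hat).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    n, p = len(y), X.shape[1]
    sigma = cov_model.build(theta)
    L = cholesky_with_jitter(sigma)
    Q = cho_solve((L, True), np.eye(n))
    beta_hat, m, mu = _joint_mode(y, X, offset, Q, beta0)
    WX = X * mu[:, None]
    K = np.block([[X.T @ WX, WX.T], [WX, Q + np.diag(mu)]])
    LK = cholesky_with_jitter(K)
    K_inv = cho_solve((LK, True), np.eye(n + p))
    a = Q @ m
    ll = float(
        y @ (X @ beta_hat + offset + m) - mu.sum() - 0.5 * m @ a
        - np.sum(np.log(np.diag(L))) - np.sum(np.log(np.diag(LK)))
    )
    J_Kinv_Jt_diag = np.einsum(
        "ij,ij->i", np.hstack([X, np.eye(n)]) @ K_inv, np.hstack([X, np.eye(n)])
    )
    K_tt = K_inv[p:, p:]
    grads = np.empty(cov_model.n_params)
    for k, dS in enumerate(cov_model.derivs(theta)):
        QdS = Q @ dS
        QdSa = QdS @ a
        rhs = np.concatenate([np.zeros(p), QdSa])
        dz = K_inv @ rhs
        dmu = mu * (X @ dz[:p] + dz[p:])
        grads[k] = (
            0.5 * a @ (dS @ a)
            - 0.5 * np.trace(QdS)
            + 0.5 * np.sum(K_tt * (QdS @ Q))
            - 0.5 * J_Kinv_Jt_diag @ dmu
        )
    return ll, grads, beta_hat, m


def maximize_reml(y, X, offset, cov_model, theta0, beta0, theta_bounds, maxiter=100):
    """Maximize the restricted Laplace likelihood over theta (multi-start).

    The restricted likelihood is often multimodal in (variance, scale,
    nugget) — a short-range/low-variance mode can trap the optimizer — so
    besides ``theta0`` two additional starts are used: a long-range and a
    nugget-dominated configuration sized from the Poisson overdispersion
    of an independence fit.  The best optimum wins.
    """

    def neg(theta):
        ll, grad, _, _ = reml_loglik_grad(y, X, offset, cov_model, theta, beta0)
        return -ll, -grad

    # crude total latent variance from the GLM overdispersion:
    # Var(y) ~ mu + mu^2 (e^{v}-1)  =>  v ~ log(1 + (disp-1)/mu_bar)
    mu_glm = np.exp(np.clip(X @ beta0 + offset, -30, 30))
    disp = float(np.mean((y - mu_glm) ** 2 / np.maximum(mu_glm, 1e-6)))
    mu_bar = float(np.mean(mu_glm))
    v_tot = max(np.log1p(max(disp - 1.0, 0.05) / max(mu_bar, 0.1)), 0.02)
    lo_s, hi_s = theta_bounds[1]
    long_range = min(0.7 * hi_s + 0.3 * lo_s, np.log(50.0))
    starts = [np.asarray(theta0, float)]
    if cov_model.n_params == 3:
        starts.append(np.array([np.log(0.7 * v_tot), long_range, np.log(0.3 * v_tot)]))
        starts.append(np.array([np.log(0.3 * v_tot), np.log(max(2.0, np.exp(lo_s) * 4)), np.log(0.7 * v_tot)]))
    else:
        # two-parameter Matérn profile is rarely multimodal; one extra start
        starts.append(np.array([np.log(v_tot), long_range]))
    best = None
    for s in starts:
        s = np.clip(s, [b[0] for b in theta_bounds], [b[1] for b in theta_bounds])
        res = minimize(neg, s, jac=True, method="L-BFGS-B", bounds=theta_bounds,
                       options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    return best


def _draw_importance(m, H, n_samples, rng):
    """Draws from N(m, H^-1) plus their log-density."""
    n = len(m)
    L = cholesky_with_jitter(H)
    z = rng.standard_normal((n, n_samples))
    T = m[:, None] + solve_triangular(L, z, lower=True, trans="T")
    logdet_H = 2.0 * np.sum(np.log(np.diag(L)))
    logq = 0.5 * logdet_H - 0.5 * n * _LOG2PI - 0.5 * np.sum(z**2, axis=0)
    return T, logq


def _mc_objective_factory(y, X, offset, cov_model, T_samples, logq):
    """Returns f(psi) -> (-loglik, -grad) for the Monte Carlo likelihood."""
    n, M = T_samples.shape
    p = X.shape[1]
    yTt = y @ T_samples  # (M,)

    def fun(psi):
        beta, theta = psi[:p], psi[p:]
        eta0 = X @ beta + offset
        sigma = cov_model.build(theta)
        L = cholesky_with_jitter(sigma)
        A = cho_solve((L, True), T_samples)  # Sigma^{-1} T, (n, M)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        quad = np.sum(T_samples * A, axis=0)
        log_prior = -0.5 * (logdet + n * _LOG2PI) - 0.5 * quad
        mu_mat = np.exp(eta0[:, None] + T_samples)  # (n, M)
        log_data = y @ eta0 + yTt - mu_mat.sum(axis=0)
        a = log_data + log_prior - logq
        amax = a.max()
        w = np.exp(a - amax)
        sw = w.sum()
        loglik = amax + np.log(sw / M)
        wn = w / sw
        grad_beta = X.T @ (y * 1.0 - mu_mat @ wn)
        # theta gradient: sum_k wn_k [0.5 A_k' dS A_k - 0.5 tr(Sigma^-1 dS)]
        sigma_inv = cho_solve((L, True), np.eye(n))
        grads_theta = np.empty(len(theta))
        for j, dS in enumerate(cov_model.derivs(theta)):
            quad_j = np.sum(A * (dS @ A), axis=0)
            tr_j = np.sum(sigma_inv * dS)
            grads_theta[j] = wn @ (0.5 * quad_j) - 0.5 * tr_j
        grad = np.concatenate([grad_beta, grads_theta])
        return -loglik, -grad

    return fun


def mc_loglik(y, X, offset, cov_model, beta, theta, n_samples, seed) -> tuple[float, float]:
    """Importance-sampling estimate of the marginal log-likelihood and its MC standard error.

    Uses the Laplace approximation at (beta, theta) as importance density.
    The standard error is the delta-method error of log(mean weight).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    beta = np.atleast_1d(np.asarray(beta, float))
    theta = np.atleast_1d(np.asarray(theta, float))
    sigma = cov_model.build(theta)
    L = cholesky_with_jitter(sigma)
    sigma_inv = cho_solve((L, True), np.eye(len(y)))
    m, mu_hat = _laplace_mode(y, X, offset, beta, sigma_inv)
    H = sigma_inv + np.diag(mu_hat)
    rng = np.random.default_rng(seed)
    T, logq = _draw_importance(m, H, n_samples, rng)
    fun = _mc_objective_factory(y, X, offset, cov_model, T, logq)
    neg_ll, _ = fun(np.concatenate([beta, theta]))
    # recompute weights for the standard error
    n = len(y)
    eta0 = X @ beta + offset
    A = cho_solve((L, True), T)
    log_prior = -0.5 * (2 * np.sum(np.log(np.diag(L))) + n * _LOG2PI) - 0.5 * np.sum(T * A, axis=0)
    log_data = y @ eta0 + y @ T - np.exp(eta0[:, None] + T).sum(axis=0)
    a = log_data + log_prior - logq
    w = np.exp(a - a.max())
    se = w.std(ddof=1) / (w.mean() * np.sqrt(len(w)))
    return -neg_ll, float(se)


def fit_poisson_lgm(
    y,
    X,
    offset,
    cov_model,
    beta_init,
    theta_init,
    settings: MCSettings | None = None,
    theta_bounds=None,
) -> PoissonLGMFit:
    """MCML fit of y_i ~ Poisson(exp(x_i'beta + offset_i + T_i)), T ~ N(0, Sigma(theta)).

    ``theta_bounds`` are optional (low, high) pairs on the log-scale
    covariance parameters, used to keep the optimizer on a sane ridge.
    Raises :class:`NonConvergenceError` when the optimizer fails.
    """
    settings = settings or MCSettings()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    offset = np.broadcast_to(np.asarray(offset, dtype=float), y.shape).copy()
    p = X.shape[1]
    psi = np.concatenate([np.atleast_1d(beta_init).astype(float), np.atleast_1d(theta_init).astype(float)])
    bounds = [(None, None)] * p + (list(theta_bounds) if theta_bounds is not None else [(-12.0, 10.0)] * cov_model.n_params)

    rng = np.random.default_rng(settings.seed)
    n_info = settings.info_samples or settings.n_samples
    n_refresh = 0
    result = None
    fun_info = None

    # stage 0: restricted (REML-type) Laplace estimation of the covariance
    # parameters, integrating out the fixed effects.  Plain ML variance
    # components are biased low on a single field realization, which then
    # understates every spatially structured coefficient's uncertainty.
    beta_irls = psi[:p].copy()
    theta_bnds = bounds[p:]
    reml_res = maximize_reml(y, X, offset, cov_model, psi[p:], beta_irls, theta_bnds,
                             maxiter=settings.optimizer_maxiter)
    theta_hat = reml_res.x
    _, _, beta_joint, _ = reml_loglik_grad(y, X, offset, cov_model, theta_hat, beta_irls)
    psi = np.concatenate([beta_joint, theta_hat])
    # the Monte Carlo refreshes refine beta at the restricted theta estimate
    bounds = [(None, None)] * p + [(t, t) for t in theta_hat]

    def one_refresh(psi, n_samples):
        beta0, theta0 = psi[:p], psi[p:]
        sigma0 = cov_model.build(theta0)
        L0 = cholesky_with_jitter(sigma0)
        sigma0_inv = cho_solve((L0, True), np.eye(len(y)))
        m, mu_hat = _laplace_mode(y, X, offset, beta0, sigma0_inv, maxiter=settings.laplace_maxiter)
        H = sigma0_inv + np.diag(mu_hat)
        T, logq = _draw_importance(m, H, n_samples, rng)
        fun = _mc_objective_factory(y, X, offset, cov_model, T, logq)
        result = minimize(
            fun,
            psi,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": settings.optimizer_maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if not result.success and "ABNORMAL" in str(result.message):
            raise NonConvergenceError(f"MCML optimizer failed: {result.message}")
        return result, fun

    for refresh in range(settings.max_refresh):
        is_last = refresh == settings.max_refresh - 1
        result, fun = one_refresh(psi, n_info if is_last else settings.n_samples)
        new_psi = result.x
        rel_change = np.max(np.abs(new_psi - psi) / (np.abs(psi) + 0.05))
        psi = new_psi
        n_refresh = refresh + 1
        if rel_change < settings.rel_tol and not is_last:
            # converged: one final refresh at the info sample size so the
            # Hessian is taken at the maximizer of the final objective
            result, fun = one_refresh(psi, n_info)
            psi = result.x
            n_refresh += 1
            break
    fun_info = fun

    beta_hat, theta_hat = psi[:p], psi[p:]
    # latent summary at the estimate
    sigma_hat = cov_model.build(theta_hat)
    Lh = cholesky_with_jitter(sigma_hat)
    sigma_hat_inv = cho_solve((Lh, True), np.eye(len(y)))
    m_hat, mu_hat = _laplace_mode(y, X, offset, beta_hat, sigma_hat_inv, maxiter=settings.laplace_maxiter)
    H_hat = sigma_hat_inv + np.diag(mu_hat)
    latent_cov = np.linalg.inv(H_hat)

    loglik = -fun_info(psi)[0]

    # Wald covariance, block diagonal:
    #  - beta block: GLS-type (X' (W^-1 + Sigma)^-1 X)^-1 at the estimate,
    #    which propagates the full latent covariance (including its
    #    common-mode component) into the coefficient uncertainty;
    #  - theta block: inverse observed information of the restricted
    #    likelihood (central differences of its analytic gradient).
    working_cov = np.diag(1.0 / np.maximum(mu_hat, 1e-10)) + sigma_hat
    beta_info = X.T @ np.linalg.solve(working_cov, X)
    cov_beta = np.linalg.pinv(beta_info)  # pinv: collinear designs stay finite

    q = cov_model.n_params
    theta_info = np.empty((q, q))
    dbeta_dtheta = np.empty((q, p))
    for j in range(q):
        h = 1e-4 * (1.0 + abs(theta_hat[j]))
        ej = np.zeros(q)
        ej[j] = h
        _, gp2, _, _ = reml_loglik_grad(y, X, offset, cov_model, theta_hat + ej, beta_hat)
        _, gm2, _, _ = reml_loglik_grad(y, X, offset, cov_model, theta_hat - ej, beta_hat)
        theta_info[j] = -(gp2 - gm2) / (2.0 * h)
        # coefficient sensitivity to theta, for the plug-in correction below
        hb = 0.1 * (1.0 + abs(theta_hat[j]))
        ej_b = np.zeros(q)
        ej_b[j] = hb
        _, _, b_p, _ = reml_loglik_grad(y, X, offset, cov_model, theta_hat + ej_b, beta_hat)
        _, _, b_m, _ = reml_loglik_grad(y, X, offset, cov_model, theta_hat - ej_b, beta_hat)
        dbeta_dtheta[j] = (b_p - b_m) / (2.0 * hb)
    theta_info = 0.5 * (theta_info + theta_info.T)
    evals, evecs = np.linalg.eigh(theta_info)
    if np.any(evals <= 0):
        warnings.warn(
            "restricted-likelihood information not positive definite; clipping "
            "eigenvalues (flat covariance-parameter direction, interpret those CIs with care)",
            RuntimeWarning,
            stacklevel=2,
        )
        evals = np.maximum(evals, 1e-8 * max(evals.max(), 1.0))
    cov_theta = (evecs / evals) @ evecs.T
    # Propagate covariance-parameter uncertainty into the coefficient
    # covariance: sigma-point average of the GLS covariance over the
    # restricted-likelihood uncertainty of theta (width effect: e.g. an
    # underestimated field variance would otherwise understate every
    # spatially structured coefficient's SE), plus the first-order
    # Kass-Steffey location term.  Sigma-point steps are capped at 2 log
    # units per component so flat nuisance directions cannot explode.
    L_theta = np.linalg.cholesky(cov_theta + 1e-12 * np.eye(q))
    sigma_cov_sum = np.zeros((p, p))
    n_pts = 0
    for j in range(q):
        step = np.clip(L_theta[:, j], -2.0, 2.0)
        for sgn in (+1.0, -1.0):
            theta_s = np.clip(
                theta_hat + sgn * step,
                [b[0] for b in theta_bnds],
                [b[1] for b in theta_bnds],
            )
            sigma_s = cov_model.build(theta_s)
            _, _, _, m_s = reml_loglik_grad(y, X, offset, cov_model, theta_s, beta_hat)
            mu_s = np.exp(np.clip(X @ beta_hat + offset + m_s, -40, 40))
            wc_s = np.diag(1.0 / np.maximum(mu_s, 1e-10)) + sigma_s
            sigma_cov_sum += np.linalg.pinv(X.T @ np.linalg.solve(wc_s, X))
            n_pts += 1
    cov_beta = sigma_cov_sum / n_pts + dbeta_dtheta.T @ cov_theta @ dbeta_dtheta
    cov = np.zeros((p + q, p + q))
    cov[:p, :p] = cov_beta
    cov[p:, p:] = cov_theta

    expected_count = float(np.exp(X @ beta_hat + offset + m_hat + 0.5 * np.diag(latent_cov)).sum())
    return PoissonLGMFit(
        beta=beta_hat,
        theta=theta_hat,
        cov=cov,
        loglik=float(loglik),
        latent_mean=m_hat,
        latent_cov=latent_cov,
        n_refresh=n_refresh,
        converged=bool(result.success) if result is not None else False,
        settings=settings,
        diagnostics={
            "expected_count": expected_count,
            "observed_count": float(y.sum()),
            "optimizer_message": str(result.message) if result is not None else "",
            "reml_loglik": float(-reml_res.fun),
            "reml_converged": bool(reml_res.success),
        },
    )


def poisson_irls(y, X, offset, maxiter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Poisson GLM coefficients by IRLS; used to initialize MCML."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3)) - offset.mean()
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-10)
        WX = X * W[:, None]
        A = X.T @ WX
        new = np.linalg.lstsq(A + 1e-9 * np.trace(A) * np.eye(X.shape[1]),
                              WX.T @ z, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta
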