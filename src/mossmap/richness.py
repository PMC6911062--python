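"""Geostatistical Poisson models of species richness for the two sources.

Species richness counts Y_j(x_i, t_i) are conditionally independent
Poisson given a spatial Gaussian field U_j(x) (exponential correlation,
variance nu_j^2, scale psi_j) and per-record Gaussian noise Z_j
(nugget variance tau_j^2).  For the opportunistic source (CSD):

    log mu_CSD = beta0 + beta1*W + beta2*V + beta3*F + beta4*log(C)
                 + f(t) + gamma*S_hat(x) + U_CSD(x) + Z_CSD,

with C the number of collectors, f(t) a cubic B-spline in the survey
year and gamma*S_hat(x) the plug-in preferential-sampling adjustment
(S_hat is the predictive mean of the sampling-process field, entered as
a fixed covariate; its estimation uncertainty is not propagated).  For
the randomized source (RSD):

    log mu_RSD = beta0 + beta1*W + beta2*V + beta3*F + beta5*(t - 1997)
                 + U_RSD(x) + Z_RSD.

Records are point-referenced but covariates and the latent field live at
cell resolution: records inherit their cell's W, V, F and share the
cell's U value, while each record gets its own nugget draw.

Fitting is by Monte Carlo maximum likelihood with Wald confidence
intervals (see :mod:`mossmap._mcml`).  Prediction surfaces target
mu_j(x, t) = exp(eta + U_j(x)) — the nugget is record-level noise and is
excluded by default — with the lognormal predictive mean and standard
error derived from the kriged conditional distribution of U_j.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from . import gp_core, region
from ._mcml import (
    ExponentialNuggetCovariance,
    MCSettings,
    fit_poisson_lgm,
    poisson_irls,
)
from .gp_core import ExponentialParams
from .lgcp import SHatSurface
from .region import CovariateSurface, Grid

__all__ = [
    "RichnessRecord",
    "SplineSpec",
    "CSDModelParams",
    "RSDModelParams",
    "RichnessFit",
    "PredictionSurface",
    "spline_basis",
    "linear_predictor_csd",
    "linear_predictor_rsd",
    "fit_richness",
    "predict_mu",
    "read_records",
    "write_fit_json",
]

#: latent variances below this are treated as exactly zero in prediction
_ZERO_VAR = 1e-12

RSD_REFERENCE_YEAR = 1997  # the linear time effect is centered at t - 1997


@dataclass(frozen=True)
class RichnessRecord:
    """One survey event: location (km), year, collector count, species count, source."""

    location: tuple[float, float]
    year: int
    collectors: int
    count: int
    source: str  # "CSD" or "RSD"

    def __post_init__(self) -> None:
        if self.source not in ("CSD", "RSD"):
            raise ValueError(f"source must be CSD or RSD, got {self.source!r}")
        if self.source == "CSD" and self.collectors < 1:
            raise ValueError("CSD records need a positive collector count")
        if self.count < 0:
            raise ValueError("species count must be non-negative")


@dataclass(frozen=True)
class SplineSpec:
    """Cubic B-spline specification for the CSD time effect f(t).

    Interior knots default to the study values (1990, 1995, 2000, 2002,
    2004, 2006); boundary knots clamp the basis at the data range.
    """

    knots: tuple = (1990, 1995, 2000, 2002, 2004, 2006)
    degree: int = 3
    boundary: tuple[float, float] = (1985, 2009)

    def __post_init__(self) -> None:
        ks = np.asarray(self.knots, float)
        if np.any(np.diff(ks) <= 0):
            raise ValueError("knots must be strictly increasing")
        lo, hi = self.boundary
        if not (lo < ks[0] and ks[-1] < hi):
            raise ValueError("interior knots must lie strictly inside the boundary")

    @property
    def n_basis(self) -> int:
        return len(self.knots) + self.degree + 1

    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[[lo] * (self.degree + 1), self.knots, [hi] * (self.degree + 1)]


def spline_basis(years, spec: SplineSpec) -> np.ndarray:
    """Full cubic B-spline design matrix at ``years`` (rows sum to 1).

    The basis spans the constant function, so one column must be dropped
    (or absorbed into the intercept) when used alongside an intercept;
    :func:`fit_richness` drops the first column.  Years outside the
    boundary raise (no extrapolation).
    """
    years = np.atleast_1d(np.asarray(years, float))
    lo, hi = spec.boundary
    if np.any(years < lo) or np.any(years > hi):
        raise ValueError(f"years outside spline boundary [{lo}, {hi}]")
    t = spec.knot_vector()
    # the right boundary point belongs to the last basis function (clamped knots)
    x = np.minimum(years, hi - 1e-9 * max(1.0, abs(hi)))
    return BSpline.design_matrix(x, t, spec.degree).toarray()


@dataclass(frozen=True)
class CSDModelParams:
    """Parameters of the opportunistic-source (CSD) model."""

    beta0: float
    beta1: float  # wetness W
    beta2: float  # value of nature V
    beta3: float  # forest cover F
    beta4: float  # log collector count
    gamma: float  # preferential-sampling adjustment on S_hat
    spline_coefs: np.ndarray  # coefficients of the dropped-first-column basis
    field: ExponentialParams
    nugget: float

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        object.__setattr__(self, "spline_coefs", np.asarray(self.spline_coefs, float))


@dataclass(frozen=True)
class RSDModelParams:
    """Parameters of the randomized-source (RSD) model."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta5: float  # linear effect on t - 1997
    field: ExponentialParams
    nugget: float

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")


def linear_predictor_csd(record: RichnessRecord, covars, shat: float, params: CSDModelParams,
                         spec: SplineSpec | None = None) -> float:
    """Fixed-effects linear predictor eta for one CSD record.

    ``covars`` is a (W, V, F) triple at the record's cell.  The latent U
    and nugget Z are added by the likelihood layer, not here.
    """
    if record.collectors < 1:
        raise ValueError("collector count must be >= 1")
    spec = spec or SplineSpec()
    W, V, F = covars
    basis = spline_basis([record.year], spec)[0, 1:]
    return float(
        params.beta0
        + params.beta1 * W
        + params.beta2 * V
        + params.beta3 * F
        + params.beta4 * np.log(record.collectors)
        + basis @ params.spline_coefs
        + params.gamma * shat
    )


def linear_predictor_rsd(record: RichnessRecord, covars, params: RSDModelParams) -> float:
    """Fixed-effects linear predictor eta for one RSD record (time centered at 1997)."""
    W, V, F = covars
    return float(
        params.beta0
        + params.beta1 * W
        + params.beta2 * V
        + params.beta3 * F
        + params.beta5 * (record.year - RSD_REFERENCE_YEAR)
    )


@dataclass
class RichnessFit:
    """Fitted richness model for one source, with Wald CIs and the latent posterior.

    Reported names mirror the usual table layout: regression coefficients
    on the natural scale; the exponential field's variance nu^2, scale
    psi and nugget tau^2 on the log scale as ``log_sigma2``, ``log_phi``,
    ``log_tau2``.
    """

    source: str
    estimates: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    column_names: list[str]
    beta: np.ndarray
    theta: np.ndarray  # (log nu2, log psi, log tau2)
    latent_mean: np.ndarray  # posterior mean of T = U + Z at records
    latent_cov: np.ndarray
    record_cells: np.ndarray  # cell-center coordinates of each record
    spline: SplineSpec | None
    grid: Grid
    loglik: float
    settings: dict
    wald_cov: np.ndarray = None
    gamma_dropped: bool = False
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def field(self) -> ExponentialParams:
        nu2, psi, _ = np.exp(self.theta)
        return ExponentialParams(variance=float(nu2), scale=float(psi))

    @property
    def nugget(self) -> float:
        return float(np.exp(self.theta[2]))

    def spline_effect(self, years) -> np.ndarray:
        """Fitted f(t), reported relative to its 1997-1999 mean (identifiability)."""
        if self.spline is None:
            raise ValueError("no spline term in this model")
        cols = [c for c in self.column_names if c.startswith("spline_")]
        coefs = self.beta[[self.column_names.index(c) for c in cols]]
        f = spline_basis(years, self.spline)[:, 1:] @ coefs
        ref = spline_basis([1997, 1998, 1999], self.spline)[:, 1:] @ coefs
        return f - ref.mean()


@dataclass(frozen=True)
class PredictionSurface:
    """Gridded predictive mean, standard error and coefficient of variation of mu_j(x, t)."""

    grid: Grid
    year: int
    collectors: int | None
    mean: np.ndarray  # flat per cell, NaN where covariates are missing
    se: np.ndarray
    cov: np.ndarray  # se / mean


def _build_design(df, surfaces, shat, model, spec, grid):
    """Design matrix, column names, record cell centers and gamma-column index."""
    pts = df[["x", "y"]].to_numpy(float)
    W = region.covariate_at(pts, surfaces["W"])
    V = region.covariate_at(pts, surfaces["V"])
    F = region.covariate_at(pts, surfaces["F"])
    if np.any(~np.isfinite(np.c_[W, V, F])):
        raise ValueError("records fall on cells with missing covariates")
    cols = [np.ones(len(df)), W, V, F]
    names = ["beta0", "beta1", "beta2", "beta3"]
    gamma_idx = None
    if model == "CSD":
        C = df["collectors"].to_numpy(float)
        if np.any(C < 1):
            raise ValueError("CSD records need collectors >= 1")
        cols.append(np.log(C))
        names.append("beta4")
        basis = spline_basis(df["year"].to_numpy(float), spec)[:, 1:]
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"spline_{j + 1}")
        if shat is None:
            raise ValueError("CSD fits need an S_hat surface (use zeros to fit unadjusted)")
        s_vals = shat.at(pts) if isinstance(shat, SHatSurface) else np.broadcast_to(
            np.asarray(shat, float), (len(df),)
        )
        if np.any(~np.isfinite(s_vals)):
            raise ValueError("S_hat missing at some record locations")
        cols.append(np.asarray(s_vals, float))
        names.append("gamma")
        gamma_idx = len(names) - 1
    else:
        cols.append(df["year"].to_numpy(float) - RSD_REFERENCE_YEAR)
        names.append("beta5")
    X = np.column_stack(cols)
    cell_idx = region.locate_cell(pts, grid)
    centers = grid.cell_centers()[np.atleast_1d(cell_idx)]
    return X, names, centers, gamma_idx


def fit_richness(
    records: pd.DataFrame,
    surfaces: dict[str, CovariateSurface],
    shat: SHatSurface | None,
    model: str,
    init=None,
    mc_settings: MCSettings | None = None,
    spline: SplineSpec | None = None,
) -> RichnessFit:
    """MCML fit of the CSD (with S_hat adjustment) or RSD richness model.

    ``records`` is a DataFrame with columns x, y, year, collectors,
    richness, source; only rows matching ``model`` are used.  If the
    supplied S_hat is identically zero its (all-zero) design column is
    dropped and gamma reported as exactly 0 — the adjustment is purely an
    extra regressor, so this reproduces the unadjusted fit.
    """
    if model not in ("CSD", "RSD"):
        raise ValueError("model must be 'CSD' or 'RSD'")
    df = records[records["source"] == model] if "source" in records.columns else records
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no {model} records")
    if len(df) < 30:
        warnings.warn(f"only {len(df)} {model} records; estimates will be unstable below ~30",
                      UserWarning, stacklevel=2)
    spec = spline or SplineSpec()
    grid = surfaces["W"].grid
    X, names, centers, gamma_idx = _build_design(df, surfaces, shat, model, spec, grid)

    gamma_dropped = False
    if gamma_idx is not None and np.allclose(X[:, gamma_idx], 0.0):
        X = np.delete(X, gamma_idx, axis=1)
        names = [n for i, n in enumerate(names) if i != gamma_idx]
        gamma_dropped = True

    # collinearity guard (e.g. a constant covariate surface)
    sd = X[:, 1:].std(axis=0)
    if np.any(sd < 1e-12):
        warnings.warn(
            f"collinear design for {model}: constant column(s) "
            f"{[names[1 + i] for i in np.flatnonzero(sd < 1e-12)]}",
            UserWarning, stacklevel=2,
        )

    y = df["richness"].to_numpy(float)
    offset = np.zeros(len(df))
    settings = mc_settings or MCSettings()
    if init is None:
        beta0 = poisson_irls(y, X, offset)
        theta0 = np.log([0.2, max(3.0 * grid.cell_size, 1.0), 0.1])
    else:
        beta0 = _init_beta(init, names)
        theta0 = np.log([init.field.variance, init.field.scale, max(init.nugget, 1e-4)])

    dist = gp_core.pairwise_distances(centers)
    cov_model = ExponentialNuggetCovariance(dist)
    extent = grid.extent
    max_range = np.hypot(extent[2] - extent[0], extent[3] - extent[1])
    theta_bounds = [(-10.0, 6.0), (np.log(grid.cell_size / 4.0), np.log(4.0 * max_range)), (-10.0, 6.0)]
    raw = fit_poisson_lgm(y, X, offset, cov_model, beta0, theta0, settings, theta_bounds)

    theta_names = ["log_sigma2", "log_phi", "log_tau2"]
    all_names = names + theta_names
    ci = raw.wald_ci()
    est = dict(zip(all_names, raw.params))
    lo = dict(zip(all_names, ci[:, 0]))
    hi = dict(zip(all_names, ci[:, 1]))
    if gamma_dropped:
        est["gamma"], lo["gamma"], hi["gamma"] = 0.0, 0.0, 0.0
    return RichnessFit(
        source=model,
        estimates=est,
        ci_low=lo,
        ci_high=hi,
        column_names=names,
        beta=raw.beta,
        theta=raw.theta,
        latent_mean=raw.latent_mean,
        latent_cov=raw.latent_cov,
        record_cells=centers,
        spline=spec if model == "CSD" else None,
        grid=grid,
        loglik=raw.loglik,
        settings={
            "model": model,
            "n_records": len(df),
            "n_samples": settings.n_samples,
            "max_refresh": settings.max_refresh,
            "n_refresh_used": raw.n_refresh,
            "seed": settings.seed,
            "spline_knots": list(spec.knots) if model == "CSD" else None,
            "gamma_dropped": gamma_dropped,
        },
        wald_cov=raw.cov,
        gamma_dropped=gamma_dropped,
        diagnostics=raw.diagnostics,
    )


def _init_beta(init, names) -> np.ndarray:
    vals = []
    for n in names:
        if n.startswith("spline_"):
            vals.append(float(init.spline_coefs[int(n.split("_")[1]) - 1]))
        elif n == "gamma":
            vals.append(init.gamma)
        elif n == "beta5":
            vals.append(init.beta5)
        else:
            vals.append(getattr(init, n))
    return np.array(vals, float)


def predict_mu(
    fit: RichnessFit,
    grid: Grid,
    year: int,
    collectors: int | None,
    surfaces: dict[str, CovariateSurface],
    shat: SHatSurface | None = None,
    include_param_uncertainty: bool = False,
    include_nugget: bool = False,
) -> PredictionSurface:
    """Predictive mean/SE surface of mu_j(x, t) = exp(eta + U_j(x)) on a grid.

    The nugget Z is excluded by default (record-level noise; the target is
    the smooth mean surface); ``include_nugget`` adds tau^2/2 to the
    log-mean.  ``include_param_uncertainty`` adds the delta-method Wald
    term for the regression coefficients to the standard error.
    """
    active = grid.active()
    centers = grid.cell_centers()
    W = surfaces["W"].values
    V = surfaces["V"].values
    F = surfaces["F"].values
    cols = {"beta0": np.ones(grid.n_cells), "beta1": W, "beta2": V, "beta3": F}
    if fit.source == "CSD":
        if collectors is None or collectors < 1:
            raise ValueError("CSD prediction needs collectors >= 1")
        cols["beta4"] = np.full(grid.n_cells, np.log(collectors))
        basis = spline_basis([year], fit.spline)[0, 1:]
        for j, b in enumerate(basis):
            cols[f"spline_{j + 1}"] = np.full(grid.n_cells, b)
        if not fit.gamma_dropped:
            if shat is None:
                raise ValueError("CSD prediction needs the S_hat surface used in the fit")
            cols["gamma"] = shat.values
    else:
        cols["beta5"] = np.full(grid.n_cells, float(year - RSD_REFERENCE_YEAR))
    Xp = np.column_stack([cols[n] for n in fit.column_names])
    eta = Xp @ fit.beta
    missing = ~np.isfinite(eta) | ~active

    nu2, psi, tau2 = np.exp(fit.theta)
    n_rec = len(fit.record_cells)
    if nu2 > _ZERO_VAR:
        expo = ExponentialParams(variance=float(nu2), scale=float(psi))
        sigma_T = gp_core.build_covariance(fit.record_cells, expo, nugget=float(tau2))
        factor = cho_factor(sigma_T + 1e-10 * nu2 * np.eye(n_rec), lower=True)
        cross = nu2 * np.exp(-gp_core.pairwise_distances(centers, fit.record_cells) / psi)
        sol_m = cho_solve(factor, fit.latent_mean)
        m_u = cross @ sol_m
        SinvC = cho_solve(factor, cross.T)  # (n_rec, n_cells)
        v_shrink = np.sum(cross.T * SinvC, axis=0)
        v_post = np.sum(SinvC * (fit.latent_cov @ SinvC), axis=0)
        v_u = np.maximum(nu2 - v_shrink + v_post, 0.0)
    else:
        m_u = np.zeros(grid.n_cells)
        v_u = np.zeros(grid.n_cells)
    if tau2 <= _ZERO_VAR:
        tau2 = 0.0

    log_mean = eta + m_u + 0.5 * v_u + (0.5 * tau2 if include_nugget else 0.0)
    mean = np.exp(log_mean)
    var = mean**2 * np.expm1(v_u)
    if include_param_uncertainty:
        vb = fit.wald_cov[: len(fit.beta), : len(fit.beta)]
        var = var + mean**2 * np.sum((Xp @ vb) * Xp, axis=1)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cov_coef = np.where(mean > 0, se / mean, np.nan)
    mean[missing] = np.nan
    se[missing] = np.nan
    cov_coef[missing] = np.nan
    return PredictionSurface(grid=grid, year=int(year), collectors=collectors,
                             mean=mean, se=se, cov=cov_coef)


# ---------------------------------------------------------------------------
# I/O


def read_records(path, units: str = "km") -> pd.DataFrame:
    """Survey records from delimited text: x, y, year, collectors, richness, source."""
    df = pd.read_csv(path)
    required = {"x", "y", "year", "richness", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"records file needs columns {sorted(required)}, got {list(df.columns)}")
    if "collectors" not in df.columns:
        df["collectors"] = 1
    df["collectors"] = df["collectors"].fillna(1).astype(int)
    if units == "m":
        df[["x", "y"]] = df[["x", "y"]] * 1e-3
    return df


def write_fit_json(fit: RichnessFit, path) -> None:
    """Fit summary as JSON mirroring the usual reporting layout."""
    out = {
        "model": f"richness_{fit.source.lower()}",
        "parameters": {
            name: {
                "estimate": fit.estimates[name],
                "ci_low": fit.ci_low[name],
                "ci_high": fit.ci_high[name],
            }
            for name in fit.estimates
        },
        "loglik": fit.loglik,
        "settings": fit.settings,
        "diagnostics": fit.diagnostics,
    }
    Path(path).write_text(json.dumps(out, indent=1, default=float))
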