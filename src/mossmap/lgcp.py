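"""Log-Gaussian Cox process model of the opportunistic sampling locations.

The citizen collectors' choice of sampling locations is modelled as a
Cox process with intensity

    Lambda(x) = exp{alpha0 + alpha1 * D(x) + alpha2 * V(x) + S(x)},

where D(x) is the distance (km) to the collectors' home, V(x) the value
of nature in [0, 1] and S(x) a zero-mean stationary Gaussian field with
Matérn correlation (smoothness kappa fixed at 1, since it cannot be
estimated consistently under in-fill asymptotics).

The latent field is discretized to one value per grid cell and the point
pattern reduced to cell counts, giving the conditional likelihood

    count_c | S ~ Poisson(area_c * exp(alpha0 + alpha1 D_c + alpha2 V_c + S_c)),

which the grid refines toward the continuous process.  Parameters are
estimated by Monte Carlo maximum likelihood (Laplace-based importance
sampling, see :mod:`mossmap._mcml`); confidence intervals are Wald
intervals from the observed information of the Monte Carlo objective.
The fitted field's predictive mean, S_hat(x), is the plug-in
preferential-sampling adjustment used by the richness models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gp_core, region
from ._mcml import MCSettings, MaternCovariance, fit_poisson_lgm, poisson_irls
from .gp_core import FieldRealization, MaternParams
from .region import CovariateSurface, Grid, HomeLocation

__all__ = [
    "PointPattern",
    "LGCPParams",
    "LGCPFit",
    "SHatSurface",
    "bin_points",
    "lgcp_loglik",
    "fit_lgcp",
    "predict_shat",
    "intensity_ratio",
    "read_point_pattern",
    "write_fit_json",
]


class MaskedCellError(ValueError):
    """A point falls inside the extent but in a masked (outside-region) cell."""


@dataclass(frozen=True)
class PointPattern:
    """Sampling locations (km) of the opportunistic source, with the survey period."""

    locations: np.ndarray  # (n, 2)
    period: tuple[int, int] = (1985, 2009)

    def __post_init__(self) -> None:
        object.__setattr__(self, "locations", np.atleast_2d(np.asarray(self.locations, float)))

    def __len__(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class LGCPParams:
    """Intensity parameters (alpha0, alpha1 per km of D, alpha2 on V) and the Matérn field."""

    alpha0: float
    alpha1: float
    alpha2: float
    field: MaternParams

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha0, self.alpha1, self.alpha2])


@dataclass
class LGCPFit:
    """Fitted LGCP: estimates with 95% CIs, per-cell latent summary, and settings used.

    ``estimates``/``ci_low``/``ci_high`` are keyed by parameter name;
    coefficients are on the natural scale, variance and scale on the log
    scale (log_sigma2, log_phi), mirroring how such fits are reported.
    """

    estimates: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    latent_mean: np.ndarray  # per active cell
    latent_var: np.ndarray
    latent_cov: np.ndarray
    grid: Grid
    cell_centers: np.ndarray  # active-cell centers the latent field lives on
    loglik: float
    settings: dict
    wald_cov: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> LGCPParams:
        e = self.estimates
        return LGCPParams(
            alpha0=e["alpha0"],
            alpha1=e["alpha1"],
            alpha2=e["alpha2"],
            field=MaternParams(
                variance=float(np.exp(e["log_sigma2"])),
                scale=float(np.exp(e["log_phi"])),
                smoothness=self.settings.get("kappa", 1.0),
            ),
        )

    def expected_count(self) -> float:
        return self.diagnostics["expected_count"]


@dataclass(frozen=True)
class SHatSurface:
    """Predictive mean S_hat(x) of the LGCP latent field, per grid cell."""

    grid: Grid
    values: np.ndarray  # flat, NaN on masked cells

    def at(self, points) -> np.ndarray:
        idx = region.locate_cell(points, self.grid)
        return self.values[np.atleast_1d(idx)]


def bin_points(pattern: PointPattern, grid: Grid) -> np.ndarray:
    """Per-cell counts of the point pattern (flat, all cells, zeros included).

    Points in masked cells raise :class:`MaskedCellError` listing the
    offending record indices.
    """
    if len(pattern) == 0:
        return np.zeros(grid.n_cells, dtype=int)
    idx = region.locate_cell(pattern.locations, grid)
    if grid.mask is not None:
        bad = ~grid.active()[idx]
        if np.any(bad):
            raise MaskedCellError(
                f"points in masked cells at indices {np.flatnonzero(bad).tolist()}"
            )
    return np.bincount(idx, minlength=grid.n_cells)


def lgcp_loglik(params: LGCPParams, counts, D, V, latent, grid: Grid) -> float:
    """Conditional Poisson log-likelihood of cell counts given the latent field.

    Cell c contributes ``count_c * eta_c - area_c * exp(eta_c)`` with
    ``eta_c = alpha0 + alpha1 D_c + alpha2 V_c + S_c``; the count-factorial
    constant is dropped (consistently with every other likelihood here).
    """
    counts = np.asarray(counts, float)
    eta = params.alpha0 + params.alpha1 * np.asarray(D, float) + params.alpha2 * np.asarray(V, float) + np.asarray(latent, float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor in LGCP likelihood")
    area = grid.cell_area
    return float(np.sum(counts * (np.log(area) + eta) - area * np.exp(eta)))


def intensity_ratio(coef: float, delta: float = 1.0) -> float:
    """Multiplicative change in sampling intensity for a ``delta`` covariate change."""
    return float(np.exp(coef * delta))


_ALPHA_NAMES = ("alpha0", "alpha1", "alpha2")
_THETA_NAMES = ("log_sigma2", "log_phi")


def fit_lgcp(
    pattern: PointPattern,
    value_surface: CovariateSurface,
    grid: Grid,
    home: HomeLocation,
    init: LGCPParams | None = None,
    mc_settings: MCSettings | None = None,
    kappa: float = 1.0,
    refine: int = 1,
) -> LGCPFit:
    """Fit the LGCP by MCML on a regular-grid discretization.

    ``refine`` subdivides the covariate grid for the latent-field
    discretization (cells ``refine`` times smaller); covariates stay at
    their native cell resolution, distance-to-home is evaluated at the
    refined cell centers.
    """
    if len(pattern) < 30:
        warnings.warn(
            f"only {len(pattern)} points; LGCP estimates will be unstable below ~30",
            UserWarning,
            stacklevel=2,
        )
    fit_grid = grid.refine(refine) if refine != 1 else grid
    counts_all = bin_points(pattern, fit_grid)
    active = fit_grid.active()
    centers = fit_grid.cell_centers()[active]
    counts = counts_all[active]
    D = region.distance_to_home(centers, home)
    V = region.covariate_at(centers, value_surface)
    if np.any(~np.isfinite(V)):
        raise ValueError("value-of-nature covariate missing on unmasked cells")
    X = np.column_stack([np.ones(len(centers)), D, V])
    offset = np.full(len(centers), np.log(fit_grid.cell_area))

    settings = mc_settings or MCSettings()
    if init is None:
        beta0 = poisson_irls(counts, X, offset)
        theta0 = np.array([np.log(0.5), np.log(max(3.0 * fit_grid.cell_size, 1.0))])
    else:
        beta0 = init.as_array()
        theta0 = np.log([init.field.variance, init.field.scale])

    cov_model = MaternCovariance(gp_core.pairwise_distances(centers), kappa=kappa)
    extent = fit_grid.extent
    max_range = np.hypot(extent[2] - extent[0], extent[3] - extent[1])
    theta_bounds = [(-8.0, 6.0), (np.log(fit_grid.cell_size / 4.0), np.log(2.0 * max_range))]
    raw = fit_poisson_lgm(counts, X, offset, cov_model, beta0, theta0, settings, theta_bounds)

    names = list(_ALPHA_NAMES) + list(_THETA_NAMES)
    ci = raw.wald_ci()
    est = dict(zip(names, raw.params))
    return LGCPFit(
        estimates=est,
        ci_low=dict(zip(names, ci[:, 0])),
        ci_high=dict(zip(names, ci[:, 1])),
        latent_mean=raw.latent_mean,
        latent_var=np.diag(raw.latent_cov).copy(),
        latent_cov=raw.latent_cov,
        grid=fit_grid,
        cell_centers=centers,
        loglik=raw.loglik,
        settings={
            "kappa": kappa,
            "refine": refine,
            "n_samples": settings.n_samples,
            "max_refresh": settings.max_refresh,
            "n_refresh_used": raw.n_refresh,
            "seed": settings.seed,
            "discretization": "regular-grid cell counts (one latent value per cell)",
        },
        wald_cov=raw.cov,
        diagnostics=raw.diagnostics,
    )


def predict_shat(fit: LGCPFit, targets=None) -> SHatSurface:
    """Predictive mean S_hat at grid cells (default: the fit grid) by kriging.

    On the fit grid itself the latent Laplace mean is returned directly;
    other targets are kriged from it with the fitted Matérn parameters
    via :func:`mossmap.gp_core.conditional_mean_field`.
    """
    observed = FieldRealization(locations=fit.cell_centers, values=fit.latent_mean)
    if targets is None or targets is fit.grid:
        grid = fit.grid
        values = np.full(grid.n_cells, np.nan)
        values[grid.active()] = fit.latent_mean
        return SHatSurface(grid=grid, values=values)
    if isinstance(targets, Grid):
        centers = targets.cell_centers()[targets.active()]
        vals = gp_core.conditional_mean_field(observed, centers, fit.params.field)
        values = np.full(targets.n_cells, np.nan)
        values[targets.active()] = vals
        return SHatSurface(grid=targets, values=values)
    # coordinate-list targets: return the kriged values directly
    return gp_core.conditional_mean_field(observed, targets, fit.params.field)


# ---------------------------------------------------------------------------
# I/O


def read_point_pattern(path, period: tuple[int, int] | None = None, units: str = "km") -> PointPattern:
    """Read a point pattern from delimited text with columns x, y, year (km easting/northing)."""
    df = pd.read_csv(path)
    required = {"x", "y", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"point-pattern file needs columns {sorted(required)}, got {list(df.columns)}")
    scale = 1e-3 if units == "m" else 1.0
    locs = df[["x", "y"]].to_numpy(float) * scale
    if period is None:
        period = (int(df["year"].min()), int(df["year"].max()))
    return PointPattern(locations=locs, period=period)


def write_fit_json(fit: LGCPFit, path) -> None:
    """Fit summary as JSON: per-parameter estimate and CI, log-likelihood, settings."""
    out = {
        "model": "lgcp",
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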