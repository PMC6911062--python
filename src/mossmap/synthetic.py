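"""Synthetic study generator with the generative structure the analysis assumes.

Generates complete desk-scale studies: smooth correlated covariate
surfaces W, V, F in [0, 1]; an opportunistic (CSD) point pattern drawn
from a log-Gaussian Cox process concentrated near the collectors' home
and in high-V cells; a forest-restricted, randomly offset lattice (RSD)
design; and conditionally Poisson richness counts for both sources.

Preferential dependence is injected through the *true* latent sampling
field S (coefficient ``gamma``), while the analysis pipeline can only
use the estimated S_hat — recovery of gamma is therefore attenuated by
construction, exactly as in a real study.

The default region is 30 x 30 cells of 1 km (desk scale); the CSD spans
1985-2009 with 1-3 collectors per visit (mode 2), the RSD 1997-1999.
Everything is reproducible from the scenario seed.  Generators draw
fields through :mod:`mossmap.gp_core` simulation primitives but never
touch any fitting code path.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import region as region_mod
from .gp_core import ExponentialParams, MaternParams, build_covariance, cholesky_with_jitter
from .lgcp import PointPattern
from .region import CovariateSurface, Grid, HomeLocation, make_grid
from .richness import SplineSpec, spline_basis

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "gen_covariates",
    "gen_csd",
    "gen_rsd",
    "gen_scenario",
    "preset",
    "PRESETS",
]

MAX_EXPECTED_POINTS = 1_000_000


@dataclass
class ScenarioConfig:
    """Complete generative description of one synthetic study.

    LGCP truth (alpha0, alpha1, alpha2, sigma2, phi) drives the CSD
    sampling locations; the CSD/RSD truth dictionaries hold the richness
    model parameters of the respective linear predictors and exponential
    latent fields.
    """

    bbox: tuple = (0.0, 0.0, 30.0, 30.0)
    cell_size: float = 1.0
    home: tuple = (5.0, 15.0)
    csd_period: tuple = (1985, 2009)
    rsd_period: tuple = (1997, 1999)
    # LGCP truth for the sampling process
    alpha0: float = -1.0
    alpha1: float = -0.1  # per km of distance to home
    alpha2: float = 1.5  # on value of nature V
    lgcp_sigma2: float = 0.5
    lgcp_phi: float = 3.0
    kappa: float = 1.0
    # CSD richness truth
    csd_beta: tuple = (1.0, 0.6, -0.3, 0.9)  # intercept, W, V, F
    beta4: float = 1.9  # log collector count
    gamma: float = 0.0  # preferential dependence on the TRUE field S
    spline_coefs: tuple = (0.0, 0.1, 0.2, 0.25, 0.2, 0.15, 0.1, 0.05, 0.0)
    csd_nu2: float = 0.15
    csd_psi: float = 5.0
    csd_tau2: float = 0.05
    # RSD richness truth
    rsd_beta: tuple = (1.5, -0.3, 0.4, 0.2)
    beta5: float = -0.08  # per year, centered at 1997
    rsd_nu2: float = 0.1
    rsd_psi: float = 13.0
    rsd_tau2: float = 0.04
    # design knobs
    forest_threshold: float = 0.5
    lattice_spacing: float = 1.0
    collector_probs: tuple = (0.1, 0.8, 0.1)  # P(C=1), P(C=2), P(C=3)
    covariate_scale: float = 5.0  # km, smoothness of W/V/F
    covariate_corr: tuple = (0.1, 0.3, 0.3)  # corr(W,V), corr(W,F), corr(V,F)
    seed: int = 0

    def grid(self) -> Grid:
        return make_grid(self.bbox, self.cell_size)

    def spline_spec(self) -> SplineSpec:
        return SplineSpec(boundary=(self.csd_period[0], self.csd_period[1]))

    def rng(self, stage: int) -> np.random.Generator:
        # one independent stream per stage so stages can be rerun in isolation
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class ScenarioBundle:
    """Everything one synthetic study produces, plus the generative truth."""

    config: ScenarioConfig
    grid: Grid
    covariates: dict
    pattern: PointPattern
    records: pd.DataFrame  # CSD and RSD rows, column `source`
    s_true: np.ndarray  # true LGCP latent field per cell
    truth: dict


def _correlated_fields(grid: Grid, scale: float, corr: tuple, rng) -> np.ndarray:
    """Three correlated smooth Gaussian fields at cell centers, (n_cells, 3)."""
    centers = grid.cell_centers()
    cov = build_covariance(centers, MaternParams(variance=1.0, scale=scale))
    L = cholesky_with_jitter(cov)
    a_wv, a_wf, a_vf = corr
    cross = np.array([[1.0, a_wv, a_wf], [a_wv, 1.0, a_vf], [a_wf, a_vf, 1.0]])
    La = np.linalg.cholesky(cross)
    z = rng.standard_normal((grid.n_cells, 3))
    return (L @ z) @ La.T


def gen_covariates(grid: Grid, seed, scale: float = 5.0,
                   corr: tuple = (0.1, 0.3, 0.3)) -> dict:
    """Smooth covariate surfaces W, V, F in [0, 1] (probit-transformed Gaussian fields)."""
    rng = np.random.default_rng(seed)
    fields = _correlated_fields(grid, scale, corr, rng)
    out = {}
    for j, name in enumerate(["W", "V", "F"]):
        vals = norm.cdf(fields[:, j])
        out[name] = CovariateSurface(grid=grid, name=name, values=vals)
    return out


def _simulate_cell_field(grid: Grid, params, rng) -> np.ndarray:
    cov = build_covariance(grid.cell_centers(), params)
    return cholesky_with_jitter(cov) @ rng.standard_normal(grid.n_cells)


def gen_csd(config: ScenarioConfig, covariates: dict, seed=None):
    """CSD locations from the LGCP truth and richness counts from the CSD model truth.

    Returns ``(pattern, records, s_true)``.  Counts use the *true* S
    (coefficient ``config.gamma``), the cell-shared latent U_CSD and a
    per-record nugget draw.
    """
    grid = config.grid()
    rng = np.random.default_rng(seed) if seed is not None else config.rng(1)
    centers = grid.cell_centers()
    s_true = _simulate_cell_field(
        grid, MaternParams(config.lgcp_sigma2, config.lgcp_phi, config.kappa), rng
    )
    D = region_mod.distance_to_home(centers, HomeLocation(config.home))
    V = covariates["V"].values
    lam = np.exp(config.alpha0 + config.alpha1 * D + config.alpha2 * V + s_true)
    lam = np.where(grid.active(), lam, 0.0)
    expected = float((grid.cell_area * lam).sum())
    if expected > MAX_EXPECTED_POINTS:
        raise ValueError(
            f"expected point count {expected:.3g} exceeds {MAX_EXPECTED_POINTS}; "
            "lower alpha0 or shrink the region"
        )
    counts = rng.poisson(grid.cell_area * lam)
    cell_idx = np.repeat(np.arange(grid.n_cells), counts)
    n = len(cell_idx)
    offsets = rng.uniform(0.0, grid.cell_size, size=(n, 2))
    lower_left = centers[cell_idx] - grid.cell_size / 2.0
    locs = lower_left + offsets
    pattern = PointPattern(locations=locs, period=config.csd_period)

    years = rng.integers(config.csd_period[0], config.csd_period[1] + 1, size=n)
    collectors = rng.choice([1, 2, 3], size=n, p=config.collector_probs)
    u_csd = _simulate_cell_field(
        grid, MaternParams(config.csd_nu2, config.csd_psi, 0.5), rng
    )  # kappa=1/2 Matérn == exponential correlation
    z = rng.normal(0.0, np.sqrt(config.csd_tau2), size=n)
    b0, b1, b2, b3 = config.csd_beta
    spec = config.spline_spec()
    f_t = spline_basis(years, spec)[:, 1:] @ np.asarray(config.spline_coefs, float)
    eta = (
        b0
        + b1 * covariates["W"].values[cell_idx]
        + b2 * covariates["V"].values[cell_idx]
        + b3 * covariates["F"].values[cell_idx]
        + config.beta4 * np.log(collectors)
        + f_t
        + config.gamma * s_true[cell_idx]
        + u_csd[cell_idx]
        + z
    )
    records = pd.DataFrame(
        {
            "x": locs[:, 0],
            "y": locs[:, 1],
            "year": years,
            "collectors": collectors,
            "richness": rng.poisson(np.exp(eta)),
            "source": "CSD",
        }
    )
    return pattern, records, s_true


def gen_rsd(config: ScenarioConfig, covariates: dict, seed=None) -> pd.DataFrame:
    """RSD records: randomly offset lattice restricted to forested cells, Poisson counts."""
    grid = config.grid()
    rng = np.random.default_rng(seed) if seed is not None else config.rng(2)
    x0, y0, x1, y1 = grid.extent
    sp = config.lattice_spacing
    off = rng.uniform(0.0, sp, size=2)
    xs = np.arange(x0 + off[0], x1, sp)
    ys = np.arange(y0 + off[1], y1, sp)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    cell_idx = region_mod.locate_cell(pts, grid)
    keep = grid.active()[cell_idx] & (covariates["F"].values[cell_idx] >= config.forest_threshold)
    pts, cell_idx = pts[keep], cell_idx[keep]
    if len(pts) == 0:
        raise ValueError("no lattice intersections pass the forest threshold")
    n = len(pts)
    years = rng.integers(config.rsd_period[0], config.rsd_period[1] + 1, size=n)
    u_rsd = _simulate_cell_field(grid, MaternParams(config.rsd_nu2, config.rsd_psi, 0.5), rng)
    z = rng.normal(0.0, np.sqrt(config.rsd_tau2), size=n)
    b0, b1, b2, b3 = config.rsd_beta
    eta = (
        b0
        + b1 * covariates["W"].values[cell_idx]
        + b2 * covariates["V"].values[cell_idx]
        + b3 * covariates["F"].values[cell_idx]
        + config.beta5 * (years - 1997)
        + u_rsd[cell_idx]
        + z
    )
    return pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "year": years,
            "collectors": np.nan,
            "richness": rng.poisson(np.exp(eta)),
            "source": "RSD",
        }
    )


def gen_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioBundle:
    """Generate a full study bundle; optionally write it in the analysis file formats.

    The written bundle contains the covariate .asc grids, the CSD point
    pattern, the combined records table, the resolved config and a truth
    JSON with every generative parameter (for recovery tests).
    """
    grid = config.grid()
    covs = gen_covariates(grid, config.rng(0), scale=config.covariate_scale,
                          corr=config.covariate_corr)
    pattern, csd_records, s_true = gen_csd(config, covs)
    rsd_records = gen_rsd(config, covs)
    records = pd.concat([csd_records, rsd_records], ignore_index=True)
    truth = asdict(config)
    bundle = ScenarioBundle(
        config=config, grid=grid, covariates=covs, pattern=pattern,
        records=records, s_true=s_true, truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            for name, surf in covs.items():
                region_mod.write_ascii_grid(out / f"{name}.asc", grid, surf.values)
            pd.DataFrame(
                {"x": pattern.locations[:, 0], "y": pattern.locations[:, 1],
                 "year": csd_records["year"]}
            ).to_csv(out / "csd_points.csv", index=False)
            records.to_csv(out / "records.csv", index=False)
            (out / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
            (out / "config.json").write_text(json.dumps(asdict(config), indent=1, default=float))
            region_mod.write_ascii_grid(out / "s_true.asc", grid, s_true)
        except Exception:
            shutil.rmtree(out, ignore_errors=True)
            raise
    return bundle


PRESETS = {
    "nonpreferential": {"gamma": 0.0},
    "preferential": {"gamma": 0.5},
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """Packaged scenario presets: 'nonpreferential' (gamma=0) and 'preferential' (gamma=0.5)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
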