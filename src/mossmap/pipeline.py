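"""End-to-end orchestration: simulate/load -> LGCP -> richness fits -> predict -> compare.

A single :class:`RunConfig` drives the whole analysis.  The global seed
fans out to per-stage seeds through ``numpy.random.SeedSequence(seed).spawn``
(stage order: simulate, lgcp, csd fit, rsd fit), so any stage can be
rerun in isolation and a rerun with the same config is bit-reproducible.

Outputs land in a run directory: fit summaries as JSON, surfaces as
ESRI ASCII grids, the resolved configuration, and a plain-text log with
ISO timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import comparison, lgcp, region, richness, synthetic
from ._mcml import MCSettings
from .region import HomeLocation
from .richness import SplineSpec

__all__ = ["RunConfig", "PipelineError", "run_full_analysis", "STAGES"]

STAGES = ("simulate", "fit-lgcp", "fit-richness", "predict", "compare")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Either ``scenario`` (a synthetic study) or ``inputs`` (paths to
    covariate .asc grids, a CSD point file and a records file, plus a
    home location) must be provided.
    """

    scenario: synthetic.ScenarioConfig | None = None
    inputs: dict | None = None  # keys: W, V, F, csd_points, records, home (x, y)
    kappa: float = 1.0
    threshold: float = 0.75
    year: int = 1998
    collectors: int = 2
    spline_knots: tuple = (1990, 1995, 2000, 2002, 2004, 2006)
    n_samples: int = 2000
    info_samples: int | None = None
    max_refresh: int = 5
    seed: int = 0
    out_dir: str = "mossmap_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        scenario = data.pop("scenario", None)
        cfg = cls(**{k: v for k, v in data.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if scenario is not None:
            cfg.scenario = synthetic.ScenarioConfig(**scenario)
        return cfg

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        if self.scenario is not None:
            out["scenario"] = dataclasses.asdict(self.scenario)
        return out

    def stage_seeds(self) -> list[int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [int(c.generate_state(1)[0] % (2**31)) for c in children]

    def mc(self, seed: int) -> MCSettings:
        return MCSettings(
            n_samples=self.n_samples,
            info_samples=self.info_samples,
            max_refresh=self.max_refresh,
            seed=seed,
        )


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def __call__(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with self.path.open("a") as fh:
            fh.write(f"{stamp} {msg}\n")


def _load_inputs(config: RunConfig, log):
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario)
        bundle = synthetic.gen_scenario(scenario)
        home = HomeLocation(tuple(scenario.home))
        log(f"simulate: {len(bundle.pattern)} CSD points, "
            f"{int((bundle.records['source'] == 'RSD').sum())} RSD records (seed {scenario.seed})")
        return bundle.grid, bundle.covariates, bundle.pattern, bundle.records, home
    if config.inputs is None:
        raise PipelineError("simulate: config needs either a scenario or input paths")
    inputs = config.inputs
    for key in ("W", "V", "F", "csd_points", "records"):
        if key not in inputs:
            raise PipelineError(f"simulate: missing input entry {key!r}")
        if not Path(inputs[key]).exists():
            raise PipelineError(f"simulate: input file not found: {inputs[key]}")
    covs = {}
    grid = None
    for name in ("W", "V", "F"):
        grid_i, vals = region.read_ascii_grid(inputs[name])
        covs[name] = region.CovariateSurface(grid=grid_i, name=name, values=vals)
        grid = grid_i
    pattern = lgcp.read_point_pattern(inputs["csd_points"])
    records = richness.read_records(inputs["records"])
    home = HomeLocation(tuple(inputs["home"]))
    log(f"load: {len(pattern)} CSD points, {len(records)} records")
    return grid, covs, pattern, records, home


def run_full_analysis(config: RunConfig, until: str = "compare") -> dict:
    """Run the pipeline up to ``until`` (inclusive); returns a dict of artifacts.

    Stage outputs are written under ``config.out_dir``; any failure
    raises :class:`PipelineError` naming the stage.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    (out / "resolved_config.json").write_text(json.dumps(config.resolved(), indent=1, default=float))
    seeds = config.stage_seeds()
    last = STAGES.index(until)
    artifacts: dict = {}

    try:
        grid, covs, pattern, records, home = _load_inputs(config, log)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"simulate: {err}") from err
    artifacts.update(grid=grid, covariates=covs, pattern=pattern, records=records, home=home)
    if config.scenario is not None:
        for name, surf in covs.items():
            region.write_ascii_grid(out / f"{name}.asc", grid, surf.values)
    if last < 1:
        return artifacts

    try:
        fit_l = lgcp.fit_lgcp(
            pattern, covs["V"], grid, home,
            mc_settings=config.mc(seeds[1]), kappa=config.kappa,
        )
        shat = lgcp.predict_shat(fit_l)
        lgcp.write_fit_json(fit_l, out / "lgcp_fit.json")
        region.write_ascii_grid(out / "shat.asc", grid, shat.values)
        log(f"fit-lgcp: loglik={fit_l.loglik:.2f}, "
            f"alpha=({fit_l.estimates['alpha0']:.3f}, {fit_l.estimates['alpha1']:.3f}, "
            f"{fit_l.estimates['alpha2']:.3f}), seed {seeds[1]}")
    except Exception as err:
        raise PipelineError(f"fit-lgcp: {err}") from err
    artifacts.update(lgcp_fit=fit_l, shat=shat)
    if last < 2:
        return artifacts

    try:
        spec = SplineSpec(knots=tuple(config.spline_knots),
                          boundary=(int(records["year"].min()), max(int(records["year"].max()), config.year)))
        fit_csd = richness.fit_richness(records, covs, shat, "CSD",
                                        mc_settings=config.mc(seeds[2]), spline=spec)
        fit_rsd = richness.fit_richness(records, covs, None, "RSD",
                                        mc_settings=config.mc(seeds[3]))
        richness.write_fit_json(fit_csd, out / "csd_fit.json")
        richness.write_fit_json(fit_rsd, out / "rsd_fit.json")
        log(f"fit-richness: CSD loglik={fit_csd.loglik:.2f} "
            f"(gamma={fit_csd.estimates['gamma']:.3f}), RSD loglik={fit_rsd.loglik:.2f}")
    except Exception as err:
        raise PipelineError(f"fit-richness: {err}") from err
    artifacts.update(csd_fit=fit_csd, rsd_fit=fit_rsd, spline=spec)
    if last < 3:
        return artifacts

    try:
        mu_csd = richness.predict_mu(fit_csd, grid, config.year, config.collectors, covs, shat)
        mu_rsd = richness.predict_mu(fit_rsd, grid, config.year, None, covs)
        for tag, surf in (("csd", mu_csd), ("rsd", mu_rsd)):
            region.write_ascii_grid(out / f"mu_{tag}_mean.asc", grid, surf.mean)
            region.write_ascii_grid(out / f"mu_{tag}_se.asc", grid, surf.se)
            region.write_ascii_grid(out / f"mu_{tag}_cov.asc", grid, surf.cov)
        log(f"predict: year={config.year}, collectors={config.collectors}")
    except Exception as err:
        raise PipelineError(f"predict: {err}") from err
    artifacts.update(mu_csd=mu_csd, mu_rsd=mu_rsd)
    if last < 4:
        return artifacts

    try:
        rsd_locs = records.loc[records["source"] == "RSD", ["x", "y"]].to_numpy(float)
        result = comparison.compare_surfaces(
            fit_csd, fit_rsd, mu_csd.mean, mu_rsd.mean, grid,
            pattern.locations, rsd_locs, threshold=config.threshold,
        )
        region.write_ascii_grid(out / "comparable_mask.asc", grid, result.mask.astype(float))
        region.write_ascii_grid(out / "rd.asc", grid, result.rd)
        summary = dict(result.summary)
        summary["mask_rule"] = (
            f"correlation >= {config.threshold} to nearest sampled location, "
            "intersection over both sources"
        )
        (out / "rd_summary.json").write_text(json.dumps(summary, indent=1))
        log(f"compare: {result.summary['n_cells']} comparable cells, "
            f"RD in [{result.summary['min']:.3f}, {result.summary['max']:.3f}]")
    except Exception as err:
        raise PipelineError(f"compare: {err}") from err
    artifacts.update(comparison=result)
    return artifacts
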