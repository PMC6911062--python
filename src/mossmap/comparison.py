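"""Comparable-region masking and relative-difference comparison of prediction surfaces.

Two richness prediction surfaces are compared only where both sources
are informative: a cell x is *comparable* when, for each source j, the
fitted correlation of the latent field U_j between x and the nearest
sampled location x_c (nearest over the union of both sources' sampled
locations) is at least a threshold (default 0.75).  With exponential
correlation this is the distance rule ||x - x_c|| <= -psi_j ln(threshold),
and requiring it for *both* sources intersects the two distance masks.

The discrepancy is summarized per cell by the relative difference

    RD(x) = (mu_CSD - mu_RSD) / max(mu_CSD, mu_RSD)  in [-1, 1],

positive where the opportunistic source predicts more species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .region import Grid
from .richness import RichnessFit

__all__ = ["ComparisonResult", "correlation_mask", "relative_difference", "summarize_rd"]

DEFAULT_THRESHOLD = 0.75
DEFAULT_BIN_EDGES = np.linspace(-0.9, 0.9, 19)  # 18 equal bins


@dataclass(frozen=True)
class ComparisonResult:
    """Comparable-region mask, per-cell RD values and their summary."""

    grid: Grid
    mask: np.ndarray  # flat bool, True = comparable
    rd: np.ndarray  # flat, NaN outside the mask
    summary: dict


def correlation_mask(
    csd_fit: RichnessFit,
    rsd_fit: RichnessFit,
    grid: Grid,
    csd_locations,
    rsd_locations,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Flat boolean mask of cells where both fitted fields correlate >= threshold
    with the nearest sampled location (union of both sources)."""
    csd_locations = np.atleast_2d(np.asarray(csd_locations, float))
    rsd_locations = np.atleast_2d(np.asarray(rsd_locations, float))
    if csd_locations.size == 0 or rsd_locations.size == 0:
        raise ValueError("both sources need at least one sampled location")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    tree = cKDTree(np.vstack([csd_locations, rsd_locations]))
    dist, _ = tree.query(grid.cell_centers())
    if threshold == 0.0:
        within = np.ones(grid.n_cells, dtype=bool)
    else:
        # exp(-d/psi) >= thr  <=>  d <= -psi ln(thr), required for both sources
        cutoff = min(
            -csd_fit.field.scale * np.log(threshold),
            -rsd_fit.field.scale * np.log(threshold),
        )
        within = dist <= cutoff
    return within & grid.active()


def relative_difference(mu_csd, mu_rsd) -> np.ndarray:
    """Element-wise RD = (mu_CSD - mu_RSD) / max(mu_CSD, mu_RSD), in [-1, 1].

    Requires non-negative means; cells where both are zero give NaN.
    """
    a = np.asarray(mu_csd, float)
    b = np.asarray(mu_rsd, float)
    if np.any(a[np.isfinite(a)] < 0) or np.any(b[np.isfinite(b)] < 0):
        raise ValueError("prediction means must be non-negative")
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        rd = np.where(denom > 0, (a - b) / denom, np.nan)
    return rd


def summarize_rd(result_or_rd, mask=None, bin_edges=None) -> dict:
    """Min, max and histogram of RD over comparable cells.

    Accepts a :class:`ComparisonResult` or a flat RD array plus mask.
    """
    if isinstance(result_or_rd, ComparisonResult):
        rd, mask = result_or_rd.rd, result_or_rd.mask
    else:
        rd = np.asarray(result_or_rd, float)
        mask = np.ones(rd.shape, bool) if mask is None else np.asarray(mask, bool)
    vals = rd[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty comparable region: no RD values to summarize")
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    # extend edges so no masked value falls outside the histogram
    full_edges = np.r_[min(edges[0], vals.min() - 1e-12), edges[1:-1], max(edges[-1], vals.max() + 1e-12)]
    counts, _ = np.histogram(vals, bins=full_edges)
    return {
        "n_cells": int(vals.size),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "bin_edges": full_edges.tolist(),
        "counts": counts.tolist(),
    }


def compare_surfaces(
    csd_fit: RichnessFit,
    rsd_fit: RichnessFit,
    mu_csd,
    mu_rsd,
    grid: Grid,
    csd_locations,
    rsd_locations,
    threshold: float = DEFAULT_THRESHOLD,
) -> ComparisonResult:
    """Mask + RD + summary in one step (the pipeline's comparison stage)."""
    mask = correlation_mask(csd_fit, rsd_fit, grid, csd_locations, rsd_locations, threshold)
    rd = relative_difference(mu_csd, mu_rsd)
    mask = mask & np.isfinite(rd)
    rd = np.where(mask, rd, np.nan)
    return ComparisonResult(grid=grid, mask=mask, rd=rd,
                            summary=summarize_rd(rd, mask))
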