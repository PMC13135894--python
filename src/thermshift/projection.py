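"""Thermal habitat suitability (THS) projection.

THS at temperature T is the predicted feeding rate FR_t scaled by the
species' maximum feeding rate at the thermal optimum, FR_opt:

    THS(T) = FR_t / FR_opt,  bounded to [0, 1].

Predicted rates are the selected fitted curve with two safeguards: raw
negative predictions clamp to zero, and where both critical limits are
defined the rate is forced to zero outside [CTmin, CTmax]. Monthly THS
layers are computed cell-wise from each monthly temperature layer and
averaged arithmetically over the 12 months; a cell missing any month is
missing in the annual mean (strict nodata propagation). Land–sea masking
restricts projections to each realm's relevant cells.
"""

from __future__ import annotations

import numpy as np

from .fitting import FittedTPC
from .grids import AlignmentError, GridDefinition, TemperatureGridStack, THSGrid

__all__ = [
    "predict_rate",
    "compute_ths",
    "project_monthly",
    "annual_mean",
    "apply_realm_mask",
    "project_annual_ths",
]


def predict_rate(fit: FittedTPC, temperature) -> np.ndarray | float:
    """Predicted feeding rate FR_t at ``temperature`` (°C).

    Non-finite temperatures yield NaN (nodata); negative raw predictions
    clamp to 0; outside [CTmin, CTmax] (when both are defined) the rate
    is 0.
    """
    if not fit.converged:
        raise ValueError("predict_rate requires a converged fit")
    t = np.asarray(temperature, dtype=float)
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t)
    finite = np.isfinite(t1)
    rate = np.zeros_like(t1)
    rate[finite] = np.maximum(fit.predict_raw(t1[finite]), 0.0)
    if fit.ctmin is not None and fit.ctmax is not None:
        outside = finite & ((t1 < fit.ctmin) | (t1 > fit.ctmax))
        rate[outside] = 0.0
    rate[~finite] = np.nan
    return float(rate[0]) if scalar else rate


def compute_ths(fit: FittedTPC, temperature) -> np.ndarray | float:
    """Normalized suitability THS = FR_t / FR_opt, clipped to [0, 1].

    Clipping guards grid-refinement rounding at the peak; it never changes
    a value by more than ~1e-9 for a correctly derived optimum.
    """
    if not np.isfinite(fit.rmax) or fit.rmax <= 0:
        raise ValueError("compute_ths requires a positive peak rate (rmax)")
    rate = predict_rate(fit, temperature)
    return np.clip(rate / fit.rmax, 0.0, 1.0)


def project_monthly(fit: FittedTPC, stack: TemperatureGridStack, realm: str | None = None) -> np.ndarray:
    """12 monthly THS layers; nodata and realm masks propagate as NaN."""
    realm = realm or fit.realm
    valid = stack.realm_mask(realm)[None, :, :] & np.isfinite(stack.months)
    layers = np.full_like(stack.months, np.nan)
    temps = stack.months[valid]
    layers[valid] = compute_ths(fit, temps)
    return layers


def annual_mean(monthly: np.ndarray, grid: GridDefinition) -> THSGrid:
    """Arithmetic mean over the 12 months; any missing month voids the cell."""
    monthly = np.asarray(monthly, float)
    if monthly.shape[0] != 12:
        raise ValueError(f"expected 12 monthly layers, got {monthly.shape[0]}")
    if monthly.shape[1:] != grid.shape:
        raise ValueError("monthly layer shape does not match grid")
    all_valid = np.all(np.isfinite(monthly), axis=0)
    values = np.where(all_valid, monthly.mean(axis=0), np.nan)
    # guard float accumulation: means of in-range layers stay in range
    values = np.where(all_valid, np.clip(values, 0.0, 1.0), np.nan)
    return THSGrid(grid=grid, values=values)


def apply_realm_mask(ths: THSGrid, realm: str, land_mask: np.ndarray,
                     mask_grid: GridDefinition | None = None) -> THSGrid:
    """Restrict a THS grid to a realm's relevant cells.

    Marine species keep sea cells; freshwater and terrestrial species keep
    land cells. The mask must be aligned to the grid — no implicit
    resampling.
    """
    if mask_grid is not None:
        ths.grid.require_aligned(mask_grid)
    land = np.asarray(land_mask, bool)
    if land.shape != ths.grid.shape:
        raise AlignmentError("land mask shape does not match THS grid")
    if realm == "marine":
        keep = ~land
    elif realm in ("freshwater", "terrestrial"):
        keep = land
    else:
        raise ValueError(f"unknown realm {realm!r}")
    return THSGrid(grid=ths.grid, values=np.where(keep, ths.values, np.nan))


def project_annual_ths(fit: FittedTPC, stack: TemperatureGridStack,
                       realm: str | None = None) -> THSGrid:
    """Monthly projection + annual aggregation in one call."""
    return annual_mean(project_monthly(fit, stack, realm=realm), stack.grid)
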