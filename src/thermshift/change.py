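"""Suitability classes, scenario change metrics and monitoring priority.

Annual THS rasters are classified into five equal 0.2-wide classes —
Minimal, Minor, Moderate, Major, Massive — with left-closed/right-open
intervals and a closed top class ([0.8, 1.0]). Class extents are
area-weighted (cell area proportional to the cosine of cell-center
latitude, reported in km² on a spherical Earth of radius 6371 km), with
raw cell counts alongside. Between a baseline and a future scenario the
module reports per-class absolute and percent extent changes, the per-cell
suitability difference ΔTHS and its summary statistics, a range-expansion
flag (strict increase of the THS ≥ 0.6 extent), and a heuristic monitoring
priority reproducing the 3×2 concern matrix: the relative change of the
THS ≥ 0.6 extent crossing configurable thresholds (defaults 5% and 20%)
maps to NoIssue / Surveillance / Priority, reported jointly with the
expansion flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AlignmentError, THSGrid

__all__ = [
    "CLASS_LABELS",
    "CLASS_BOUNDS",
    "SuitabilityClassGrid",
    "ChangeSummary",
    "PriorityThresholds",
    "classify",
    "class_extents",
    "delta_ths",
    "range_expansion_flag",
    "priority_category",
    "summarize_change",
]

CLASS_LABELS = ("Minimal", "Minor", "Moderate", "Major", "Massive")
CLASS_BOUNDS = (0.2, 0.4, 0.6, 0.8)
#: suitability threshold defining "moderate-to-high" habitat for range expansion
EXPANSION_THRESHOLD = 0.6


@dataclass(frozen=True)
class SuitabilityClassGrid:
    """Per-cell class codes 1..5 (order of CLASS_LABELS); 0 = nodata."""

    grid: "object"
    codes: np.ndarray

    def label_at(self, code: int) -> str:
        return CLASS_LABELS[code - 1]


@dataclass(frozen=True)
class PriorityThresholds:
    """Percent-change cutoffs for the monitoring-priority heuristic."""

    low: float = 5.0
    high: float = 20.0

    def validate(self) -> None:
        if self.low < 0 or self.high < 0:
            raise ValueError("priority thresholds must be non-negative")
        if self.low >= self.high:
            raise ValueError("low threshold must be below high threshold")


def classify(ths: THSGrid) -> SuitabilityClassGrid:
    """Map THS values to the five classes.

    Intervals are left-closed/right-open except the top class, which is
    closed: [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0].
    """
    v = ths.values
    finite = np.isfinite(v)
    if np.any((v[finite] < 0.0) | (v[finite] > 1.0)):
        raise ValueError("THS values outside [0, 1]; upstream contract violated")
    codes = np.zeros(v.shape, dtype=np.uint8)
    codes[finite] = np.digitize(v[finite], CLASS_BOUNDS, right=False) + 1
    return SuitabilityClassGrid(grid=ths.grid, codes=codes)


def class_extents(classes: SuitabilityClassGrid) -> pd.DataFrame:
    """Area (km², cosine-weighted) and raw cell count per class."""
    areas = classes.grid.cell_areas_km2()
    rows = []
    for code, label in enumerate(CLASS_LABELS, start=1):
        sel = classes.codes == code
        rows.append(
            {"class": label, "code": code,
             "area_km2": float(areas[sel].sum()), "n_cells": int(sel.sum())}
        )
    return pd.DataFrame(rows)


def _require_comparable(baseline: THSGrid, future: THSGrid) -> None:
    baseline.grid.require_aligned(future.grid)
    if not np.array_equal(baseline.valid_mask, future.valid_mask):
        raise AlignmentError("baseline and future THS grids have different masks")


def delta_ths(baseline: THSGrid, future: THSGrid) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell future − baseline suitability, plus mean/min/max stats."""
    _require_comparable(baseline, future)
    diff = future.values - baseline.values
    valid = np.isfinite(diff)
    if valid.any():
        stats = {
            "mean": float(diff[valid].mean()),
            "min": float(diff[valid].min()),
            "max": float(diff[valid].max()),
        }
    else:
        stats = {"mean": float("nan"), "min": float("nan"), "max": float("nan")}
    return diff, stats


def _extent_at_least(ths: THSGrid, threshold: float) -> float:
    areas = ths.grid.cell_areas_km2()
    sel = np.isfinite(ths.values) & (ths.values >= threshold)
    return float(areas[sel].sum())


def range_expansion_flag(baseline: THSGrid, future: THSGrid) -> tuple[bool, float, float]:
    """Range-expanding iff the THS ≥ 0.6 extent strictly increases."""
    _require_comparable(baseline, future)
    base_ext = _extent_at_least(baseline, EXPANSION_THRESHOLD)
    fut_ext = _extent_at_least(future, EXPANSION_THRESHOLD)
    return fut_ext > base_ext, base_ext, fut_ext


def priority_category(
    baseline_extent: float,
    future_extent: float,
    thresholds: PriorityThresholds = PriorityThresholds(),
) -> tuple[str, float]:
    """Monitoring priority from the relative change of the THS ≥ 0.6 extent.

    Returns ``(category, r)`` where r is the sign-preserving percent change
    (+inf when suitable habitat appears where baseline had none):
    |r| ≥ high → Priority, low ≤ |r| < high → Surveillance, else NoIssue.
    """
    thresholds.validate()
    if baseline_extent > 0:
        r = 100.0 * (future_extent - baseline_extent) / baseline_extent
    elif future_extent > 0:
        r = float("inf")
    else:
        r = 0.0
    if abs(r) >= thresholds.high:
        return "Priority", r
    if abs(r) >= thresholds.low:
        return "Surveillance", r
    return "NoIssue", r


@dataclass(frozen=True)
class ChangeSummary:
    """Per-species scenario comparison (one row of the study's summary table)."""

    species: str
    class_table: pd.DataFrame  # per class: baseline/future extents + changes
    delta_mean: float
    delta_min: float
    delta_max: float
    extent_ge_06_baseline: float
    extent_ge_06_future: float
    range_expanding: bool
    priority: str
    percent_change_ge_06: float
    thresholds: PriorityThresholds


def summarize_change(
    species: str,
    baseline: THSGrid,
    future: THSGrid,
    thresholds: PriorityThresholds = PriorityThresholds(),
) -> ChangeSummary:
    """Full change analysis for one species between two scenarios."""
    base_classes = classify(baseline)
    fut_classes = classify(future)
    base_ext = class_extents(base_classes).rename(
        columns={"area_km2": "baseline_km2", "n_cells": "baseline_cells"}
    )
    fut_ext = class_extents(fut_classes).rename(
        columns={"area_km2": "future_km2", "n_cells": "future_cells"}
    )
    table = base_ext.merge(fut_ext, on=["class", "code"])
    table["absolute_change_km2"] = table["future_km2"] - table["baseline_km2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * table["absolute_change_km2"] / table["baseline_km2"]
    # percent change undefined when the class was absent at baseline
    table["percent_change"] = np.where(table["baseline_km2"] > 0, pct, np.nan)

    _, stats = delta_ths(baseline, future)
    expanding, ext_b, ext_f = range_expansion_flag(baseline, future)
    priority, r = priority_category(ext_b, ext_f, thresholds)

    return ChangeSummary(
        species=species,
        class_table=table,
        delta_mean=stats["mean"],
        delta_min=stats["min"],
        delta_max=stats["max"],
        extent_ge_06_baseline=ext_b,
        extent_ge_06_future=ext_f,
        range_expanding=expanding,
        priority=priority,
        percent_change_ge_06=r,
        thresholds=thresholds,
    )
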