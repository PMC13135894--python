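"""File formats and pipeline configuration.

Trait tables are CSV with header ``species, realm, trait, temperature_C,
rate`` (decimal point dialect; anything non-numeric in the numeric columns
is a schema error reported with its row number). Monthly temperature
stacks are NetCDF, either one 12-month file or a directory of files
``month_01.nc`` … ``month_12.nc`` sharing one grid. Configuration is a
YAML key/value tree with all defaults embedded.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .change import PriorityThresholds
from .grids import GridDefinition, TemperatureGridStack
from .observations import REALMS

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_trait_table",
    "write_trait_table",
    "read_monthly_stack",
    "FLOAT_FORMAT",
]

#: floating-point outputs use 6 significant digits for reproducible reruns
FLOAT_FORMAT = "%.6g"


class SchemaError(ValueError):
    """An input file violates its documented schema."""


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a trait CSV.

    Returns a typed DataFrame with columns species (str), realm (one of
    freshwater/marine/terrestrial), trait (str), temperature_C (float),
    rate (float). Errors carry 1-based data row numbers.
    """
    from .fitting import REQUIRED_COLUMNS

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    bad_realm = ~df["realm"].isin(REALMS)
    if bad_realm.any():
        row = int(np.flatnonzero(bad_realm.to_numpy())[0]) + 1
        raise SchemaError(
            f"{path}: row {row}: unknown realm {df['realm'].iloc[row - 1]!r} "
            f"(expected one of {', '.join(REALMS)})"
        )
    out = df.copy()
    for col in ("temperature_C", "rate"):
        parsed = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = parsed.isna() & (df[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(
                f"{path}: row {row}: non-numeric {col} value {df[col].iloc[row - 1]!r} "
                "(decimal point dialect required)"
            )
        out[col] = parsed.astype(float)
    return out


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_monthly_stack(path) -> TemperatureGridStack:
    """Load a 12-month temperature stack from one file or a directory.

    Directory layout: ``month_01.nc`` … ``month_12.nc``, each holding a
    single-month dataset on the same grid; a missing month is an error
    naming it, and layers on different grids are refused.
    """
    p = Path(path)
    if p.is_file():
        return TemperatureGridStack.load(p)
    if not p.is_dir():
        raise FileNotFoundError(f"no such climate input: {p}")

    months = []
    grid = None
    land = None
    for m in range(1, 13):
        f = p / f"month_{m:02d}.nc"
        if not f.exists():
            raise SchemaError(f"{p}: missing climate layer for month {m:02d} ({f.name})")
        with xr.open_dataset(f, engine="scipy") as ds:
            ds = ds.load()
        if "units" not in ds["temperature"].attrs:
            raise SchemaError(f"{f}: temperature variable lacks units metadata")
        g = GridDefinition(np.asarray(ds["lat"].values), np.asarray(ds["lon"].values))
        if grid is None:
            grid = g
            land = np.asarray(ds["land_mask"].values).astype(bool)
        elif not grid.aligned_with(g):
            raise SchemaError(f"{f}: grid differs from month_01 (mixed grids refused)")
        temp = np.asarray(ds["temperature"].values, float)
        temp = np.squeeze(temp)
        if temp.ndim != 2:
            raise SchemaError(f"{f}: expected a single monthly layer")
        months.append(np.where(temp <= -9998.5, np.nan, temp))
    return TemperatureGridStack(grid=grid, months=np.stack(months), land_mask=land)


@dataclass
class PipelineConfig:
    """End-to-end run configuration with embedded defaults."""

    traits: str = "traits.csv"
    baseline_climate: str = "climate_baseline.nc"
    future_climate: str = "climate_future.nc"
    out_dir: str = "out"
    n_starts: int = 10
    n_boot: int = 200
    level: float = 0.95
    seed: int = 0
    aic_variant: str = "aicc"  # "aicc" or "aic"
    priority_low: float = 5.0
    priority_high: float = 20.0

    def validate(self) -> None:
        if self.aic_variant not in ("aicc", "aic"):
            raise ValueError("aic_variant must be 'aicc' or 'aic'")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        PriorityThresholds(self.priority_low, self.priority_high).validate()

    @property
    def priority_thresholds(self) -> PriorityThresholds:
        return PriorityThresholds(self.priority_low, self.priority_high)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
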