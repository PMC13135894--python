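"""Container for one species' trait observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REALMS = ("freshwater", "marine", "terrestrial")

#: fewer distinct test temperatures cannot identify a 4-parameter curve
MIN_DISTINCT_TEMPERATURES = 4


@dataclass(frozen=True)
class TraitObservationSet:
    """(temperature, rate) measurements of one feeding-related trait.

    Rates are non-negative by contract (quality filtering removes negative
    values upstream); temperatures are in °C. ``replicates`` at the same
    temperature are kept as separate points.
    """

    species: str
    realm: str
    trait: str
    temperatures: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("temperatures and rates must be matching 1-D arrays")
        if self.realm not in REALMS:
            raise ValueError(f"unknown realm {self.realm!r}; expected one of {REALMS}")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(r)):
            raise ValueError("non-finite temperature or rate in observation set")
        if np.any(r < 0):
            raise ValueError("negative rates are excluded by quality filtering")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rates", r)

    def __len__(self) -> int:
        return self.temperatures.size

    @property
    def n_distinct_temperatures(self) -> int:
        return np.unique(self.temperatures).size

    @property
    def temperature_span(self) -> tuple[float, float]:
        return float(self.temperatures.min()), float(self.temperatures.max())

    def sufficient_for_fitting(self) -> bool:
        return self.n_distinct_temperatures >= MIN_DISTINCT_TEMPERATURES
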