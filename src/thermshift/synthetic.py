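"""Synthetic trait observations and paired climate grids.

Every downstream stage (fitting, projection, change analysis) is exercised
against data generated here from *known* thermal performance curves and an
idealised climate, so ground truth is always available:

* trait observations are drawn from a registry form at chosen "true"
  parameters, with additive Gaussian noise scaled to the curve's true peak
  rate and truncated below at zero (empirical feeding rates are
  non-negative);
* monthly temperature grids combine a latitudinal gradient, a
  hemisphere-aware seasonal cycle and smooth spatial noise; the future
  scenario is the baseline plus a uniform warming offset, cell for cell,
  sharing the identical land–sea mask.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grids import GridDefinition, TemperatureGridStack
from .models import ModelRegistry, list_model_forms
from .observations import REALMS, TraitObservationSet

__all__ = [
    "SyntheticTPCSpec",
    "SyntheticClimateSpec",
    "StudyFixture",
    "generate_tpc_observations",
    "generate_temperature_grids",
    "generate_study_fixture",
    "true_peak",
]


@dataclass(frozen=True)
class SyntheticTPCSpec:
    """Recipe for one species' synthetic trait observations."""

    form_name: str
    true_params: tuple[float, ...]
    n_temperatures: int = 15
    temperature_range: tuple[float, float] = (5.0, 35.0)
    noise_cv: float = 0.05
    replicates_per_temperature: int = 1
    seed: int = 0
    species: str = "synthetic_sp"
    realm: str = "marine"
    trait: str = "ingestion_rate"

    def validate(self) -> None:
        if self.n_temperatures < 4:
            raise ValueError("n_temperatures must be >= 4 to identify a 4-parameter form")
        lo, hi = self.temperature_range
        if not lo < hi:
            raise ValueError("temperature_range must satisfy Tlow < Thigh")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates_per_temperature < 1:
            raise ValueError("replicates_per_temperature must be >= 1")
        if self.realm not in REALMS:
            raise ValueError(f"unknown realm {self.realm!r}")


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Recipe for paired baseline/future monthly temperature grids.

    The latitudinal gradient follows insolation (cos² of latitude) between
    ``mean_equator_temp`` and ``mean_pole_temp``; the seasonal cycle is a
    12-month sinusoid whose sign flips between hemispheres (boreal vs
    austral seasons) and peaks in July in the north.
    """

    n_lat: int = 36
    n_lon: int = 72
    lat_range: tuple[float, float] = (-90.0, 90.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    mean_equator_temp: float = 27.0
    mean_pole_temp: float = -18.0
    seasonal_amplitude: float = 8.0
    warming_offset: float = 2.0
    land_fraction: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_lat <= 0 or self.n_lon <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.lat_range[0] < self.lat_range[1]:
            raise ValueError("lat_range must be increasing")
        if not self.lon_range[0] < self.lon_range[1]:
            raise ValueError("lon_range must be increasing")
        if not 0.0 <= self.land_fraction <= 1.0:
            raise ValueError("land_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def true_peak(form_name: str, params, registry: ModelRegistry | None = None) -> tuple[float, float]:
    """(Topt, rmax) of a form at known parameters, by dense scan.

    Scans [-50, 60] °C at 0.01 °C; adequate for generator truth because the
    synthetic curves are smooth and unimodal.
    """
    registry = registry or list_model_forms()
    form = registry[form_name]
    t = np.arange(-50.0, 60.0 + 1e-9, 0.01)
    r = form.evaluate(t, params)
    i = int(np.argmax(r))
    return float(t[i]), float(r[i])


def generate_tpc_observations(spec: SyntheticTPCSpec) -> TraitObservationSet:
    """Draw noisy observations from a known curve.

    Temperatures are evenly spaced over ``temperature_range``; the rate at
    each point is ``form(T; true_params) + N(0, noise_cv * rmax_true)``,
    truncated below at zero.
    """
    spec.validate()
    registry = list_model_forms()
    form = registry[spec.form_name]  # raises KeyError for unknown forms

    temps = np.linspace(*spec.temperature_range, spec.n_temperatures)
    temps = np.repeat(temps, spec.replicates_per_temperature)
    clean = form.evaluate(temps, spec.true_params)

    if spec.noise_cv > 0:
        _, rmax_true = true_peak(spec.form_name, spec.true_params, registry)
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_cv * rmax_true, size=temps.shape)
        rates = np.maximum(clean + noise, 0.0)
    else:
        rates = np.maximum(clean, 0.0)

    return TraitObservationSet(
        species=spec.species,
        realm=spec.realm,
        trait=spec.trait,
        temperatures=temps,
        rates=rates,
    )


def _latitudinal_gradient(lats: np.ndarray, equator: float, pole: float) -> np.ndarray:
    return pole + (equator - pole) * np.cos(np.radians(lats)) ** 2


def _seasonal_cycle(lats: np.ndarray, amplitude: float) -> np.ndarray:
    """(12, n_lat) seasonal anomaly; July peak in the north, January in the south."""
    months = np.arange(1, 13)
    cycle = np.cos(2.0 * np.pi * (months - 7) / 12.0)  # +1 in July
    hemi = np.where(lats >= 0.0, 1.0, -1.0)
    return amplitude * cycle[:, None] * hemi[None, :]


def _land_mask(spec: SyntheticClimateSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field thresholded to hit the requested land fraction."""
    if spec.land_fraction >= 1.0:
        return np.ones((spec.n_lat, spec.n_lon), bool)
    if spec.land_fraction <= 0.0:
        return np.zeros((spec.n_lat, spec.n_lon), bool)
    field_ = rng.normal(size=(spec.n_lat, spec.n_lon))
    sigma = max(min(spec.n_lat, spec.n_lon) / 12.0, 1.0)
    smooth = ndimage.gaussian_filter(field_, sigma=sigma, mode="wrap")
    thresh = np.quantile(smooth, 1.0 - spec.land_fraction)
    return smooth >= thresh


def generate_temperature_grids(
    spec: SyntheticClimateSpec,
) -> tuple[TemperatureGridStack, TemperatureGridStack]:
    """Baseline and future monthly stacks sharing grid, mask and noise.

    The future stack equals the baseline plus ``warming_offset`` at every
    cell and month, exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    lat_lo, lat_hi = spec.lat_range
    lon_lo, lon_hi = spec.lon_range
    dlat = (lat_hi - lat_lo) / spec.n_lat
    dlon = (lon_hi - lon_lo) / spec.n_lon
    lats = lat_hi - dlat * (np.arange(spec.n_lat) + 0.5)  # north-up
    lons = lon_lo + dlon * (np.arange(spec.n_lon) + 0.5)
    grid = GridDefinition(lats, lons)

    land = _land_mask(spec, rng)

    gradient = _latitudinal_gradient(lats, spec.mean_equator_temp, spec.mean_pole_temp)
    seasonal = _seasonal_cycle(lats, spec.seasonal_amplitude)
    base = gradient[None, :, None] + seasonal[:, :, None]
    base = np.broadcast_to(base, (12, spec.n_lat, spec.n_lon)).copy()
    if spec.noise_sd > 0:
        base += rng.normal(0.0, spec.noise_sd, size=base.shape)

    baseline = TemperatureGridStack(grid=grid, months=base, land_mask=land)
    future = TemperatureGridStack(
        grid=grid, months=base + spec.warming_offset, land_mask=land
    )
    return baseline, future


# --------------------------------------------------------------------------
# study fixture: a full multi-species, multi-realm dataset
# --------------------------------------------------------------------------

#: Generating forms cycled through when building fixture species. All are
#: standard unimodal shapes whose truth is easy to recover.
_FIXTURE_FORMS = ("gaussian", "quadratic", "rosso", "deutsch")


def _fixture_species_spec(realm: str, index: int, seed: int) -> SyntheticTPCSpec:
    """Deterministic, realm-plausible generating curve for fixture species."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, REALMS.index(realm), index]))
    base_topt = {"freshwater": 20.0, "marine": 16.0, "terrestrial": 26.0}[realm]
    topt = base_topt + rng.uniform(-4.0, 4.0)
    rmax = float(rng.uniform(0.5, 5.0))
    breadth = float(rng.uniform(4.0, 7.0))
    form = _FIXTURE_FORMS[index % len(_FIXTURE_FORMS)]
    if form == "gaussian":
        params = (rmax, topt, breadth)
    elif form == "quadratic":
        lo, hi = topt - 2.0 * breadth, topt + 2.0 * breadth
        scale = rmax / (breadth * breadth)  # peak value rmax at the vertex
        # -scale (T - lo)(T - hi) expanded to a + bT + cT^2, peak at (lo+hi)/2
        a, b, c = -scale * lo * hi, scale * (lo + hi), -scale
        params = (a, b, c)
    elif form == "rosso":
        params = (rmax, topt, topt - 2.5 * breadth, topt + 1.2 * breadth)
    else:  # deutsch
        params = (rmax, topt, topt + 1.5 * breadth, breadth)
    return SyntheticTPCSpec(
        form_name=form,
        true_params=params,
        n_temperatures=15,
        temperature_range=(topt - 2.0 * breadth, topt + 1.1 * breadth),
        noise_cv=0.05,
        seed=int(rng.integers(0, 2**31 - 1)),
        species=f"{realm[:2]}_sp{index + 1:02d}",
        realm=realm,
        trait="ingestion_rate",
    )


@dataclass(frozen=True)
class StudyFixture:
    """Trait tables plus paired climate stacks for an end-to-end run."""

    species_specs: tuple[SyntheticTPCSpec, ...]
    observations: tuple[TraitObservationSet, ...]
    baseline: TemperatureGridStack
    future: TemperatureGridStack

    def trait_frame(self):
        import pandas as pd

        rows = []
        for obs in self.observations:
            for t, r in zip(obs.temperatures, obs.rates):
                rows.append((obs.species, obs.realm, obs.trait, t, r))
        return pd.DataFrame(
            rows, columns=["species", "realm", "trait", "temperature_C", "rate"]
        )

    def realm_masked_stacks(self, realm: str) -> tuple[TemperatureGridStack, TemperatureGridStack]:
        """Baseline/future views restricted to the realm's valid cells."""
        masks = self.baseline.realm_mask(realm)
        def restrict(stack: TemperatureGridStack) -> TemperatureGridStack:
            months = np.where(masks[None, :, :], stack.months, np.nan)
            return TemperatureGridStack(stack.grid, months, stack.land_mask)
        return restrict(self.baseline), restrict(self.future)


def generate_study_fixture(
    n_species_per_realm: int | Mapping[str, int] = 1,
    seed: int = 0,
    climate: SyntheticClimateSpec | None = None,
) -> StudyFixture:
    """Multi-species fixture emulating the study composition.

    ``n_species_per_realm`` may be a single count or a per-realm mapping,
    e.g. ``{"freshwater": 4, "marine": 16, "terrestrial": 8}`` for a
    28-species composition.
    """
    if isinstance(n_species_per_realm, int):
        counts = {realm: n_species_per_realm for realm in REALMS}
    else:
        counts = {realm: int(n_species_per_realm.get(realm, 0)) for realm in REALMS}
    if any(c < 1 for c in counts.values()):
        raise ValueError("need at least one species per realm")

    specs: list[SyntheticTPCSpec] = []
    for realm in REALMS:
        for i in range(counts[realm]):
            specs.append(_fixture_species_spec(realm, i, seed))
    observations = tuple(generate_tpc_observations(s) for s in specs)

    climate = climate or SyntheticClimateSpec(seed=seed)
    if climate.seed != seed:
        climate = replace(climate, seed=seed)
    baseline, future = generate_temperature_grids(climate)

    return StudyFixture(
        species_specs=tuple(specs),
        observations=observations,
        baseline=baseline,
        future=future,
    )
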