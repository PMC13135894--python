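"""Simulation studies validating the fitting pipeline against known truth.

These are first-class package utilities (not test scaffolding): they
generate data from known curves with the synthetic module, push it through
the same fitting and bootstrap code used on real data, and measure how
well truth is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FittedTPC, bootstrap_ci, derive_parameters, fit_single_form
from .models import list_model_forms
from .synthetic import SyntheticTPCSpec, generate_tpc_observations

__all__ = ["CoverageResult", "topt_bootstrap_coverage", "gaussian_recovery_errors"]

_GAUSS_TRUTH = (1.0, 20.0, 5.0)  # rmax, Topt (°C), width (°C)


def _fit_gaussian(seed: int, n_temperatures: int, noise_cv: float,
                  n_starts: int = 10) -> tuple:
    form = list_model_forms()["gaussian"]
    spec = SyntheticTPCSpec(
        "gaussian", _GAUSS_TRUTH, n_temperatures=n_temperatures,
        temperature_range=(5.0, 35.0), noise_cv=noise_cv, seed=seed,
    )
    obs = generate_tpc_observations(spec)
    fit = fit_single_form(obs, form, n_starts=n_starts, seed=seed)
    return obs, form, fit


@dataclass(frozen=True)
class CoverageResult:
    n_datasets: int
    n_covered: int
    n_failed_fits: int
    nominal_level: float

    @property
    def coverage_percent(self) -> float:
        n_ok = self.n_datasets - self.n_failed_fits
        return 100.0 * self.n_covered / n_ok if n_ok else float("nan")


def topt_bootstrap_coverage(
    n_datasets: int = 200,
    n_resamples: int = 500,
    level: float = 0.95,
    base_seed: int = 0,
    n_temperatures: int = 20,
    noise_cv: float = 0.05,
) -> CoverageResult:
    """Empirical coverage of bootstrap percentile intervals for Topt.

    Simulates ``n_datasets`` Gaussian-TPC datasets (true Topt 20 °C, rmax 1,
    width 5, temperatures evenly spaced over [5, 35] °C), fits the Gaussian
    form to each, builds a residual-bootstrap percentile interval for the
    thermal optimum, and counts intervals containing the truth. Dataset i
    uses seed ``base_seed + i`` (i = 1..n_datasets).
    """
    true_topt = _GAUSS_TRUTH[1]
    covered = failed = 0
    for i in range(1, n_datasets + 1):
        seed = base_seed + i
        obs, form, fit = _fit_gaussian(seed, n_temperatures, noise_cv)
        if not fit.converged:
            failed += 1
            continue
        traits = derive_parameters(form, fit.params, *obs.temperature_span)
        fitted = FittedTPC(
            species=obs.species, realm=obs.realm, form_name="gaussian",
            params=fit.params, aicc=fit.aicc, rss=fit.rss, converged=True,
            rmax=traits.rmax, topt=traits.topt, ctmin=traits.ctmin,
            ctmax=traits.ctmax, q10=traits.q10,
            t_obs_min=obs.temperature_span[0], t_obs_max=obs.temperature_span[1],
        )
        boot = bootstrap_ci(obs, fitted, n_resamples=n_resamples, level=level, seed=seed)
        lo, hi = boot.intervals["topt"]
        if lo <= true_topt <= hi:
            covered += 1
    return CoverageResult(n_datasets, covered, failed, level)


def gaussian_recovery_errors(
    n_sims: int = 100,
    base_seed: int = 0,
    n_temperatures: int = 20,
    noise_cv: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-simulation |Topt error| (°C) and relative rmax error.

    Fits the Gaussian form to ``n_sims`` noisy Gaussian datasets and
    compares the derived optimum and peak rate to the generating truth.
    """
    rmax_true, topt_true, _ = _GAUSS_TRUTH
    topt_err, rmax_err = [], []
    for i in range(1, n_sims + 1):
        seed = base_seed + i
        obs, form, fit = _fit_gaussian(seed, n_temperatures, noise_cv)
        if not fit.converged:
            topt_err.append(np.inf)
            rmax_err.append(np.inf)
            continue
        traits = derive_parameters(form, fit.params, *obs.temperature_span)
        topt_err.append(abs(traits.topt - topt_true))
        rmax_err.append(abs(traits.rmax - rmax_true) / rmax_true)
    return np.asarray(topt_err), np.asarray(rmax_err)
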