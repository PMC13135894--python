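"""Fitting, model selection, derived thermal traits and bootstrap CIs.

Per species the workflow is:

1. quality-filter the raw trait table (``filter_observations``);
2. fit every candidate form in the registry by bounded nonlinear least
   squares with seeded multi-start initials (``fit_single_form``);
3. select the best form by small-sample-corrected Akaike information
   criterion, AICc, among converged fits whose derived parameters are
   plausible (``fit_all_forms``); ties go to the form with fewer
   parameters, then to registry order;
4. extract thermal traits from the selected curve — peak rate ``rmax``,
   thermal optimum ``Topt``, critical limits ``CTmin``/``CTmax`` (nearest
   zero-crossings around the optimum, when they exist) and the temperature
   sensitivity ``Q10`` over the 10 °C below the optimum
   (``derive_parameters``);
5. quantify uncertainty with a residual bootstrap refitting the selected
   form only (``bootstrap_ci``); intervals are percentile-based.

AICc uses k = n_params + 1 (the residual variance is an estimated
parameter): ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1)``. Species are
excluded, with a recorded reason, when no form converges, when every
converged fit is implausible, or when fewer than four distinct test
temperatures are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ModelRegistry, ObservationSummary, TPCModelForm, list_model_forms
from .observations import MIN_DISTINCT_TEMPERATURES, REALMS, TraitObservationSet

__all__ = [
    "FormFitResult",
    "FittedTPC",
    "ThermalTraits",
    "ModelSelectionResult",
    "BootstrapResult",
    "FilterResult",
    "filter_observations",
    "fit_single_form",
    "fit_all_forms",
    "derive_parameters",
    "plausibility_filter",
    "bootstrap_ci",
]

REQUIRED_COLUMNS = ("species", "realm", "trait", "temperature_C", "rate")

#: half-width (°C) of the search window beyond the observed temperature span
#: when locating the optimum and the critical limits on a fitted curve
SEARCH_WINDOW_PAD = 25.0
#: grid step (°C) of the dense scan locating the optimum
SCAN_STEP = 0.01
#: plausibility rules, explicit stand-ins for "unrealistic parameter estimates"
TOPT_PAD = 10.0
MAX_THERMAL_BREADTH = 80.0


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterResult:
    """Quality-filtered per-species observation sets plus exclusions."""

    observations: tuple[TraitObservationSet, ...]
    excluded: dict[str, str]  # species -> reason
    n_rows_dropped: int


def filter_observations(raw: pd.DataFrame) -> FilterResult:
    """Apply the data-quality rules to a raw trait table.

    Rows with missing temperature or rate are dropped, as are negative
    rates; exact duplicate (species, temperature, rate) rows collapse to
    one. Species left with fewer than four distinct temperatures are
    excluded with reason ``insufficient_data``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"trait table missing required columns: {missing}")

    df = raw.copy()
    n0 = len(df)
    df["temperature_C"] = pd.to_numeric(df["temperature_C"], errors="coerce")
    df["rate"] = pd.to_numeric(df["rate"], errors="coerce")
    df = df.dropna(subset=["temperature_C", "rate"])
    df = df[df["rate"] >= 0.0]
    df = df.drop_duplicates(subset=["species", "temperature_C", "rate"])

    observations: list[TraitObservationSet] = []
    excluded: dict[str, str] = {}
    for species, grp in df.groupby("species", sort=True):
        realm = str(grp["realm"].iloc[0])
        trait = str(grp["trait"].iloc[0])
        temps = grp["temperature_C"].to_numpy(float)
        rates = grp["rate"].to_numpy(float)
        if np.unique(temps).size < MIN_DISTINCT_TEMPERATURES:
            excluded[str(species)] = "insufficient_data"
            continue
        observations.append(
            TraitObservationSet(str(species), realm, trait, temps, rates)
        )
    # species entirely removed by row-level filtering are insufficient too
    for species in raw["species"].unique():
        if str(species) not in excluded and not any(
            o.species == str(species) for o in observations
        ):
            excluded[str(species)] = "insufficient_data"
    return FilterResult(tuple(observations), excluded, n0 - len(df))


# --------------------------------------------------------------------------
# single-form fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FormFitResult:
    form_name: str
    params: np.ndarray | None
    rss: float
    aicc: float
    converged: bool
    n_obs: int


def _aicc(rss: float, n: int, n_params: int, variant: str = "aicc") -> float:
    """Information criterion with residual variance counted as a parameter."""
    k = n_params + 1
    if rss <= 0:
        rss = 1e-300  # perfect fit: push the criterion to -inf-ish finitely
    base = n * math.log(rss / n) + 2 * k
    if variant == "aic":
        return base
    if n - k - 1 <= 0:
        return math.nan
    return base + 2 * k * (k + 1) / (n - k - 1)


def fit_single_form(
    obs: TraitObservationSet,
    form: TPCModelForm,
    n_starts: int = 10,
    seed: int = 0,
    aic_variant: str = "aicc",
    max_nfev: int = 1000,
) -> FormFitResult:
    """Bounded least squares from ``n_starts`` jittered initials.

    Initials are the form's heuristic start values perturbed by ±20%
    multiplicative jitter (seeded), clipped into bounds; the converged run
    with the lowest residual sum of squares wins. Failure of every start,
    or an undefined criterion (n - k - 1 <= 0), marks the form
    non-converged.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    t, y = obs.temperatures, obs.rates
    n = t.size
    lo, hi = form.bounds
    summary = ObservationSummary.from_points(t, y)
    p0 = form.start_values(summary)
    rng = np.random.default_rng(seed)

    def residuals(p: np.ndarray) -> np.ndarray:
        r = form.evaluate(t, p) - y
        return np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)

    best_params, best_rss = None, np.inf
    for i in range(n_starts):
        if i == 0:
            start = p0
        else:
            start = p0 * rng.uniform(0.8, 1.2, size=p0.shape)
            start = np.where(p0 == 0.0, rng.uniform(-0.1, 0.1, size=p0.shape), start)
        start = np.clip(start, lo, hi)
        try:
            with np.errstate(all="ignore"):
                res = optimize.least_squares(
                    residuals, start, bounds=(lo, hi), method="trf", max_nfev=max_nfev
                )
        except (ValueError, FloatingPointError):
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and np.isfinite(rss) and rss < best_rss:
            best_rss, best_params = rss, res.x.copy()

    if best_params is None or not np.isfinite(best_rss):
        return FormFitResult(form.name, None, math.inf, math.nan, False, n)

    aicc = _aicc(best_rss, n, form.n_params, aic_variant)
    if math.isnan(aicc):
        return FormFitResult(form.name, best_params, best_rss, math.nan, False, n)
    return FormFitResult(form.name, best_params, best_rss, aicc, True, n)


# --------------------------------------------------------------------------
# derived thermal traits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalTraits:
    rmax: float
    topt: float
    ctmin: float | None
    ctmax: float | None
    q10: float | None


def derive_parameters(
    form: TPCModelForm,
    params: Sequence[float],
    t_obs_min: float,
    t_obs_max: float,
) -> ThermalTraits:
    """Thermal traits of a fitted curve.

    The optimum is located by a 0.01 °C grid scan over the observed span
    padded by ±25 °C, refined locally by bounded scalar minimisation.
    ``CTmin``/``CTmax`` are the nearest points below/above the optimum
    where the raw curve reaches zero (bisection on the bracketing grid
    interval); they are undefined when the curve never crosses zero inside
    the window. ``Q10 = rmax / f(Topt - 10)``, undefined when the rate
    10 °C below the optimum is not positive.
    """
    p = np.asarray(params, float)
    lo_t = t_obs_min - SEARCH_WINDOW_PAD
    hi_t = t_obs_max + SEARCH_WINDOW_PAD
    grid = np.arange(lo_t, hi_t + SCAN_STEP / 2, SCAN_STEP)
    vals = form.evaluate(grid, p)
    i = int(np.argmax(vals))

    # local refinement within one grid step on either side
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda x: -form.evaluate(np.array([x]), p)[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-6},
        )
        topt = float(res.x)
        rmax = float(-res.fun)
        if rmax < vals[i]:  # refinement must never lose to the scan
            topt, rmax = float(grid[i]), float(vals[i])
    else:
        topt, rmax = float(grid[i]), float(vals[i])

    def crossing(side: str) -> float | None:
        if side == "below":
            idx = np.arange(i, 0, -1)
        else:
            idx = np.arange(i, grid.size - 1)
        seg = vals[idx]
        nonpos = np.flatnonzero(seg <= 0.0)
        if nonpos.size == 0:
            return None
        j = idx[nonpos[0]]
        # bracket between j (<=0) and its neighbour toward topt (>0)
        k = j + 1 if side == "below" else j - 1
        t_lo, t_hi = (grid[j], grid[k]) if side == "below" else (grid[k], grid[j])
        f = lambda x: form.evaluate(np.array([x]), p)[0]
        if vals[j] == 0.0:
            return float(grid[j])
        try:
            return float(optimize.brentq(f, t_lo, t_hi, xtol=1e-6))
        except ValueError:
            return float(grid[j])

    ctmin = crossing("below")
    ctmax = crossing("above")

    rate_below = form.evaluate(np.array([topt - 10.0]), p)[0]
    q10 = float(rmax / rate_below) if rate_below > 0 else None

    return ThermalTraits(rmax=rmax, topt=topt, ctmin=ctmin, ctmax=ctmax, q10=q10)


# --------------------------------------------------------------------------
# plausibility
# --------------------------------------------------------------------------

def plausibility_filter(
    traits: ThermalTraits, obs: TraitObservationSet
) -> tuple[bool, str | None]:
    """Explicit stand-in rules for "unrealistic parameter estimates".

    A fit is rejected when its peak rate is non-positive, its optimum lies
    more than 10 °C outside the observed temperature span, or its thermal
    breadth (CTmax - CTmin, when both limits exist) exceeds 80 °C.
    """
    t_lo, t_hi = obs.temperature_span
    if not np.isfinite(traits.rmax) or traits.rmax <= 0:
        return False, "implausible_parameters"
    if traits.topt < t_lo - TOPT_PAD or traits.topt > t_hi + TOPT_PAD:
        return False, "implausible_parameters"
    if (
        traits.ctmin is not None
        and traits.ctmax is not None
        and traits.ctmax - traits.ctmin > MAX_THERMAL_BREADTH
    ):
        return False, "implausible_parameters"
    return True, None


# --------------------------------------------------------------------------
# selection across all forms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedTPC:
    """The selected curve for one species, with derived thermal traits."""

    species: str
    realm: str
    form_name: str
    params: np.ndarray
    aicc: float
    rss: float
    converged: bool
    rmax: float
    topt: float
    ctmin: float | None
    ctmax: float | None
    q10: float | None
    t_obs_min: float
    t_obs_max: float

    def predict_raw(self, temperature) -> np.ndarray:
        """Raw curve value (may be negative outside the thermal window)."""
        form = list_model_forms()[self.form_name]
        return form.evaluate(temperature, self.params)


@dataclass(frozen=True)
class ModelSelectionResult:
    species: str
    table: pd.DataFrame  # one row per candidate form
    selected: FittedTPC | None
    exclusion_reason: str | None  # None when a form was selected


def fit_all_forms(
    obs: TraitObservationSet,
    registry: ModelRegistry | None = None,
    n_starts: int = 10,
    seed: int = 0,
    aic_variant: str = "aicc",
) -> ModelSelectionResult:
    """Score every candidate form and select the AICc-best plausible fit.

    Ties (to machine precision) are broken by fewer parameters, then by
    registry order. Exclusion reasons follow the study rules:
    ``no_convergence`` when no form converges, ``implausible_parameters``
    when converged fits all fail the plausibility rules,
    ``insufficient_data`` when the design cannot identify a curve.
    """
    registry = registry or list_model_forms()

    if not obs.sufficient_for_fitting():
        table = pd.DataFrame(
            {"form_name": registry.names, "aicc": np.nan, "converged": False,
             "plausible": False}
        )
        return ModelSelectionResult(obs.species, table, None, "insufficient_data")

    rows = []
    candidates = []  # (aicc, n_params, registry_index, fit, traits)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0])
    form_seeds = ss.generate_state(len(registry))
    t_lo, t_hi = obs.temperature_span
    any_converged = False
    for idx, form in enumerate(registry):
        fit = fit_single_form(
            obs, form, n_starts=n_starts, seed=int(form_seeds[idx]), aic_variant=aic_variant
        )
        plausible = False
        traits = None
        if fit.converged:
            any_converged = True
            traits = derive_parameters(form, fit.params, t_lo, t_hi)
            plausible, _ = plausibility_filter(traits, obs)
            if plausible:
                candidates.append((fit.aicc, form.n_params, idx, fit, traits))
        rows.append(
            {
                "form_name": form.name,
                "n_params": form.n_params,
                "aicc": fit.aicc,
                "rss": fit.rss,
                "converged": fit.converged,
                "plausible": plausible,
                "params": None if fit.params is None else tuple(np.round(fit.params, 10)),
            }
        )
    table = pd.DataFrame(rows)

    if not candidates:
        reason = "implausible_parameters" if any_converged else "no_convergence"
        return ModelSelectionResult(obs.species, table, None, reason)

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    aicc, _, idx, fit, traits = candidates[0]
    form = registry.forms[idx]
    selected = FittedTPC(
        species=obs.species,
        realm=obs.realm,
        form_name=form.name,
        params=np.asarray(fit.params, float),
        aicc=aicc,
        rss=fit.rss,
        converged=True,
        rmax=traits.rmax,
        topt=traits.topt,
        ctmin=traits.ctmin,
        ctmax=traits.ctmax,
        q10=traits.q10,
        t_obs_min=t_lo,
        t_obs_max=t_hi,
    )
    return ModelSelectionResult(obs.species, table, selected, None)


# --------------------------------------------------------------------------
# residual bootstrap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    species: str
    n_resamples: int
    n_failed: int
    nominal_level: float
    intervals: dict[str, tuple[float, float]]
    n_defined: dict[str, int]
    seed: int
    warning: str | None = None


def _hat_values(form: TPCModelForm, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Leverages h_i = diag(J (J'J)^-1 J') from a finite-difference Jacobian.

    Clipped to [0, 0.95] so a near-interpolating point cannot blow up its
    modified residual; degenerate Jacobians fall back to h = n_params/n
    (the average leverage).
    """
    n, p = t.size, params.size
    jac = np.empty((n, p))
    base = form.evaluate(t, params)
    for j in range(p):
        step = 1e-6 * max(abs(params[j]), 1e-6)
        pj = params.copy()
        pj[j] += step
        jac[:, j] = (form.evaluate(t, pj) - base) / step
    try:
        u, s, _ = np.linalg.svd(jac, full_matrices=False)
        keep = s > s.max() * 1e-10 if s.size and s.max() > 0 else np.zeros(s.size, bool)
        h = np.sum(u[:, keep] ** 2, axis=1)
    except np.linalg.LinAlgError:
        h = np.full(n, p / n)
    if not np.all(np.isfinite(h)):
        h = np.full(n, p / n)
    return np.clip(h, 0.0, 0.95)


def bootstrap_ci(
    obs: TraitObservationSet,
    fit: FittedTPC,
    n_resamples: int = 500,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Residual-bootstrap percentile intervals for the derived traits.

    Leverage-corrected residuals from the selected fit (e_i / sqrt(1-h_i),
    with hat values h_i from the Jacobian at the estimate — raw residuals
    systematically underestimate the error scale because the fit absorbs
    one degree of freedom per parameter) are centered, resampled with
    replacement, added to the fitted values, truncated at zero, and the
    *selected form only* is refit (single start at the point estimate).
    Each successful refit contributes re-derived thermal traits; percentile
    intervals at ``level`` are taken over the defined values. Resamples
    whose refit fails are dropped and counted; more than 50% failures sets
    a warning.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    form = list_model_forms()[fit.form_name]
    t, y = obs.temperatures, obs.rates
    fitted = form.evaluate(t, fit.params)
    resid = (y - fitted) / np.sqrt(1.0 - _hat_values(form, fit.params, t))
    resid = resid - resid.mean()
    lo_b, hi_b = form.bounds
    rng = np.random.default_rng(seed)
    start = np.clip(fit.params, lo_b, hi_b)

    draws: dict[str, list[float]] = {k: [] for k in ("rmax", "topt", "ctmin", "ctmax", "q10")}
    n_failed = 0
    for _ in range(n_resamples):
        y_star = np.maximum(fitted + rng.choice(resid, size=resid.size, replace=True), 0.0)

        def residuals(p: np.ndarray) -> np.ndarray:
            r = form.evaluate(t, p) - y_star
            return np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)

        try:
            with np.errstate(all="ignore"):
                res = optimize.least_squares(
                    residuals, start, bounds=(lo_b, hi_b), method="trf", max_nfev=500
                )
        except (ValueError, FloatingPointError):
            n_failed += 1
            continue
        if not res.success or not np.isfinite(res.cost):
            n_failed += 1
            continue
        traits = derive_parameters(form, res.x, fit.t_obs_min, fit.t_obs_max)
        draws["rmax"].append(traits.rmax)
        draws["topt"].append(traits.topt)
        if traits.ctmin is not None:
            draws["ctmin"].append(traits.ctmin)
        if traits.ctmax is not None:
            draws["ctmax"].append(traits.ctmax)
        if traits.q10 is not None:
            draws["q10"].append(traits.q10)

    alpha = (1.0 - level) / 2.0
    intervals: dict[str, tuple[float, float]] = {}
    n_defined: dict[str, int] = {}
    for key, values in draws.items():
        n_defined[key] = len(values)
        if values:
            arr = np.asarray(values)
            intervals[key] = (
                float(np.quantile(arr, alpha)),
                float(np.quantile(arr, 1.0 - alpha)),
            )
    warning = None
    if n_failed > n_resamples / 2:
        warning = f"{n_failed}/{n_resamples} bootstrap refits failed"
    return BootstrapResult(
        species=obs.species,
        n_resamples=n_resamples,
        n_failed=n_failed,
        nominal_level=level,
        intervals=intervals,
        n_defined=n_defined,
        seed=seed,
        warning=warning,
    )
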