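"""Registry of nonlinear thermal performance curve (TPC) model forms.

A thermal performance curve describes how a biological rate (here,
feeding-related traits such as ingestion or prey-capture rate) varies with
temperature: typically a unimodal, left-skewed curve rising to a maximum
``rmax`` at the thermal optimum ``Topt`` and collapsing toward the critical
limits. No single functional form fits all traits and taxa well, so the
standard practice is to fit a battery of candidate forms per species and
select among them by information criterion.

This module provides exactly 22 candidate forms drawn from the ectotherm
thermal-biology literature, each with:

* a vectorized ``evaluate(temperature, params)`` on the Celsius scale,
  guaranteed finite for any finite temperature with in-bounds parameters;
* per-parameter box bounds used by the bounded least-squares fitter;
* a start-value heuristic mapping observed (temperature, rate) data to an
  initial parameter vector inside the bounds.

Forms that can go negative outside their thermal window (quadratic, Brière,
Thomas, Spain, Hinshelwood, ...) are evaluated *raw* here: clamping to zero
is a projection-stage concern, and the fitter must see the true functional
form. The registry order is fixed and versioned because it participates in
tie-breaking during model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "TPCModelForm",
    "ModelRegistry",
    "ObservationSummary",
    "list_model_forms",
    "evaluate_form",
    "start_values",
    "BOLTZMANN_EV",
]

#: Boltzmann constant in eV/K, used by the thermodynamic (Arrhenius-type) forms.
BOLTZMANN_EV = 8.617333262e-5

#: Reference temperature (Kelvin) for Sharpe–Schoolfield normalisation (20 °C).
_TREF_K = 293.15

_EXP_CLIP = 500.0  # exp argument clip keeping every form finite in float64


def _exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def _kelvin(t: np.ndarray) -> np.ndarray:
    return t + 273.15


@dataclass(frozen=True)
class ObservationSummary:
    """Scale information extracted from one species' observations.

    Start-value heuristics only ever see this summary, which makes them
    cheap and deterministic: ``rmax_obs`` is the maximum observed rate,
    ``topt_obs`` the temperature where it occurs (lowest such temperature on
    ties), and ``tmin_obs``/``tmax_obs`` the observed temperature span.
    """

    rmax_obs: float
    topt_obs: float
    tmin_obs: float
    tmax_obs: float

    @property
    def span(self) -> float:
        return max(self.tmax_obs - self.tmin_obs, 1.0)

    @classmethod
    def from_points(cls, temperatures: Sequence[float], rates: Sequence[float]) -> "ObservationSummary":
        t = np.asarray(temperatures, dtype=float)
        r = np.asarray(rates, dtype=float)
        if t.size == 0:
            raise ValueError("cannot summarise empty observations")
        order = np.argsort(t, kind="stable")  # lowest-T tie-break below
        t_sorted, r_sorted = t[order], r[order]
        imax = int(np.flatnonzero(r_sorted == r_sorted.max())[0])
        return cls(
            rmax_obs=float(r_sorted[imax]),
            topt_obs=float(t_sorted[imax]),
            tmin_obs=float(t_sorted.min()),
            tmax_obs=float(t_sorted.max()),
        )


@dataclass(frozen=True)
class TPCModelForm:
    """One candidate TPC functional form."""

    name: str
    param_names: tuple[str, ...]
    citation: str
    _evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    _bounds_lo: tuple[float, ...]
    _bounds_hi: tuple[float, ...]
    _start: Callable[[ObservationSummary], np.ndarray]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self._bounds_lo, float), np.asarray(self._bounds_hi, float)

    def evaluate(self, temperature, params) -> np.ndarray:
        """Rate at ``temperature`` (°C); vectorizes over array input."""
        p = np.asarray(params, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(
                f"form {self.name!r} takes {self.n_params} parameters "
                f"({', '.join(self.param_names)}); got {p.size}"
            )
        t = np.asarray(temperature, dtype=float)
        scalar = t.ndim == 0
        with np.errstate(all="ignore"):
            out = np.asarray(self._evaluate(np.atleast_1d(t), p), dtype=float)
        out = np.nan_to_num(out, nan=0.0, posinf=np.finfo(float).max / 1e10,
                            neginf=-np.finfo(float).max / 1e10)
        return float(out[0]) if scalar else out

    def start_values(self, summary: ObservationSummary) -> np.ndarray:
        """Initial parameter vector from the observation summary, clipped into bounds."""
        lo, hi = self.bounds
        p0 = np.asarray(self._start(summary), dtype=float)
        # keep strictly interior so jittered multi-starts have room to move
        width = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        return np.clip(p0, lo + 1e-9 * np.abs(width), np.minimum(hi, np.nan_to_num(hi, posinf=1e30)))


# --------------------------------------------------------------------------
# form definitions
# --------------------------------------------------------------------------

def _quadratic(t, p):
    a, b, c = p
    return a + b * t + c * t * t


def _quadratic_start(s: ObservationSummary) -> np.ndarray:
    c = -s.rmax_obs / (s.span / 2.0) ** 2
    b = -2.0 * c * s.topt_obs
    a = s.rmax_obs + c * s.topt_obs**2
    return np.array([a, b, c])


def _gaussian(t, p):
    rmax, topt, width = p
    return rmax * _exp(-0.5 * ((t - topt) / width) ** 2)


def _briere1(t, p):
    a, tmin, tmax = p
    inside = (t > tmin) & (t < tmax)
    out = np.zeros_like(t)
    ti = t[inside]
    out[inside] = a * ti * (ti - tmin) * np.sqrt(np.maximum(tmax - ti, 0.0))
    return out


def _briere_scale(s: ObservationSummary, tmin: float, tmax: float, exponent: float = 0.5) -> float:
    tpk = np.clip(s.topt_obs, tmin + 1e-3, tmax - 1e-3)
    shape = tpk * (tpk - tmin) * (tmax - tpk) ** exponent
    return s.rmax_obs / shape if shape > 0 else 1e-4


def _flinn(t, p):
    a, b, c = p
    den = 1.0 + a + b * t + c * t * t
    den = np.where(np.abs(den) < 1e-8, np.copysign(1e-8, den), den)
    return 1.0 / den


def _flinn_start(s: ObservationSummary) -> np.ndarray:
    c = 1.0 / (max(s.rmax_obs, 1e-6) * (s.span / 2.0) ** 2)
    b = -2.0 * c * s.topt_obs
    a = 1.0 / max(s.rmax_obs, 1e-6) - 1.0 - b * s.topt_obs - c * s.topt_obs**2
    return np.array([a, b, c])


def _modified_gaussian(t, p):
    rmax, topt, width, shape = p
    return rmax * _exp(-0.5 * (np.abs(t - topt) / width) ** shape)


def _briere2(t, p):
    a, tmin, tmax, b = p
    inside = (t > tmin) & (t < tmax)
    out = np.zeros_like(t)
    ti = t[inside]
    out[inside] = a * ti * (ti - tmin) * np.maximum(tmax - ti, 0.0) ** (1.0 / b)
    return out


def _lactin2(t, p):
    a, b, tmax, dt = p
    return _exp(a * t) - _exp(a * tmax - (tmax - t) / dt) + b


def _lactin2_start(s: ObservationSummary) -> np.ndarray:
    a = np.log(s.rmax_obs + 1.0) / max(s.topt_obs, 5.0)
    return np.array([min(a, 1.5), 0.0, s.tmax_obs + 3.0, 3.0])


def _ratkowsky(t, p):
    a, b, tmin, tmax = p
    return (a * (t - tmin) * (1.0 - _exp(b * (t - tmax)))) ** 2


def _ratkowsky_start(s: ObservationSummary) -> np.ndarray:
    a = np.sqrt(s.rmax_obs) / s.span
    return np.array([a, 0.2, s.tmin_obs - 5.0, s.tmax_obs + 3.0])


def _ss_core(t, r_tref, e):
    tk = _kelvin(t)
    return r_tref * _exp(e / BOLTZMANN_EV * (1.0 / _TREF_K - 1.0 / tk))


def _sharpeschoolfield_high(t, p):
    r_tref, e, eh, th = p
    tk = _kelvin(t)
    inact = _exp(eh / BOLTZMANN_EV * (1.0 / _kelvin(th) - 1.0 / tk))
    return _ss_core(t, r_tref, e) / (1.0 + inact)


def _sharpeschoolfield_low(t, p):
    r_tref, e, el, tl = p
    tk = _kelvin(t)
    inact = _exp(el / BOLTZMANN_EV * (1.0 / _kelvin(tl) - 1.0 / tk))
    return _ss_core(t, r_tref, e) / (1.0 + inact)


def _sharpeschoolfield_full(t, p):
    r_tref, e, el, tl, eh, th = p
    tk = _kelvin(t)
    low = _exp(el / BOLTZMANN_EV * (1.0 / _kelvin(tl) - 1.0 / tk))
    high = _exp(eh / BOLTZMANN_EV * (1.0 / _kelvin(th) - 1.0 / tk))
    return _ss_core(t, r_tref, e) / (1.0 + low + high)


def _ss_start(s: ObservationSummary, *, full: bool = False, low: bool = False) -> np.ndarray:
    e = 0.6
    # r_tref so the Arrhenius part alone matches the observed scale at 20 °C
    r_tref = s.rmax_obs * np.exp(-e / BOLTZMANN_EV * (1.0 / _TREF_K - 1.0 / (s.topt_obs + 273.15)))
    r_tref = float(np.clip(r_tref, 1e-8, 1e8))
    if full:
        return np.array([r_tref, e, 2.0, s.tmin_obs - 2.0, 4.0, s.tmax_obs + 2.0])
    if low:
        return np.array([r_tref, e, 2.0, s.tmin_obs - 2.0])
    return np.array([r_tref, e, 4.0, s.tmax_obs + 2.0])


def _weibull(t, p):
    a, topt, b, c = p
    f = (c - 1.0) / c
    base = (t - topt) / b + f ** (1.0 / c)
    base = np.maximum(base, 0.0)
    return a * f ** ((1.0 - c) / c) * base ** (c - 1.0) * _exp(-(base**c) + f)


def _thomas1(t, p):
    a, b, z, w = p
    return a * _exp(b * t) * (1.0 - ((t - z) / (w / 2.0)) ** 2)


def _thomas1_start(s: ObservationSummary) -> np.ndarray:
    b = 0.05
    a = s.rmax_obs * np.exp(-b * s.topt_obs)
    return np.array([a, b, s.topt_obs, 2.0 * s.span])


def _rezende(t, p):
    a, q10, b, c = p
    rise = a * 10.0 ** (np.log10(np.maximum(q10, 1e-9)) * t / 10.0)
    fall = np.where(t > b, 1.0 - c * (b - t) ** 2, 1.0)
    return rise * fall


def _rezende_start(s: ObservationSummary) -> np.ndarray:
    q10 = 2.0
    a = s.rmax_obs / 10.0 ** (np.log10(q10) * s.topt_obs / 10.0)
    c = 1.0 / max((s.tmax_obs - s.topt_obs) * 2.0, 1.0) ** 2
    return np.array([a, q10, s.topt_obs, c])


def _rosso(t, p):
    rmax, topt, ctmin, ctmax = p
    out = np.zeros_like(t)
    ok = (t > ctmin) & (t < ctmax) & (ctmin < topt) & (topt < ctmax)
    ti = t[ok]
    num = (ti - ctmax) * (ti - ctmin) ** 2
    den = (topt - ctmin) * (
        (topt - ctmin) * (ti - topt) - (topt - ctmax) * (topt + ctmin - 2.0 * ti)
    )
    out[ok] = np.where(np.abs(den) > 1e-12, rmax * num / den, 0.0)
    return out


def _oneill(t, p):
    rmax, ctmax, topt, q10 = p
    w = np.maximum((q10 - 1.0) * (ctmax - topt), 1e-6)
    x = (w**2 / 400.0) * (1.0 + np.sqrt(1.0 + 40.0 / w)) ** 2
    v = (ctmax - t) / np.maximum(ctmax - topt, 1e-6)
    v = np.maximum(v, 0.0)
    return rmax * v**x * _exp(x * (1.0 - v))


def _johnsonlewin(t, p):
    r0, e, eh, topt = p
    if eh <= e:
        return np.zeros_like(t)
    tk = _kelvin(t)
    topt_k = topt + 273.15
    phi = eh / topt_k + BOLTZMANN_EV * np.log(e / (eh - e))
    return r0 * _exp(-e / (BOLTZMANN_EV * tk)) / (1.0 + _exp(-(eh - phi * tk) / (BOLTZMANN_EV * tk)))


def _johnsonlewin_start(s: ObservationSummary) -> np.ndarray:
    e, eh = 0.6, 3.0
    topt_k = s.topt_obs + 273.15
    r0 = 2.0 * s.rmax_obs * np.exp(e / (BOLTZMANN_EV * topt_k))
    return np.array([float(np.clip(r0, 1e-6, 1e200)), e, eh, s.topt_obs])


def _deutsch(t, p):
    rmax, topt, ctmax, a = p
    below = rmax * _exp(-(((t - topt) / (2.0 * a)) ** 2))
    span = np.maximum(topt - ctmax, -1e6)
    above = rmax * (1.0 - ((t - topt) / np.where(np.abs(span) < 1e-6, 1e-6, span)) ** 2)
    return np.where(t <= topt, below, above)


def _hinshelwood(t, p):
    a, e, b, eh = p
    tk = _kelvin(t)
    return a * _exp(-e / (BOLTZMANN_EV * tk)) - b * _exp(-eh / (BOLTZMANN_EV * tk))


def _hinshelwood_start(s: ObservationSummary) -> np.ndarray:
    e, eh = 0.6, 2.5
    topt_k = s.topt_obs + 273.15
    a = s.rmax_obs / max(1.0 - e / eh, 0.1) * np.exp(e / (BOLTZMANN_EV * topt_k))
    b = a * (e / eh) * np.exp((eh - e) / (BOLTZMANN_EV * topt_k))
    return np.array([float(np.clip(a, 1e-6, 1e190)), e, float(np.clip(b, 1e-6, 1e190)), eh])


def _spain(t, p):
    a, b, c, d = p
    return a * _exp(b * t) * (1.0 - c * _exp(d * t))


def _spain_start(s: ObservationSummary) -> np.ndarray:
    b, d = 0.1, 0.15
    c = b / ((b + d) * np.exp(d * s.topt_obs))
    peak_shape = np.exp(b * s.topt_obs) * (1.0 - c * np.exp(d * s.topt_obs))
    a = s.rmax_obs / peak_shape if peak_shape > 0 else s.rmax_obs
    return np.array([a, b, c, d])


def _joehnk(t, p):
    rmax, topt, a, b, c = p
    dt = t - topt
    bb = _exp(dt * np.log(b))
    cc = _exp(dt * np.log(c))
    return rmax * (1.0 + a * ((bb - 1.0) - (np.log(b) / np.log(c)) * (cc - 1.0)))


def _boatman(t, p):
    rmax, tmin, tmax, a, b = p
    out = np.zeros_like(t)
    inside = (t >= tmin) & (t <= tmax) & (tmax > tmin)
    prog = (t[inside] - tmin) / (tmax - tmin)
    out[inside] = rmax * np.sin(np.pi * prog**a) ** b
    return out


def _F(  # noqa: N802 - tiny local factory keeps the table below readable
    name: str,
    params: tuple[str, ...],
    citation: str,
    fn,
    lo: tuple[float, ...],
    hi: tuple[float, ...],
    start,
) -> TPCModelForm:
    return TPCModelForm(name, params, citation, fn, lo, hi, start)


_INF = np.inf

_FORMS: tuple[TPCModelForm, ...] = (
    # -- 3-parameter forms ---------------------------------------------------
    _F("quadratic", ("a", "b", "c"),
       "concave second-order polynomial (e.g. Montagnes et al. 2008)",
       _quadratic, (-1e6, -1e6, -1e6), (1e6, 1e6, 0.0), _quadratic_start),
    _F("gaussian", ("rmax", "topt", "width"),
       "Gaussian TPC (Lynch & Gabriel 1987)",
       _gaussian, (1e-10, -60.0, 1e-2), (1e6, 80.0, 100.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, s.span / 4.0])),
    _F("briere1", ("a", "tmin", "tmax"),
       "Brière et al. 1999, simplified (exponent 1/2)",
       _briere1, (1e-12, -80.0, -60.0), (1e6, 80.0, 100.0),
       lambda s: np.array([_briere_scale(s, s.tmin_obs - 5.0, s.tmax_obs + 5.0),
                           s.tmin_obs - 5.0, s.tmax_obs + 5.0])),
    _F("flinn", ("a", "b", "c"),
       "Flinn 1991 inverse-quadratic",
       _flinn, (-1e6, -1e6, -1e6), (1e6, 1e6, 1e6), _flinn_start),
    # -- 4-parameter forms ---------------------------------------------------
    _F("modified_gaussian", ("rmax", "topt", "width", "shape"),
       "Gaussian with free exponent (Angilletta 2006)",
       _modified_gaussian, (1e-10, -60.0, 1e-2, 0.2), (1e6, 80.0, 100.0, 10.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, s.span / 4.0, 2.0])),
    _F("briere2", ("a", "tmin", "tmax", "b"),
       "Brière et al. 1999, free exponent 1/b",
       _briere2, (1e-12, -80.0, -60.0, 0.5), (1e6, 80.0, 100.0, 12.0),
       lambda s: np.array([_briere_scale(s, s.tmin_obs - 5.0, s.tmax_obs + 5.0, 0.5),
                           s.tmin_obs - 5.0, s.tmax_obs + 5.0, 2.0])),
    _F("lactin2", ("a", "b", "tmax", "delta_t"),
       "Lactin et al. 1995, two-parameter variant with intercept",
       _lactin2, (1e-6, -1e3, -20.0, 0.1), (2.0, 1e3, 100.0, 50.0), _lactin2_start),
    _F("ratkowsky", ("a", "b", "tmin", "tmax"),
       "Ratkowsky et al. 1983 square-root model",
       _ratkowsky, (1e-8, 1e-4, -80.0, -20.0), (100.0, 5.0, 60.0, 100.0), _ratkowsky_start),
    _F("sharpeschoolfield_high", ("r_tref", "e", "eh", "th"),
       "Sharpe & DeMichele 1977 / Schoolfield et al. 1981, high-T inactivation only (Tref 20 degC)",
       _sharpeschoolfield_high, (1e-10, 0.01, 0.02, -40.0), (1e8, 10.0, 40.0, 100.0),
       lambda s: _ss_start(s)),
    _F("sharpeschoolfield_low", ("r_tref", "e", "el", "tl"),
       "Schoolfield et al. 1981, low-T inactivation only (Tref 20 degC)",
       _sharpeschoolfield_low, (1e-10, 0.01, 0.02, -60.0), (1e8, 10.0, 40.0, 80.0),
       lambda s: _ss_start(s, low=True)),
    _F("weibull", ("a", "topt", "b", "c"),
       "Weibull-type TPC (Angilletta 2006)",
       _weibull, (1e-10, -60.0, 1e-2, 1.01), (1e6, 80.0, 300.0, 30.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, s.span, 3.0])),
    _F("thomas1", ("a", "b", "z", "w"),
       "Thomas et al. 2012 exponential-times-parabola",
       _thomas1, (1e-12, -0.5, -60.0, 1.0), (1e6, 0.5, 80.0, 300.0), _thomas1_start),
    _F("rezende", ("a", "q10", "b", "c"),
       "Rezende & Bozinovic 2019 piecewise Q10-rise with quadratic decline",
       _rezende, (1e-12, 1.01, -40.0, 1e-8), (1e6, 10.0, 80.0, 10.0), _rezende_start),
    _F("rosso", ("rmax", "topt", "ctmin", "ctmax"),
       "Rosso et al. 1993 cardinal-temperature model (Lobry-Rosso-Flandrois)",
       _rosso, (1e-10, -50.0, -80.0, -40.0), (1e6, 70.0, 60.0, 100.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, s.tmin_obs - 5.0, s.tmax_obs + 5.0])),
    _F("oneill", ("rmax", "ctmax", "topt", "q10"),
       "O'Neill et al. 1972",
       _oneill, (1e-10, -40.0, -50.0, 1.05), (1e6, 100.0, 70.0, 10.0),
       lambda s: np.array([s.rmax_obs, s.tmax_obs + 5.0, s.topt_obs, 2.0])),
    _F("johnsonlewin", ("r0", "e", "eh", "topt"),
       "Johnson & Lewin 1946",
       _johnsonlewin, (1e-10, 0.01, 0.05, -50.0), (1e60, 3.0, 20.0, 70.0), _johnsonlewin_start),
    _F("deutsch", ("rmax", "topt", "ctmax", "a"),
       "Deutsch et al. 2008 Gaussian-rise / quadratic-fall",
       _deutsch, (1e-10, -50.0, -40.0, 0.1), (1e6, 70.0, 100.0, 100.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, s.tmax_obs + 5.0, s.span / 3.0])),
    _F("hinshelwood", ("a", "e", "b", "eh"),
       "Hinshelwood 1947 difference of Arrhenius terms",
       _hinshelwood, (1e-10, 0.01, 1e-10, 0.1), (1e60, 3.0, 1e120, 6.0), _hinshelwood_start),
    _F("spain", ("a", "b", "c", "d"),
       "Spain 1982 exponential-rise with exponential inhibition",
       _spain, (1e-12, 1e-4, 1e-8, 1e-4), (1e6, 1.0, 10.0, 1.0), _spain_start),
    # -- 5- and 6-parameter forms ---------------------------------------------
    _F("joehnk", ("rmax", "topt", "a", "b", "c"),
       "Joehnk et al. 2008",
       _joehnk, (1e-10, -50.0, 1e-4, 1.0001, 1.0002), (1e6, 70.0, 100.0, 3.0, 3.0),
       lambda s: np.array([s.rmax_obs, s.topt_obs, 1.0, 1.05, 1.10])),
    _F("boatman", ("rmax", "tmin", "tmax", "a", "b"),
       "Boatman et al. 2017 power-sine",
       _boatman, (1e-10, -80.0, -60.0, 0.05, 0.05), (1e6, 80.0, 100.0, 20.0, 20.0),
       lambda s: np.array([s.rmax_obs, s.tmin_obs - 5.0, s.tmax_obs + 5.0, 1.0, 1.0])),
    _F("sharpeschoolfield_full", ("r_tref", "e", "el", "tl", "eh", "th"),
       "Schoolfield et al. 1981, full low+high inactivation (Tref 20 degC)",
       _sharpeschoolfield_full,
       (1e-10, 0.01, 0.02, -60.0, 0.02, -40.0), (1e8, 10.0, 40.0, 80.0, 40.0, 100.0),
       lambda s: _ss_start(s, full=True)),
)


class ModelRegistry:
    """Ordered, immutable collection of the 22 candidate TPC forms."""

    def __init__(self, forms: Sequence[TPCModelForm]):
        self._forms = tuple(forms)
        names = [f.name for f in self._forms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate form names in registry")
        self._by_name = {f.name: f for f in self._forms}

    @property
    def forms(self) -> tuple[TPCModelForm, ...]:
        return self._forms

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self._forms)

    def __len__(self) -> int:
        return len(self._forms)

    def __iter__(self) -> Iterator[TPCModelForm]:
        return iter(self._forms)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TPCModelForm:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown TPC form {name!r}; known forms: {', '.join(self.names)}"
            ) from None

    def order_index(self, name: str) -> int:
        """Position of a form in the fixed registry order (AIC tie-break key)."""
        return self.names.index(name)


_REGISTRY = ModelRegistry(_FORMS)


def list_model_forms() -> ModelRegistry:
    """Return the fixed registry of 22 candidate model forms."""
    return _REGISTRY


def evaluate_form(form: TPCModelForm, params, temperature):
    """Evaluate ``form`` at ``temperature`` (°C) — convenience wrapper."""
    return form.evaluate(temperature, params)


def start_values(form: TPCModelForm, temperatures, rates) -> np.ndarray:
    """Heuristic initial parameters for ``form`` given raw observations."""
    t = np.asarray(temperatures, float)
    if t.size == 0:
        raise ValueError("start_values requires non-empty observations")
    return form.start_values(ObservationSummary.from_points(t, np.asarray(rates, float)))
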