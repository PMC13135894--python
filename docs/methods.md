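# Methods

This note documents the models, numerical choices and limitations behind
`thermshift`, in the package's own terms.

## Thermal performance curves and the candidate set

A thermal performance curve (TPC) maps temperature to a biological rate:
near zero at a lower limit, rising to a maximum `rmax` at the thermal
optimum `Topt`, collapsing toward an upper limit. Because no single
functional form is adequate across traits and taxa, the package fits a
fixed battery of **22 candidate forms** per species and selects among
them. The registry (in `thermshift.models`, each form with its source
citation) spans simple polynomials (quadratic, Flinn), Gaussian-type
curves (Gaussian, modified Gaussian, Weibull, Deutsch), degree-day-style
windows (Brière-1/2, Ratkowsky, Boatman, Rosso cardinal-temperature,
O'Neill, Thomas), exponential-rise-with-inhibition forms (Lactin-2,
Spain, Rezende, Joehnk) and thermodynamic forms (Sharpe–Schoolfield full/high/low with reference
temperature 20 °C, Johnson–Lewin, Hinshelwood). The exact composition of
the candidate set is a documented package choice; what matters downstream
is that all species are scored against the same fixed, ordered set of 22.
Registry order is versioned because it participates in tie-breaking.

Forms that can go negative outside their window (quadratic, Brière,
Thomas, Spain, Hinshelwood) are evaluated raw during fitting — the
optimizer must see the true functional form — and clamped only at
projection time. Every form is guarded to return finite values for any
finite temperature with in-bounds parameters (exponent arguments clipped
at ±500; denominators floored at 1e−8), so the optimizer never sees NaN.

## Fitting and model selection

Each form is fit by bounded nonlinear least squares (trust-region
reflective) from `n_starts = 10` initials: a per-form heuristic start
(peak-rate/peak-temperature read off the data; window edges padded 5 °C
beyond the observed span) jittered ±20% multiplicatively, seeded. The
lowest-RSS converged run wins.

Selection uses **AICc** with the residual variance counted as a
parameter, `k = n_params + 1`:

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1),

undefined (form treated as non-converged) when `n − k − 1 ≤ 0`. AICc
rather than plain AIC is the package default because the trait datasets
are small (often 10–25 points); plain AIC is available via
`aic_variant="aic"`. Ties are broken by fewer parameters, then registry
order. Exclusion rules: `insufficient_data` (< 4 distinct test
temperatures), `no_convergence` (no form converges), or
`implausible_parameters` (no converged fit passes plausibility).

Plausibility is an explicit stand-in for "unrealistic estimates":
reject when `rmax ≤ 0`, when `Topt` lies more than 10 °C outside the
observed temperature span, or when the thermal breadth
`CTmax − CTmin` (both defined) exceeds 80 °C.

## Derived thermal traits

On the selected curve, the optimum is located by a 0.01 °C grid scan over
the observed span padded ±25 °C, refined by bounded scalar minimisation
(the pad admits limits slightly outside the design without chasing
asymptotes of open-ended forms). `CTmin`/`CTmax` are the nearest
zero-crossings below/above the optimum (bisection on the bracketing grid
interval), undefined for curves that never reach zero (e.g. Gaussian).
`Q10 = rmax / f(Topt − 10)` — the rising-limb definition over the 10 °C
below the optimum — undefined when `f(Topt − 10) ≤ 0`. The interval
convention is configurable in principle but fixed here and documented;
other conventions (e.g. Q10 between two arbitrary temperatures) change
the number.

## Bootstrap uncertainty

Uncertainty uses a **residual bootstrap**: residuals from the selected
fit — leverage-corrected as e_i/√(1−h_i), with hat values from the
Jacobian at the estimate, because raw residuals from a fitted model
underestimate the error scale by the degrees of freedom the fit absorbs —
are centered, resampled with replacement, added to fitted values,
truncated at zero (rates are non-negative), and the *selected form only*
is refit from the point estimate; derived traits are recomputed per
resample and 95% percentile intervals are taken over defined values.
Residual rather than case resampling preserves the temperature design,
which is sparse and structured; resamples with failed refits are dropped
and counted (> 50% failures flags a warning). Intervals quantify
parameter uncertainty only — they are **not** propagated into the spatial
projections, which use the best-fit curve.

A simulation study (`thermshift.validation`) measures empirical coverage
of the Topt intervals under a Gaussian truth (rmax 1, Topt 20 °C, width
5 °C, 20 temperatures over [5, 35] °C, additive noise with sd 5% of the
peak): with the leverage correction, empirical coverage of the nominal
95% intervals sits around 90–92% depending on the simulation block;
without it, coverage drops several points further, which is why the
correction is the default. The residual gap is attributable to the
zero-truncation of rates, which makes the noise mildly heteroscedastic
(edge-temperature errors are truncated and smaller-scaled), so pooled
residual resampling slightly under-scales the informative central
points — a known limitation of i.i.d. residual resampling; the wild
bootstrap, which preserves per-point scale, performs worse at n = 20
because single residual magnitudes are too noisy a scale estimate.

## Synthetic data

The generator exists so every stage can be tested against known truth.

* **Traits**: temperatures evenly spaced over the species' range;
  `rate = form(T; θ_true) + N(0, noise_cv · rmax_true)`, truncated at 0.
  Defaults: 15 temperatures, `noise_cv = 0.05`, one replicate. Additive
  peak-scaled noise (not multiplicative lognormal) keeps
  parameter-recovery tolerances interpretable; the truncation mirrors the
  non-negativity of empirical feeding rates.
* **Climate**: a cos²-latitude gradient between an equatorial (27 °C) and
  polar (−18 °C) mean, a 12-month sinusoidal seasonal cycle (default
  amplitude 8 °C) peaking in July in the northern hemisphere and January
  in the southern, smooth-field land–sea mask at a target land fraction
  (default 0.3), and cell-level Gaussian noise (sd 0.5 °C) shared between
  scenarios, so that **future = baseline + warming offset exactly**
  (default +2 °C). Default grid 36×72 (5° cells) — desk-scale; finer
  grids are supported.
* **Study fixture**: species counts per realm (the study composition is
  4 freshwater + 16 marine + 8 terrestrial = 28), generating forms cycled
  over Gaussian/quadratic/Rosso/Deutsch with realm-plausible optima
  (freshwater ~20 °C, marine ~16 °C, terrestrial ~26 °C ± 4 °C).

What the generator does **not** emulate: heteroscedastic or
multiplicative trait noise, replicate structure, spatially realistic
continents, climate-model spread, non-uniform warming patterns, or
seasonal asymmetries. Passing tests therefore demonstrate correctness of
the pipeline's computations and calibration under a clean, known truth —
not predictive skill on empirical data.

## Projection

`THS(T) = FR_t / FR_opt`, clipped to [0, 1]; the clip guards only
grid-refinement rounding at the peak (asserted ≤ 1e−9 in tests).
Predicted rates clamp negatives to zero and force zero outside
[CTmin, CTmax] when both limits exist — belt and braces, since some forms
decay naturally and others cross zero. Monthly layers are averaged
arithmetically; a cell missing any month is missing in the annual mean
(the conservative reading of a 12-month average). Grids must already
share a common raster definition: there is no implicit resampling, and
misaligned inputs raise an alignment error. Annual means are per-cell
temporal means; spatial (area) weighting belongs to extent computation,
not aggregation.

## Change analysis

Class boundaries are left-closed/right-open with a closed top class,
resolving the ambiguity of shared interval endpoints; 0.4 is Moderate,
0.8 and 1.0 are Massive. Extents weight cells by cos(latitude of cell
center) on a spherical Earth (R = 6371 km), reported in km² with raw
cell counts alongside; per-scenario class extents partition the total
unmasked area (relative tolerance 1e−6). Percent change of a class
absent at baseline is reported as undefined ("new"), not a number.

Range expansion follows the strict rule: a species is range-expanding iff
the area-weighted extent of cells with THS ≥ 0.6 increases from baseline
to future. Monitoring priority is a heuristic on the relative change `r`
of that extent: |r| ≥ 20% → Priority, 5% ≤ |r| < 20% → Surveillance,
else NoIssue (+∞ when suitable habitat appears from a zero baseline →
Priority). The 5%/20% cutoffs are invented, configurable defaults — the
underlying concern matrix is qualitative — and every output carries the
thresholds used.

## Problem sizes and determinism

Default analysis sizes: 28 species × 15 temperatures; 36×72 grid × 12
months × 2 scenarios; 10 multi-starts × 22 forms per species; 200–500
bootstrap resamples; the coverage study uses 200 simulated datasets ×
500 resamples. Every stochastic stage (noise, jitter, resampling) is
driven by an explicit seed; per-species seeds are derived stably from the
run seed and the species name, so results are independent of table order
and reruns are byte-identical. Floating-point table outputs are written
with 6 significant digits.

## Known limitations

* The index is relative: it ignores absolute metabolic demand, prey
  availability, competition and dispersal; it is a screening proxy, not
  an energetic balance.
* Laboratory-derived TPCs tend to overestimate field optima (ad libitum
  food, constant temperatures); projections are physiological potential,
  not realized performance.
* Monthly means hide daily extremes; annual averaging hides seasonal
  mismatch.
* Parameter uncertainty is quantified but not propagated into maps or
  class assignments.
* The candidate-set composition and the plausibility thresholds are
  package choices; sensible alternatives exist and would shift
  species-level selections without changing the pipeline's structure.
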