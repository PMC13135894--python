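# thermshift

Thermal performance curves → climate-scenario projections of feeding
suitability.

`thermshift` is for thermal ecologists and risk assessors who want to turn
laboratory feeding-trait measurements of ectotherms (ingestion rate, prey
capture, digestion — any rate measured across test temperatures) into
global, scenario-comparable maps of where a species can feed effectively,
and how that changes under warming.

## The method

For each species the package:

1. **Fits thermal performance curves (TPCs).** Twenty-two standard
   nonlinear forms from the ectotherm literature (quadratic, Gaussian,
   Brière, Lactin, Ratkowsky, Sharpe–Schoolfield variants, Weibull,
   O'Neill, Rosso, Deutsch, …) are fit to the (temperature, rate) data by
   bounded least squares with seeded multi-start initials. The best form
   is selected by small-sample-corrected Akaike information criterion
   (AICc); species are excluded when no form converges or every converged
   fit is implausible.
2. **Derives thermal traits.** From the selected curve: the peak rate
   *r*<sub>max</sub>, thermal optimum *T*<sub>opt</sub>, critical limits
   CT<sub>min</sub>/CT<sub>max</sub> (zero-crossings around the optimum,
   when they exist) and the temperature sensitivity
   *Q*<sub>10</sub> = *r*<sub>max</sub> / *f*(*T*<sub>opt</sub> − 10).
   Uncertainty comes from a residual bootstrap (95% percentile intervals)
   that refits the selected form.
3. **Projects Thermal Habitat Suitability (THS).** For monthly temperature
   grids of a baseline and a future climate scenario,

   THS(*T*) = FR<sub>*t*</sub> / FR<sub>opt</sub> ∈ [0, 1],

   the predicted feeding rate at the cell's temperature scaled by the rate
   at the optimum, computed per cell per month, averaged over the 12
   months, and masked to each species' realm (marine → sea cells,
   freshwater/terrestrial → land cells).
4. **Quantifies change.** Annual THS is classified into five classes —
   Minimal [0, 0.2), Minor [0.2, 0.4), Moderate [0.4, 0.6), Major
   [0.6, 0.8), Massive [0.8, 1.0] — with cosine-latitude-weighted extents
   (km²) and absolute/percent changes between scenarios, per-cell ΔTHS,
   a range-expansion flag (strict increase of the THS ≥ 0.6 extent) and a
   heuristic monitoring priority (Priority / Surveillance / NoIssue at
   ±20% / ±5% relative extent change).

A synthetic-data module generates trait observations from known curves
and paired baseline/future monthly climatologies, so the whole pipeline
is testable end to end against ground truth.

## Worked example

```python
import numpy as np
from thermshift import (SyntheticTPCSpec, generate_tpc_observations,
                        fit_all_forms, compute_ths)

# noisy observations from a Gaussian TPC: rmax=1, Topt=20 °C, width=5 °C
spec = SyntheticTPCSpec("gaussian", (1.0, 20.0, 5.0), n_temperatures=20,
                        temperature_range=(5, 35), noise_cv=0.05, seed=3)
obs = generate_tpc_observations(spec)

sel = fit_all_forms(obs, seed=1)          # scores all 22 candidate forms
fit = sel.selected
print(fit.form_name, round(fit.topt, 2), round(fit.rmax, 3))
print(round(float(compute_ths(fit, 25.0)), 3))
```

prints

```
modified_gaussian 19.97 1.111
0.491
```

— the AICc-best form (here a modified Gaussian, whose free shape
exponent absorbs sampling noise slightly better than the generating
form), a thermal optimum recovered within 0.03 °C of the true 20 °C, a
peak rate near the true 1.0, and a suitability of ~0.49 at 25 °C: the
cell is five degrees above the optimum, so the species is predicted to
feed at about half its maximal rate there.

The `analysis/` scripts run the full study workflow on synthetic data
(`01_simulate.py` → `04_change_priority.py`), writing tables under
`results/`. The `thermshift` command-line tool exposes the same stages
(`simulate`, `models list`, `fit`, `project`, `change`, `run`).

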