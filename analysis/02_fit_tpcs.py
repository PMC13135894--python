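#!/usr/bin/env python
"""Fit thermal performance curves to every species.

Scores all 22 candidate model forms per species by AICc, applies the
convergence and plausibility exclusion rules, derives thermal traits
(rmax, Topt, CTmin, CTmax, Q10) and residual-bootstrap 95% confidence
intervals for the selected curve.

Reads results/traits.csv; writes results/fit_report.csv,
results/bootstrap_intervals.json and scratch/selected_fits.json (the
selected parameters, reused by the projection step).
"""

import json
from pathlib import Path

import pandas as pd

from thermshift import read_trait_table
from thermshift.fitting import bootstrap_ci, filter_observations, fit_all_forms
from thermshift.io import FLOAT_FORMAT

SEED = 1
N_STARTS = 10
N_BOOT = 200
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    traits = read_trait_table(ROOT / "results" / "traits.csv")
    filtered = filter_observations(traits)

    rows, intervals, selected = [], {}, {}
    for species, reason in sorted(filtered.excluded.items()):
        rows.append({"species": species, "status": "excluded", "exclusion_reason": reason})
    for obs in filtered.observations:
        sel = fit_all_forms(obs, n_starts=N_STARTS, seed=SEED)
        if sel.selected is None:
            rows.append({"species": obs.species, "realm": obs.realm, "status": "excluded",
                         "exclusion_reason": sel.exclusion_reason})
            continue
        f = sel.selected
        rows.append({
            "species": obs.species, "realm": obs.realm, "status": "fitted",
            "form": f.form_name, "aicc": f.aicc, "rmax": f.rmax, "topt": f.topt,
            "ctmin": f.ctmin, "ctmax": f.ctmax, "q10": f.q10,
        })
        boot = bootstrap_ci(obs, f, n_resamples=N_BOOT, level=0.95, seed=SEED)
        intervals[obs.species] = {k: list(v) for k, v in boot.intervals.items()}
        selected[obs.species] = {
            "realm": f.realm, "form_name": f.form_name, "params": list(f.params),
            "t_obs_min": f.t_obs_min, "t_obs_max": f.t_obs_max,
        }

    report = pd.DataFrame(rows)
    report.to_csv(ROOT / "results" / "fit_report.csv", index=False, float_format=FLOAT_FORMAT)
    with open(ROOT / "results" / "bootstrap_intervals.json", "w") as fh:
        json.dump(intervals, fh, indent=1, sort_keys=True)
    with open(ROOT / "scratch" / "selected_fits.json", "w") as fh:
        json.dump(selected, fh, indent=1, sort_keys=True)

    fitted = report[report["status"] == "fitted"]
    print(f"fitted {len(fitted)} / {len(report)} species "
          f"({len(report) - len(fitted)} excluded)")
    if len(fitted):
        print("selected forms:", fitted["form"].value_counts().to_dict())
        print("Topt range: %.1f-%.1f °C" % (fitted["topt"].min(), fitted["topt"].max()))


if __name__ == "__main__":
    main()
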