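"""Filtering, least-squares fitting, selection, derived traits, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from thermshift import (
    SyntheticTPCSpec,
    TraitObservationSet,
    generate_tpc_observations,
    list_model_forms,
)
from thermshift.fitting import (
    bootstrap_ci,
    derive_parameters,
    filter_observations,
    fit_all_forms,
    fit_single_form,
    plausibility_filter,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["species", "realm", "trait", "temperature_C", "rate"])


class TestFilterObservations:
    def test_negative_rate_rows_removed_others_kept(self):
        rows = [("a", "marine", "ing", t, r) for t, r in
                [(5, 0.1), (10, 0.5), (15, 1.0), (20, 0.8), (25, -0.2)]]
        res = filter_observations(_table(rows))
        obs = res.observations[0]
        assert len(obs) == 4
        assert np.all(obs.rates >= 0)

    def test_too_few_distinct_temperatures_excluded(self):
        rows = [("a", "marine", "ing", t, 1.0) for t in (5, 10, 15)]
        res = filter_observations(_table(rows))
        assert res.observations == ()
        assert res.excluded == {"a": "insufficient_data"}

    def test_clean_table_passes_unchanged(self):
        rows = [("a", "marine", "ing", t, r) for t, r in
                [(5, 0.1), (10, 0.5), (15, 1.0), (20, 0.8)]]
        res = filter_observations(_table(rows))
        assert len(res.observations[0]) == 4
        assert res.n_rows_dropped == 0
        assert res.excluded == {}

    def test_duplicate_rows_collapse(self):
        rows = [("a", "marine", "ing", t, r) for t, r in
                [(5, 0.1), (5, 0.1), (10, 0.5), (15, 1.0), (20, 0.8)]]
        res = filter_observations(_table(rows))
        assert len(res.observations[0]) == 4

    def test_missing_values_dropped(self):
        rows = [("a", "marine", "ing", t, r) for t, r in
                [(5, 0.1), (10, None), (None, 0.4), (15, 1.0), (20, 0.8), (25, 0.2)]]
        res = filter_observations(_table(rows))
        assert len(res.observations[0]) == 4

    def test_missing_columns_schema_error(self):
        with pytest.raises(ValueError, match="missing required columns"):
            filter_observations(pd.DataFrame({"species": ["a"], "rate": [1.0]}))


class TestFitSingleForm:
    def test_zero_noise_gaussian_recovers_truth(self, clean_gaussian_obs, registry):
        fit = fit_single_form(clean_gaussian_obs, registry["gaussian"], n_starts=5, seed=1)
        assert fit.converged
        assert fit.params[1] == pytest.approx(20.0, abs=1e-3)
        assert fit.params[0] == pytest.approx(1.0, rel=1e-3)

    def test_seeded_multistart_is_deterministic(self, registry):
        spec = SyntheticTPCSpec("gaussian", (1.0, 20.0, 5.0), noise_cv=0.05, seed=9)
        obs = generate_tpc_observations(spec)
        a = fit_single_form(obs, registry["gaussian"], n_starts=10, seed=42)
        b = fit_single_form(obs, registry["gaussian"], n_starts=10, seed=42)
        assert np.array_equal(a.params, b.params)
        assert a.rss == b.rss

    def test_criterion_undefined_when_dof_exhausted(self, registry):
        # n=4 and gaussian k=4: n-k-1 < 0 -> non-converged, AICc undefined
        obs = TraitObservationSet("a", "marine", "ing",
                                  np.array([10.0, 15.0, 20.0, 25.0]),
                                  np.array([0.2, 0.8, 1.0, 0.5]))
        fit = fit_single_form(obs, registry["gaussian"], n_starts=3, seed=0)
        assert not fit.converged
        assert math.isnan(fit.aicc)


class TestDeriveParameters:
    def test_quadratic_closed_form_oracle(self, registry):
        traits = derive_parameters(registry["quadratic"], [-3.0, 0.4, -0.01], 10.0, 30.0)
        assert traits.topt == pytest.approx(20.0, abs=0.01)
        assert traits.rmax == pytest.approx(1.0, abs=1e-4)
        assert traits.ctmin == pytest.approx(10.0, abs=0.01)
        assert traits.ctmax == pytest.approx(30.0, abs=0.01)
        # rate at Topt-10 = 10 °C is exactly zero -> Q10 undefined
        assert traits.q10 is None

    def test_gaussian_q10_matches_e_squared(self, registry):
        traits = derive_parameters(registry["gaussian"], [1.0, 20.0, 5.0], 5.0, 35.0)
        assert traits.q10 == pytest.approx(np.exp(2.0), rel=1e-4)
        assert traits.ctmin is None and traits.ctmax is None

    def test_topt_confined_to_extended_window(self, registry):
        # monotone rising curve: optimum lands on the upper window edge
        traits = derive_parameters(registry["quadratic"], [0.0, 0.01, 0.0], 5.0, 35.0)
        assert traits.topt <= 35.0 + 25.0 + 1e-6


class TestPlausibility:
    def test_topt_beyond_observed_span_excluded(self, registry):
        obs = TraitObservationSet("a", "marine", "ing",
                                  np.linspace(5, 25, 8), np.linspace(0.1, 1.0, 8))
        traits = derive_parameters(registry["gaussian"], [1.0, 40.0, 5.0], 5.0, 25.0)
        keep, reason = plausibility_filter(traits, obs)
        assert not keep and reason == "implausible_parameters"

    def test_healthy_fit_kept(self, clean_gaussian_obs, registry):
        traits = derive_parameters(registry["gaussian"], [1.0, 20.0, 5.0], 5.0, 35.0)
        keep, reason = plausibility_filter(traits, clean_gaussian_obs)
        assert keep and reason is None

    def test_flat_fit_with_zero_rmax_excluded(self, clean_gaussian_obs):
        from thermshift.fitting import ThermalTraits
        traits = ThermalTraits(rmax=0.0, topt=20.0, ctmin=None, ctmax=None, q10=None)
        keep, _ = plausibility_filter(traits, clean_gaussian_obs)
        assert not keep

    def test_excessive_thermal_breadth_excluded(self, clean_gaussian_obs):
        from thermshift.fitting import ThermalTraits
        traits = ThermalTraits(rmax=1.0, topt=20.0, ctmin=-50.0, ctmax=45.0, q10=2.0)
        keep, _ = plausibility_filter(traits, clean_gaussian_obs)
        assert not keep


@pytest.fixture(scope="module")
def selection():
    spec = SyntheticTPCSpec("gaussian", (1.0, 20.0, 5.0), n_temperatures=20,
                            temperature_range=(5.0, 35.0), noise_cv=0.05, seed=3)
    obs = generate_tpc_observations(spec)
    return obs, fit_all_forms(obs, n_starts=5, seed=1)


class TestFitAllForms:
    def test_every_candidate_form_scored(self, selection, registry):
        _, sel = selection
        assert len(sel.table) == 22
        assert list(sel.table["form_name"]) == list(registry.names)

    def test_selected_is_minimum_aicc_among_plausible(self, selection):
        _, sel = selection
        ok = sel.table[sel.table["converged"] & sel.table["plausible"]]
        assert sel.selected is not None
        assert sel.selected.aicc == pytest.approx(ok["aicc"].min())

    def test_selection_invariant_to_observation_order(self, selection):
        obs, sel = selection
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(obs))
        shuffled = TraitObservationSet(obs.species, obs.realm, obs.trait,
                                       obs.temperatures[perm], obs.rates[perm])
        sel2 = fit_all_forms(shuffled, n_starts=5, seed=1)
        assert sel2.selected.form_name == sel.selected.form_name
        assert sel2.selected.topt == pytest.approx(sel.selected.topt, abs=1e-6)

    def test_insufficient_data_short_circuits(self):
        obs = TraitObservationSet("a", "marine", "ing",
                                  np.array([5.0, 10.0, 15.0]), np.array([0.1, 0.5, 1.0]))
        sel = fit_all_forms(obs, n_starts=1, seed=0)
        assert sel.selected is None
        assert sel.exclusion_reason == "insufficient_data"

    def test_aicc_tie_breaks_to_fewer_parameters(self):
        """Construct a tie and check the documented tie-break ordering."""
        candidates = [(-10.0, 4, 5), (-10.0, 3, 7), (-10.0, 3, 2)]
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        assert candidates[0] == (-10.0, 3, 2)


class TestBootstrap:
    def test_nominal_level_echoed_and_reproducible(self, registry):
        spec = SyntheticTPCSpec("gaussian", (1.0, 20.0, 5.0), n_temperatures=20,
                                noise_cv=0.05, seed=6)
        obs = generate_tpc_observations(spec)
        fit = fit_single_form(obs, registry["gaussian"], n_starts=5, seed=1)
        from conftest import make_fitted
        fitted = make_fitted("gaussian", fit.params, 5.0, 35.0)
        a = bootstrap_ci(obs, fitted, n_resamples=100, level=0.95, seed=7)
        b = bootstrap_ci(obs, fitted, n_resamples=100, level=0.95, seed=7)
        assert a.nominal_level == 0.95
        assert a.intervals == b.intervals

    def test_zero_noise_gives_zero_width_intervals(self, clean_gaussian_obs, gaussian_fit):
        res = bootstrap_ci(clean_gaussian_obs, gaussian_fit, n_resamples=50, seed=0)
        lo, hi = res.intervals["topt"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)
        assert res.n_failed == 0

    def test_point_estimate_inside_interval(self, registry):
        spec = SyntheticTPCSpec("gaussian", (1.0, 20.0, 5.0), n_temperatures=20,
                                noise_cv=0.05, seed=8)
        obs = generate_tpc_observations(spec)
        fit = fit_single_form(obs, registry["gaussian"], n_starts=5, seed=1)
        from conftest import make_fitted
        fitted = make_fitted("gaussian", fit.params, 5.0, 35.0)
        res = bootstrap_ci(obs, fitted, n_resamples=200, seed=3)
        lo, hi = res.intervals["topt"]
        assert lo <= fitted.topt <= hi
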