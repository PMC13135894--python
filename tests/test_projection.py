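"""THS projection: normalization, clamping, aggregation, masking, monotonicity."""

import numpy as np
import pytest

from thermshift import (
    AlignmentError,
    GridDefinition,
    TemperatureGridStack,
    THSGrid,
    annual_mean,
    apply_realm_mask,
    compute_ths,
    predict_rate,
    project_annual_ths,
    project_monthly,
)


def uniform_stack(temp: float, n_lat: int = 4, n_lon: int = 6,
                  land: bool | np.ndarray = True) -> TemperatureGridStack:
    grid = GridDefinition(np.linspace(60, -60, n_lat), np.linspace(-150, 150, n_lon))
    months = np.full((12, n_lat, n_lon), float(temp))
    if isinstance(land, bool):
        land = np.full(grid.shape, land)
    return TemperatureGridStack(grid=grid, months=months, land_mask=land)


class TestPredictRate:
    def test_negative_raw_prediction_clamped(self, quadratic_fit):
        # -0.01 (5-10)(5-30) = -1.25 raw -> 0
        assert predict_rate(quadratic_fit, 5.0) == 0.0

    def test_peak_value_preserved(self, quadratic_fit, gaussian_fit):
        assert predict_rate(quadratic_fit, 20.0) == pytest.approx(1.0)
        assert predict_rate(gaussian_fit, gaussian_fit.topt) == pytest.approx(gaussian_fit.rmax)

    def test_zero_outside_critical_limits(self, quadratic_fit):
        assert quadratic_fit.ctmin == pytest.approx(10.0, abs=0.01)
        assert predict_rate(quadratic_fit, 9.0) == 0.0
        assert predict_rate(quadratic_fit, 31.0) == 0.0

    def test_nonfinite_temperature_gives_nodata(self, gaussian_fit):
        out = predict_rate(gaussian_fit, np.array([20.0, np.nan, np.inf]))
        assert np.isfinite(out[0])
        assert np.isnan(out[1]) and np.isnan(out[2])


class TestComputeTHS:
    def test_unity_at_thermal_optimum(self, gaussian_fit):
        assert compute_ths(gaussian_fit, gaussian_fit.topt) == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_value_from_closed_form(self, quadratic_fit):
        # rate(15) = -0.01 (15-10)(15-30) = 0.75 and rmax = 1
        assert compute_ths(quadratic_fit, 15.0) == pytest.approx(0.75, abs=1e-6)

    def test_zero_outside_limits(self, quadratic_fit):
        assert compute_ths(quadratic_fit, 5.0) == 0.0

    def test_bounded_to_unit_interval_everywhere(self, gaussian_fit, quadratic_fit):
        t = np.linspace(-40, 70, 2201)
        for fit in (gaussian_fit, quadratic_fit):
            v = compute_ths(fit, t)
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_requires_positive_rmax(self, gaussian_fit):
        import dataclasses
        broken = dataclasses.replace(gaussian_fit, rmax=0.0)
        with pytest.raises(ValueError, match="positive peak rate"):
            compute_ths(broken, 20.0)


class TestProjectMonthly:
    def test_uniform_topt_grid_is_unity_every_month(self, quadratic_fit):
        stack = uniform_stack(20.0)
        layers = project_monthly(quadratic_fit, stack, realm="terrestrial")
        assert layers.shape == (12, 4, 6)
        assert np.allclose(layers, 1.0)

    def test_masked_cells_are_nodata_in_all_months(self, quadratic_fit):
        land = np.ones((4, 6), bool)
        land[0, :] = False
        stack = uniform_stack(20.0, land=land)
        layers = project_monthly(quadratic_fit, stack, realm="terrestrial")
        assert np.all(np.isnan(layers[:, 0, :]))
        assert np.all(np.isfinite(layers[:, 1:, :]))

    def test_month_permutation_gives_same_layer_multiset(self, gaussian_fit):
        stack = uniform_stack(18.0)
        months = stack.months.copy()
        months[3] = 25.0
        stack_a = TemperatureGridStack(stack.grid, months, stack.land_mask)
        perm = np.roll(np.arange(12), 5)
        stack_b = TemperatureGridStack(stack.grid, months[perm], stack.land_mask)
        la = project_monthly(gaussian_fit, stack_a, realm="terrestrial")
        lb = project_monthly(gaussian_fit, stack_b, realm="terrestrial")
        assert np.allclose(np.sort(la, axis=0), np.sort(lb, axis=0), equal_nan=True)


class TestAnnualMean:
    def grid(self):
        return GridDefinition(np.array([10.0, -10.0]), np.array([0.0, 20.0]))

    def test_constant_months_average_to_constant(self):
        g = self.grid()
        out = annual_mean(np.full((12, 2, 2), 0.4), g)
        assert np.allclose(out.values, 0.4)

    def test_half_and_half_averages_to_half(self):
        g = self.grid()
        layers = np.concatenate([np.ones((6, 2, 2)), np.zeros((6, 2, 2))])
        assert np.allclose(annual_mean(layers, g).values, 0.5)

    def test_any_missing_month_voids_the_cell(self):
        g = self.grid()
        layers = np.full((12, 2, 2), 0.4)
        layers[7, 0, 0] = np.nan
        out = annual_mean(layers, g)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1, 1])

    def test_wrong_layer_count_rejected(self):
        with pytest.raises(ValueError, match="12 monthly layers"):
            annual_mean(np.zeros((11, 2, 2)), self.grid())


class TestRealmMask:
    def grid_values(self):
        g = GridDefinition(np.array([10.0, -10.0]), np.array([0.0, 20.0]))
        return THSGrid(grid=g, values=np.full((2, 2), 0.7))

    def test_marine_species_on_all_land_mask_all_nodata(self):
        ths = self.grid_values()
        out = apply_realm_mask(ths, "marine", np.ones((2, 2), bool))
        assert np.all(np.isnan(out.values))

    def test_terrestrial_keeps_land_voids_sea(self):
        ths = self.grid_values()
        land = np.array([[True, False], [False, True]])
        out = apply_realm_mask(ths, "terrestrial", land)
        assert np.isfinite(out.values[0, 0]) and np.isfinite(out.values[1, 1])
        assert np.isnan(out.values[0, 1]) and np.isnan(out.values[1, 0])

    def test_shifted_origin_mask_is_alignment_error(self):
        ths = self.grid_values()
        shifted = GridDefinition(np.array([12.0, -8.0]), np.array([0.0, 20.0]))
        with pytest.raises(AlignmentError):
            apply_realm_mask(ths, "marine", np.ones((2, 2), bool), mask_grid=shifted)


class TestProjectionInvariants:
    def test_grid_held_at_topt_gives_annual_unity(self, gaussian_fit):
        stack = uniform_stack(gaussian_fit.topt)
        out = project_annual_ths(gaussian_fit, stack, realm="terrestrial")
        assert np.allclose(out.values, 1.0)

    def test_projection_is_deterministic(self, gaussian_fit):
        stack = uniform_stack(17.3)
        a = project_annual_ths(gaussian_fit, stack, realm="terrestrial")
        b = project_annual_ths(gaussian_fit, stack, realm="terrestrial")
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("t_base, delta", [(10.0, 2.0), (14.0, 5.9), (18.0, 1.9)])
    def test_warming_below_topt_never_decreases_ths(self, gaussian_fit, t_base, delta):
        assert t_base + delta <= gaussian_fit.topt
        cold = project_annual_ths(gaussian_fit, uniform_stack(t_base), realm="terrestrial")
        warm = project_annual_ths(gaussian_fit, uniform_stack(t_base + delta), realm="terrestrial")
        assert np.all(warm.values >= cold.values)
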