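"""Unit and property tests for the linearized climate model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulseflow import (
    ClimateModel,
    ConfigError,
    TimeGrid,
    co2_fraction_remaining,
    cumulative_impact,
    gas_fraction_remaining,
)


class TestTimeGrid:
    def test_points_strictly_increasing(self):
        grid = TimeGrid(horizon_years=10, step_years=0.5)
        assert np.all(np.diff(grid.times) > 0)
        assert grid.n_steps == 20
        assert grid.times[-1] == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"horizon_years": 0},
            {"horizon_years": 1001},
            {"horizon_years": 10, "step_years": 0.0},
            {"horizon_years": 10, "step_years": -1.0},
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            TimeGrid(**kwargs)

    def test_millennial_horizon_supported(self):
        assert TimeGrid(horizon_years=1000).n_steps == 1000


class TestFractionRemaining:
    def test_co2_starts_at_one_and_floors_at_a0(self, model):
        irf = model.config.co2_irf
        assert co2_fraction_remaining(0.0, irf) == pytest.approx(1.0)
        assert co2_fraction_remaining(1e6, irf) == pytest.approx(irf.a0)

    def test_co2_monotone_decay_with_persistent_fraction(self, model):
        irf = model.config.co2_irf
        grid = np.linspace(0.0, 1000.0, 4001)
        vals = co2_fraction_remaining(grid, irf)
        assert np.all(np.diff(vals) < 0)
        v50, v100 = co2_fraction_remaining([50.0, 100.0], irf)
        assert irf.a0 < v100 < v50 < 1.0

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError):
            co2_fraction_remaining(-1.0, model.config.co2_irf)
        with pytest.raises(ValueError):
            gas_fraction_remaining(-1.0, model.config.gas("CH4"))

    def test_single_lifetime_efolding(self, model):
        ch4 = model.config.gas("CH4")
        assert gas_fraction_remaining(0.0, ch4) == pytest.approx(1.0)
        assert gas_fraction_remaining(
            ch4.perturbation_lifetime_years, ch4
        ) == pytest.approx(np.exp(-1.0))
        assert gas_fraction_remaining(118.0, ch4) == pytest.approx(
            np.exp(-10.0), rel=1e-3
        )

    def test_co2_has_no_single_lifetime(self, model):
        with pytest.raises(ConfigError):
            gas_fraction_remaining(10.0, model.config.gas("CO2"))

    def test_lifetime_and_potency_ordering(self, model):
        ch4, n2o, co2 = (model.config.gas(g) for g in ("CH4", "N2O", "CO2"))
        assert ch4.perturbation_lifetime_years < n2o.perturbation_lifetime_years
        assert (
            n2o.effective_efficiency
            > ch4.effective_efficiency
            > co2.effective_efficiency
        )


class TestPulseForcing:
    @given(mass=st.floats(min_value=1e-3, max_value=1e9))
    def test_linear_in_mass(self, model, grid100, mass):
        unit = model.rf_pulse("CH4", 1.0, grid100).annual_values
        scaled = model.rf_pulse("CH4", mass, grid100).annual_values
        np.testing.assert_allclose(scaled, mass * unit, rtol=1e-9)

    def test_zero_mass_gives_zero_series(self, model, grid100):
        assert not model.rf_pulse("N2O", 0.0, grid100).annual_values.any()

    def test_negative_mass_rejected(self, model, grid100):
        with pytest.raises(ValueError):
            model.rf_pulse("CO2", -1.0, grid100)

    def test_unknown_gas_rejected(self, model, grid100):
        with pytest.raises(ConfigError):
            model.rf_pulse("SF6", 1.0, grid100)

    def test_year_one_potency_ordering(self, model, grid100):
        year_one = {
            g: model.rf_pulse(g, 1.0, grid100).value_at(1)
            for g in ("CO2", "CH4", "N2O")
        }
        assert year_one["N2O"] > year_one["CH4"] > year_one["CO2"]


class TestContinuousForcing:
    def test_superposition_of_staggered_pulses(self, model):
        """Continuous flow equals an independently coded double-loop sum of
        one annual pulse per year."""
        grid = TimeGrid(horizon_years=40)
        for gas in ("CH4", "CO2"):
            pulse = model.rf_pulse(gas, 1.0, grid).annual_values
            oracle = np.zeros(grid.n_steps)
            for start in range(grid.n_steps):
                for t in range(start, grid.n_steps):
                    oracle[t] += pulse[t - start]
            cont = model.rf_continuous(gas, 1.0, grid).annual_values
            np.testing.assert_allclose(cont, oracle, rtol=1e-12)

    def test_zero_rate_gives_zero_series(self, model, grid100):
        assert not model.rf_continuous("CH4", 0.0, grid100).annual_values.any()

    def test_single_lifetime_plateau(self, model):
        """Direct forcing under a constant rate is monotone, bounded by the
        geometric-sum limit, and within 1% of rate x efficiency x lifetime
        at year 300."""
        grid = TimeGrid(horizon_years=300)
        rf = model.rf_continuous(
            "CH4", 1.0, grid, include_feedback=False
        ).annual_values
        gas = model.config.gas("CH4")
        eff_nw_per_t = gas.effective_efficiency * 1e12
        tau = gas.perturbation_lifetime_years
        limit = eff_nw_per_t * np.exp(-0.5 / tau) / (1 - np.exp(-1.0 / tau))
        assert np.all(np.diff(rf) >= 0)
        assert np.all(rf <= limit * (1 + 1e-12))
        gap_at_10_lifetimes = 1.0 - rf[int(10 * tau) - 1] / limit
        assert gap_at_10_lifetimes < 1e-4
        assert rf[-1] == pytest.approx(eff_nw_per_t * tau, rel=0.01)

    def test_stabilization_contrast_with_co2(self, model, grid500):
        """CH4 forcing stabilizes under a constant flow; CO2 keeps rising."""
        ch4 = model.rf_continuous("CH4", 1.0, grid500)
        co2 = model.rf_continuous("CO2", 1.0, grid500)
        assert ch4.value_at(500) / ch4.value_at(100) == pytest.approx(1.0, abs=0.05)
        assert co2.value_at(500) / co2.value_at(100) > 2.0


class TestTemperature:
    def test_zero_forcing_zero_temperature(self, model, grid100):
        series = model.rf_pulse("CH4", 0.0, grid100)
        assert not model.temperature_response(series).annual_values.any()

    def test_constant_forcing_approaches_equilibrium(self, model):
        """Sustained forcing F warms towards F x sum(c_j), following the
        exact two-box charging curve."""
        from pulseflow.climate import ImpactSeries

        grid = TimeGrid(horizon_years=1000)
        f = 2.5  # nW m-2, arbitrary
        series = ImpactSeries("RF", grid, np.full(grid.n_steps, f))
        temp = model.temperature_response(series).annual_values
        terms = model.config.temperature_response.terms
        expected = f * sum(
            c * (1 - np.exp(-grid.times / d)) for c, d in terms
        )
        np.testing.assert_allclose(temp, expected, rtol=1e-9)
        equilibrium = f * model.config.temperature_response.equilibrium_response
        assert temp[-1] > 0.9 * equilibrium

    def test_temperature_lags_forcing_for_pulse(self, model, grid100):
        rf = model.rf_pulse("CH4", 1.0, grid100)
        temp = model.temperature_response(rf)
        assert np.argmax(temp.annual_values) > np.argmax(rf.annual_values)

    def test_rejects_temperature_series_input(self, model, grid100):
        temp = model.pulse("CH4", 1.0, grid100, metric="TC")
        with pytest.raises(ValueError):
            model.temperature_response(temp)

    def test_continuous_cumulative_temperature_shapes(self, model, grid500):
        """Cumulative warming from continuous CO2 is convex (annual T keeps
        accelerating is not required — but increments never shrink), while
        continuous CH4 shows a trend towards stabilization: its annual
        warming increments decline once the forcing has plateaued."""
        t_co2 = model.continuous("CO2", 1.0, grid500, metric="TC").annual_values
        t_ch4 = model.continuous("CH4", 1.0, grid500, metric="TC").annual_values
        # second difference of cumulative TC = first difference of annual T
        assert np.all(np.diff(t_co2) > 0)
        increments_ch4 = np.diff(t_ch4)
        assert np.all(np.diff(increments_ch4[100:]) < 0)


class TestCumulativeImpact:
    def test_zero_horizon(self, model, grid100):
        series = model.rf_pulse("CO2", 1.0, grid100)
        assert cumulative_impact(series, 0) == 0.0

    def test_constant_series_rectangle_rule(self, model):
        from pulseflow.climate import ImpactSeries

        grid = TimeGrid(horizon_years=50)
        series = ImpactSeries("RF", grid, np.full(50, 3.0))
        assert cumulative_impact(series, 50) == pytest.approx(150.0)

    def test_horizon_beyond_grid_rejected(self, model, grid100):
        series = model.rf_pulse("CO2", 1.0, grid100)
        with pytest.raises(ValueError):
            cumulative_impact(series, 101)

    def test_running_integral_consistency(self, model, grid100):
        series = model.rf_pulse("N2O", 1.0, grid100)
        cum = series.cumulative_values
        np.testing.assert_allclose(
            np.diff(cum), series.annual_values[1:] * grid100.step_years
        )
        assert np.all(np.diff(cum) >= 0)  # annual values non-negative

    def test_agwp_integral_against_refined_quadrature(self, model, grid100):
        """Annual-step cumulative forcing of a CO2 pulse agrees with a
        step-0.1 trapezoid integration of the continuous curve within 1%."""
        from scipy.integrate import trapezoid

        series = model.rf_pulse("CO2", 1.0, grid100)
        coarse = cumulative_impact(series, 100)
        gas = model.config.gas("CO2")
        t_fine = np.arange(0.0, 100.0 + 1e-9, 0.1)
        rf_fine = (
            gas.effective_efficiency
            * 1e12
            * co2_fraction_remaining(t_fine, model.config.co2_irf)
        )
        fine = trapezoid(rf_fine, t_fine)
        assert coarse == pytest.approx(fine, rel=0.01)
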