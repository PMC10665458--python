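"""Linearized climate model: forcing and temperature of GHG emissions.

The model propagates a pulse or a continuous flow of CO2, CH4 or N2O through
three linear stages:

1. an atmospheric decay kernel — a multi-exponential impulse response for CO2
   (part of a pulse stays airborne practically indefinitely), a single
   e-folding lifetime for CH4 and N2O;
2. radiative forcing proportional to the remaining burden (effective
   efficiencies include indirect chemistry effects), plus, for CH4/N2O, a
   temperature-driven carbon-cycle feedback term ``beta * T`` representing
   CO2 outgassed by the induced warming;
3. a two-timescale temperature impulse response (mixed layer + deep ocean),
   so that temperature lags forcing.

Discretization: emissions are placed at mid-year and series are evaluated at
year-ends ("year one" = t=1).  A continuous flow is the exact superposition
of one annual pulse per year, which makes the plateau of a single-lifetime
gas approach ``rate x efficiency x lifetime / step`` to within a fraction of
a percent.  Internally everything is SI (W m-2, K, kg); outputs are converted
once at the boundary to nW m-2 and nK per tonne-scale emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    ClimateConfig,
    ClimateResponseParams,
    CO2ResponseParams,
    ConfigError,
    GasSpec,
    TimeGrid,
    load_config,
)

W_TO_NANO = 1e9  # W m-2 -> nW m-2 (and K -> nK)
T_TO_KG = 1e3


def co2_fraction_remaining(t, params: CO2ResponseParams):
    """Fraction of a CO2 pulse still airborne after ``t`` years.

    ``a0 + sum_i a_i exp(-t/tau_i)``: decays slowly, floor ``a0 > 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    acc = np.full_like(t, params.a0)
    for a, tau in params.terms:
        acc = acc + a * np.exp(-t / tau)
    return acc if acc.shape else float(acc)


def gas_fraction_remaining(t, gas: GasSpec):
    """Fraction of a single-lifetime gas (CH4, N2O) remaining after ``t`` years."""
    if gas.perturbation_lifetime_years is None:
        raise ConfigError(
            f"{gas.name} has no single perturbation lifetime; "
            "use co2_fraction_remaining"
        )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-t / gas.perturbation_lifetime_years)
    return out if out.shape else float(out)


@dataclass
class ImpactSeries:
    """Annual and cumulative climate impact on a time grid.

    ``annual_values`` holds the instantaneous impact at each grid point
    (nW m-2 for RF, nK for TC); ``cumulative_values`` the running rectangle
    integral (nW m-2 yr / nK yr), i.e. the area under the curve.
    """

    metric: str  # "RF" or "TC"
    grid: TimeGrid
    annual_values: np.ndarray
    gas: str | None = None
    mode: str | None = None  # "pulse" or "continuous"
    unit: str = field(init=False)

    def __post_init__(self) -> None:
        self.annual_values = np.asarray(self.annual_values, dtype=float)
        if self.metric not in ("RF", "TC"):
            raise ValueError("metric must be 'RF' or 'TC'")
        if self.annual_values.shape != (self.grid.n_steps,):
            raise ValueError("annual_values do not match the grid")
        self.unit = "nW m-2" if self.metric == "RF" else "nK"

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def cumulative_values(self) -> np.ndarray:
        return np.cumsum(self.annual_values) * self.grid.step_years

    def value_at(self, year: float) -> float:
        return float(self.annual_values[self.grid.index_of(year)])

    def cumulative_at(self, year: float) -> float:
        if year == 0:
            return 0.0
        return float(self.cumulative_values[self.grid.index_of(year)])


def cumulative_impact(series: ImpactSeries, horizon: float) -> float:
    """Time-integral of the annual values over [0, horizon] (rectangle rule)."""
    return series.cumulative_at(horizon)


class ClimateModel:
    """Evaluates forcing/temperature series for pulse and continuous emissions."""

    def __init__(self, config: ClimateConfig | None = None):
        self.config = config if config is not None else load_config()

    # -- kernels ---------------------------------------------------------

    def _kernel_step_weights(self, grid: TimeGrid) -> np.ndarray:
        """Exact integral of the temperature kernel over each grid interval.

        Treating forcing as piecewise constant per interval, convolving with
        these weights gives a temperature that converges exactly to
        ``F x sum(c_j)`` under sustained forcing F.
        """
        step = grid.step_years
        u = step * np.arange(grid.n_steps)
        w = np.zeros(grid.n_steps)
        for c, d in self.config.temperature_response.terms:
            w += c * (np.exp(-u / d) - np.exp(-(u + step) / d))
        return w

    def _convolve_temperature(
        self, annual_forcing: np.ndarray, grid: TimeGrid
    ) -> np.ndarray:
        w = self._kernel_step_weights(grid)
        return np.convolve(annual_forcing, w)[: grid.n_steps]

    # -- forcing ---------------------------------------------------------

    def _unit_pulse_rf(
        self, gas: GasSpec, grid: TimeGrid, include_feedback: bool
    ) -> np.ndarray:
        """Forcing (W m-2) of a 1-kg pulse emitted at the mid of interval one."""
        ages = grid.times - 0.5 * grid.step_years
        if gas.perturbation_lifetime_years is None:
            frac = co2_fraction_remaining(ages, self.config.co2_irf)
        else:
            frac = gas_fraction_remaining(ages, gas)
        rf = gas.effective_efficiency * frac
        if include_feedback and gas.carbon_cycle_feedback != 0.0:
            temp = self._convolve_temperature(rf, grid)
            rf = rf + gas.carbon_cycle_feedback * temp
        return rf

    def rf_pulse(
        self,
        gas_name: str,
        mass_t: float,
        grid: TimeGrid | None = None,
        include_feedback: bool = True,
    ) -> ImpactSeries:
        """Radiative forcing of a one-off pulse of ``mass_t`` tonnes."""
        if mass_t < 0:
            raise ValueError("mass must be >= 0")
        grid = grid or self.config.default_grid
        gas = self.config.gas(gas_name)
        rf = mass_t * T_TO_KG * self._unit_pulse_rf(gas, grid, include_feedback)
        return ImpactSeries(
            "RF", grid, rf * W_TO_NANO, gas=gas_name, mode="pulse"
        )

    def rf_continuous(
        self,
        gas_name: str,
        rate_t_per_yr: float,
        grid: TimeGrid | None = None,
        include_feedback: bool = True,
    ) -> ImpactSeries:
        """Forcing of a continuous flow of ``rate_t_per_yr`` tonnes per year.

        Exact superposition of one pulse of ``rate x step`` per interval,
        staggered over the grid (hence a cumulative sum of the pulse series).
        Single-lifetime gases plateau; CO2 keeps rising on any modelled
        horizon because a fraction of every pulse never decays.
        """
        if rate_t_per_yr < 0:
            raise ValueError("rate must be >= 0")
        grid = grid or self.config.default_grid
        gas = self.config.gas(gas_name)
        pulse_kg = rate_t_per_yr * grid.step_years * T_TO_KG
        base = pulse_kg * self._unit_pulse_rf(gas, grid, include_feedback)
        rf = np.cumsum(base)
        return ImpactSeries(
            "RF", grid, rf * W_TO_NANO, gas=gas_name, mode="continuous"
        )

    # -- temperature -----------------------------------------------------

    def temperature_response(self, forcing: ImpactSeries) -> ImpactSeries:
        """Global surface temperature change driven by a forcing series."""
        if forcing.metric != "RF":
            raise ValueError("temperature_response expects an RF series")
        temp = self._convolve_temperature(forcing.annual_values, forcing.grid)
        return ImpactSeries(
            "TC", forcing.grid, temp, gas=forcing.gas, mode=forcing.mode
        )

    # -- conveniences ----------------------------------------------------

    def pulse(
        self,
        gas_name: str,
        mass_t: float,
        grid: TimeGrid | None = None,
        metric: str = "RF",
        include_feedback: bool = True,
    ) -> ImpactSeries:
        rf = self.rf_pulse(gas_name, mass_t, grid, include_feedback)
        return rf if metric.upper() == "RF" else self.temperature_response(rf)

    def continuous(
        self,
        gas_name: str,
        rate_t_per_yr: float,
        grid: TimeGrid | None = None,
        metric: str = "RF",
        include_feedback: bool = True,
    ) -> ImpactSeries:
        rf = self.rf_continuous(gas_name, rate_t_per_yr, grid, include_feedback)
        return rf if metric.upper() == "RF" else self.temperature_response(rf)
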