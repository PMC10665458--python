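"""Equate a continuous CH4/N2O emission stream with a one-off CO2 pulse.

A stabilizing (single-lifetime) gas emitted at a constant rate approaches a
forcing plateau, so its climate impact at a horizon H can be matched by the
impact, at the same H, of a single CO2 removal placed in year one.  The
conversion ratio is

    R(gas, H, metric) = impact of continuous 1 t/yr of gas, at year H
                        -----------------------------------------------
                        impact of a 1 t CO2 pulse in year one, at year H

in tonnes of CO2 per (tonne gas per year).  By default the *end-point* impact
at H is compared (the accumulated burden of the flow vs the decayed pulse);
``basis="cumulative"`` compares time-integrated impact instead, for
sensitivity analysis.  R grows with H — the benefit of the pulse removal
fades while the flow's impact still edges up — and grows faster for N2O,
whose 109-yr lifetime keeps it further from its plateau.

A continuous CO2 flow cannot be equated with any finite one-off removal: its
impact rises without bound.

One tonne of soil carbon is 44/12 t of CO2, so the flow rate that one tonne
of sequestered C can offset over H is ``44/12 * 1000 / R`` kg of gas per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateModel
from .params import TimeGrid

#: exact C -> CO2 molar-mass ratio (1 t C = 44/12 t CO2)
C_TO_CO2 = 44.0 / 12.0

_BASES = ("endpoint", "cumulative")


@dataclass(frozen=True)
class ConversionRatio:
    gas: str
    metric: str
    horizon: int
    co2_per_unit_flow: float  # t CO2 per (t gas / yr)
    offsettable_rate_per_tonne_c: float  # kg gas / yr per t C


def _series_pair(model, gas, metric, grid, basis):
    if gas == "CO2":
        raise ValueError(
            "a continuous CO2 flow cannot be equated to a one-off "
            "sequestration: its impact accumulates without bound"
        )
    metric = metric.upper()
    cont = model.continuous(gas, 1.0, grid, metric=metric)
    pulse = model.pulse("CO2", 1.0, grid, metric=metric)
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")
    if basis == "endpoint":
        return cont.annual_values, pulse.annual_values
    return cont.cumulative_values, pulse.cumulative_values


def co2_pulse_equivalent(
    model: ClimateModel,
    gas: str,
    horizon: int,
    metric: str = "RF",
    *,
    basis: str = "endpoint",
    grid: TimeGrid | None = None,
) -> float:
    """Tonnes of pulse CO2 equivalent to a continuous 1 t/yr flow of ``gas``."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    grid = grid or TimeGrid(horizon_years=int(horizon))
    num, den = _series_pair(model, gas, metric, grid, basis)
    idx = grid.index_of(horizon)
    return float(num[idx] / den[idx])


def offsettable_rate_per_tonne_c(
    model: ClimateModel,
    gas: str,
    horizon: int,
    metric: str = "RF",
    *,
    basis: str = "endpoint",
    grid: TimeGrid | None = None,
) -> float:
    """kg of ``gas`` per year whose impact over ``horizon`` one t C offsets."""
    ratio = co2_pulse_equivalent(
        model, gas, horizon, metric, basis=basis, grid=grid
    )
    return C_TO_CO2 * 1000.0 / ratio


def conversion_curve(
    model: ClimateModel,
    gas: str,
    metric: str = "RF",
    h_max: int = 500,
    *,
    basis: str = "endpoint",
) -> pd.DataFrame:
    """Conversion ratios for every horizon 1..h_max, as a tidy table.

    Each row equals a fresh :func:`co2_pulse_equivalent` call at that horizon
    (series values at year h do not depend on the grid horizon beyond h).
    """
    grid = TimeGrid(horizon_years=int(h_max))
    num, den = _series_pair(model, gas, metric, grid, basis)
    ratios = num / den
    return pd.DataFrame(
        {
            "gas": gas,
            "metric": metric.upper(),
            "horizon": np.arange(1, grid.n_steps + 1),
            "co2_tonnes_per_tonne_yr": ratios,
            "kg_gas_per_yr_per_tonne_c": C_TO_CO2 * 1000.0 / ratios,
        }
    )


def conversion_ratio(
    model: ClimateModel,
    gas: str,
    horizon: int,
    metric: str = "RF",
    *,
    basis: str = "endpoint",
) -> ConversionRatio:
    r = co2_pulse_equivalent(model, gas, horizon, metric, basis=basis)
    return ConversionRatio(
        gas=gas,
        metric=metric.upper(),
        horizon=int(horizon),
        co2_per_unit_flow=r,
        offsettable_rate_per_tonne_c=C_TO_CO2 * 1000.0 / r,
    )
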