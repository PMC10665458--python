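"""Offset accounting for ruminant systems.

Applies the pulse-flow conversion ratios to emission and grassland
inventories: the one-off soil-carbon sequestration required to neutralize
continuous CH4 and N2O emissions, the cattle density a hectare of grassland
can carry if its sequestration potential must pay for the animals' enteric
CH4, and per-region gap tables comparing required sequestration with current
soil organic carbon (SOC) stocks.  Yearly emissions are held constant over
the horizon (a simplification: herd projections are out of scope), and CH4 —
the dominant, fastest-stabilizing ruminant gas — is offset before N2O when a
sequestration capacity cap binds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateModel, ImpactSeries
from .conversion import C_TO_CO2, offsettable_rate_per_tonne_c
from .params import InputError, TimeGrid

OFFSET_GASES = ("CH4", "N2O")
RUMINANT_SPECIES = ("cattle", "buffalo", "sheep", "goat")

EMISSION_COLUMNS = ("region", "species", "gas", "tonnes_per_year")
GRASSLAND_COLUMNS = ("region", "area_ha", "soc_t_per_ha")

GLOBAL_ROW = "GLOBAL"


@dataclass(frozen=True)
class EmissionInventory:
    """Region x species x gas annual emissions, tonnes of gas per year."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmissionInventory":
        missing = [c for c in EMISSION_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"emission table is missing columns {missing}")
        df = df.loc[:, list(EMISSION_COLUMNS)].copy()
        bad_gas = set(df["gas"]) - set(OFFSET_GASES)
        if bad_gas:
            raise InputError(f"emission table has unknown gases {sorted(bad_gas)}")
        if (df["tonnes_per_year"] < 0).any():
            raise InputError("emission table has negative annual masses")
        if df.duplicated(["region", "species", "gas"]).any():
            raise InputError(
                "emission table has duplicate (region, species, gas) rows"
            )
        return cls(df.reset_index(drop=True))

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def totals_by_gas(self, region: str | None = None) -> dict[str, float]:
        """Annual tonnes per gas, for one region or globally."""
        df = self.table
        if region is not None:
            df = df[df["region"] == region]
        sums = df.groupby("gas")["tonnes_per_year"].sum()
        return {g: float(sums.get(g, 0.0)) for g in OFFSET_GASES}


@dataclass(frozen=True)
class GrasslandInventory:
    """Managed grassland per region: area (ha) and SOC stock (t C/ha, 0-30 cm)."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GrasslandInventory":
        missing = [c for c in GRASSLAND_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"grassland table is missing columns {missing}")
        df = df.loc[:, list(GRASSLAND_COLUMNS)].copy()
        if (df["area_ha"] <= 0).any():
            raise InputError("grassland areas must be > 0")
        if (df["soc_t_per_ha"] < 0).any():
            raise InputError("SOC stocks must be >= 0")
        if df["region"].duplicated().any():
            raise InputError("grassland table has duplicate regions")
        return cls(df.reset_index(drop=True))

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    @property
    def total_stock_t(self) -> float:
        return float((self.table["area_ha"] * self.table["soc_t_per_ha"]).sum())


@dataclass(frozen=True)
class OffsetRequirement:
    """One region's required one-off sequestration, split by gas (t C)."""

    region: str
    required_c_ch4: float
    required_c_n2o: float
    area_ha: float | None = None
    current_stock_per_ha: float | None = None

    @property
    def required_c_total(self) -> float:
        return self.required_c_ch4 + self.required_c_n2o

    @property
    def required_c_per_ha(self) -> float | None:
        if self.area_ha is None:
            return None
        return self.required_c_total / self.area_ha

    @property
    def gap_ratio(self) -> float | None:
        """required / current stock (dimensionless); x100 = percent increase."""
        if self.current_stock_per_ha in (None, 0) or self.area_ha is None:
            return None
        return self.required_c_per_ha / self.current_stock_per_ha


def offset_rates(
    model: ClimateModel, horizon: int = 100, metric: str = "RF"
) -> dict[str, float]:
    """kg of gas per year offsettable by one tonne C, per gas."""
    return {
        g: offsettable_rate_per_tonne_c(model, g, horizon, metric)
        for g in OFFSET_GASES
    }


def required_carbon(
    inventory: EmissionInventory,
    model: ClimateModel,
    horizon: int = 100,
    metric: str = "RF",
) -> pd.DataFrame:
    """Per-region and global one-off sequestration requirement (t C).

    required_C = E_CH4 / r_CH4 + E_N2O / r_N2O with E in kg/yr and r the
    per-tonne-C offsettable rates at the chosen horizon and metric.
    """
    if inventory.table.empty:
        raise InputError("emission inventory is empty")
    rates = offset_rates(model, horizon, metric)
    rows = []
    for region in inventory.regions:
        totals = inventory.totals_by_gas(region)
        rows.append(
            {
                "region": region,
                "e_ch4_t_yr": totals["CH4"],
                "e_n2o_t_yr": totals["N2O"],
                "required_c_ch4_t": totals["CH4"] * 1000.0 / rates["CH4"],
                "required_c_n2o_t": totals["N2O"] * 1000.0 / rates["N2O"],
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns="region").sum()
    df.loc[len(df)] = {"region": GLOBAL_ROW, **total.to_dict()}
    df["required_c_t"] = df["required_c_ch4_t"] + df["required_c_n2o_t"]
    return df


def allowed_animal_density(
    seq_potential_t_ha: float,
    ef_ch4_kg_head_yr: float,
    model: ClimateModel,
    horizon: int = 100,
    metric: str = "RF",
) -> float:
    """Cattle per hectare whose enteric CH4 one hectare's sequestration offsets.

    density = potential x r_CH4 / EF, with the potential in t C/ha (bundled
    IPCC-derived range 0-50) and EF the enteric emission factor in
    kg CH4/head/yr.
    """
    if not 0.0 <= seq_potential_t_ha <= 50.0:
        raise ValueError("seq_potential must be within 0-50 t C/ha")
    if ef_ch4_kg_head_yr <= 0:
        raise ValueError("enteric emission factor must be > 0")
    rate = offsettable_rate_per_tonne_c(model, "CH4", horizon, metric)
    return seq_potential_t_ha * rate / ef_ch4_kg_head_yr


def density_grid(
    model: ClimateModel,
    potentials_t_ha: np.ndarray | None = None,
    efs_kg_head_yr: np.ndarray | None = None,
    horizon: int = 100,
    metric: str = "RF",
) -> pd.DataFrame:
    """Allowed-density lattice over sequestration potential x emission factor.

    The default lattice spans potentials 5-50 t C/ha and the display range of
    enteric emission factors, 40-160 kg/head/yr; rows at or above one head
    per hectare are flagged.
    """
    if potentials_t_ha is None:
        potentials_t_ha = np.arange(5.0, 51.0, 5.0)
    if efs_kg_head_yr is None:
        efs_kg_head_yr = np.arange(40.0, 161.0, 20.0)
    rate = offsettable_rate_per_tonne_c(model, "CH4", horizon, metric)
    rows = [
        {
            "seq_potential_t_ha": p,
            "ef_ch4_kg_head_yr": ef,
            "allowed_head_per_ha": p * rate / ef,
        }
        for p in potentials_t_ha
        for ef in efs_kg_head_yr
    ]
    df = pd.DataFrame(rows)
    df["at_least_one_head_per_ha"] = df["allowed_head_per_ha"] >= 1.0
    return df


def gap_table(
    emissions: EmissionInventory,
    grasslands: GrasslandInventory,
    model: ClimateModel,
    horizon: int = 100,
    metric: str = "RF",
) -> pd.DataFrame:
    """Required sequestration vs current SOC stock, per region plus global."""
    missing = sorted(set(emissions.regions) - set(grasslands.regions))
    if missing:
        raise InputError(
            f"regions present in emissions but absent in grasslands: {missing}"
        )
    req = required_carbon(emissions, model, horizon, metric)
    req = req[req["region"] != GLOBAL_ROW]
    gl = grasslands.table.set_index("region")
    rows = []
    for rec in req.itertuples():
        area = float(gl.loc[rec.region, "area_ha"])
        soc = float(gl.loc[rec.region, "soc_t_per_ha"])
        r = OffsetRequirement(
            region=rec.region,
            required_c_ch4=rec.required_c_ch4_t,
            required_c_n2o=rec.required_c_n2o_t,
            area_ha=area,
            current_stock_per_ha=soc,
        )
        rows.append(
            {
                "region": r.region,
                "required_c_t": r.required_c_total,
                "area_ha": area,
                "required_c_t_ha": r.required_c_per_ha,
                "current_stock_t_ha": soc,
                "current_stock_t": area * soc,
                "gap_ratio": r.gap_ratio,
                "percent_increase": 100.0 * r.gap_ratio,
            }
        )
    df = pd.DataFrame(rows)
    tot_req = df["required_c_t"].sum()
    tot_area = df["area_ha"].sum()
    tot_stock = df["current_stock_t"].sum()
    df.loc[len(df)] = {
        "region": GLOBAL_ROW,
        "required_c_t": tot_req,
        "area_ha": tot_area,
        "required_c_t_ha": tot_req / tot_area,
        "current_stock_t_ha": tot_stock / tot_area,
        "current_stock_t": tot_stock,
        "gap_ratio": tot_req / tot_stock,
        "percent_increase": 100.0 * tot_req / tot_stock,
    }
    return df


@dataclass(frozen=True)
class CapacityAllocation:
    """Result of allocating a sequestration capacity, CH4 first."""

    capacity_t_c: float
    allocated_ch4_t_c: float
    allocated_n2o_t_c: float
    ch4_fraction: float
    n2o_fraction: float
    unused_t_c: float


def capacity_capped_offset(
    requirement: OffsetRequirement, capacity_t_c: float
) -> CapacityAllocation:
    """Allocate a capped capacity sequentially: CH4 first, N2O the residual."""
    if capacity_t_c < 0:
        raise ValueError("capacity must be >= 0")
    used_ch4 = min(capacity_t_c, requirement.required_c_ch4)
    used_n2o = min(capacity_t_c - used_ch4, requirement.required_c_n2o)
    frac = lambda used, need: 1.0 if need == 0 else used / need
    return CapacityAllocation(
        capacity_t_c=capacity_t_c,
        allocated_ch4_t_c=used_ch4,
        allocated_n2o_t_c=used_n2o,
        ch4_fraction=frac(used_ch4, requirement.required_c_ch4),
        n2o_fraction=frac(used_n2o, requirement.required_c_n2o),
        unused_t_c=capacity_t_c - used_ch4 - used_n2o,
    )


PROFILE_SHAPES = ("one_off_pulse", "linear_ramp", "exponential_approach")


@dataclass(frozen=True)
class SequestrationProfile:
    """Timing profile of a soil-carbon removal totalling ``total_c`` t C.

    ``one_off_pulse`` books everything in year one (the default accounting
    assumption); ``linear_ramp`` sequesters at a constant annual rate so the
    stock ramps linearly over ``duration`` years; ``exponential_approach``
    sequesters fastest first, the stock approaching its new equilibrium with
    an e-folding time of a quarter of ``duration``.  All shapes are
    normalized so annual removals sum exactly to ``total_c``.
    """

    shape: str
    total_c: float
    duration: int = 1

    def __post_init__(self) -> None:
        if self.shape not in PROFILE_SHAPES:
            raise ValueError(f"shape must be one of {PROFILE_SHAPES}")
        if self.total_c < 0:
            raise ValueError("total_c must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")

    def annual_removals(self) -> np.ndarray:
        """t C removed in each year 1..duration; sums to total_c."""
        if self.shape == "one_off_pulse":
            w = np.zeros(self.duration)
            w[0] = 1.0
        elif self.shape == "linear_ramp":
            w = np.ones(self.duration)
        else:
            years = np.arange(self.duration)
            w = np.exp(-years / (self.duration / 4.0))
        w = w / w.sum()
        return self.total_c * w


def profile_impact(
    profile: SequestrationProfile,
    model: ClimateModel,
    grid: TimeGrid | None = None,
    metric: str = "RF",
) -> ImpactSeries:
    """Net (negative) impact of a removal schedule, by superposition.

    Each year's removal enters as a mid-year CO2 pulse of 44/12 times the
    carbon mass, with a negative sign (sequestration is a negative emission).
    """
    grid = grid or TimeGrid(horizon_years=100)
    if profile.duration > grid.horizon_years:
        raise ValueError("profile duration exceeds the grid horizon")
    removals = profile.annual_removals()
    n = grid.n_steps
    unit = model.rf_pulse("CO2", 1.0, grid).annual_values
    rf = np.zeros(n)
    per_year = int(round(1.0 / grid.step_years))
    for year, c_mass in enumerate(removals):
        if c_mass == 0.0:
            continue
        offset = year * per_year
        rf[offset:] -= c_mass * C_TO_CO2 * unit[: n - offset]
    series = ImpactSeries("RF", grid, rf, gas="CO2", mode="sequestration")
    if metric.upper() == "RF":
        return series
    return model.temperature_response(series)
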