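"""Bundled IPCC Tier-1 constants and synthetic inventory generation.

Two constant tables ship with the package as editable CSVs: enteric CH4
emission factors of cattle (kg/head/yr, Tier-1 style, native range 41-138
before display rounding to 40-160) and the inputs of the grassland
sequestration-potential calculation (reference SOC stocks for six climate
zones x three soil types, plus land-use/management/input stock-change
factors).  The potential is the stock difference between well-managed
grassland and poorly managed cropland (low input, full tillage) on the same
soil; across the bundled combinations it spans ~5 (tropical dry, sandy) to
~50 (cool temperate moist, high-activity clay) t C/ha.

The global livestock and soil databases the regional analysis would need are
access-restricted, so :func:`generate_inventories` builds a synthetic
emulation instead: an 11-region inventory whose global totals are pinned to
the published sector totals (110 Mt CH4/yr, 2.4 Mt N2O/yr, 78 Gt SOC in
managed grasslands) and whose regional structure follows a documented base
split (a populous South-Asia-like region with small grassland area, a
stock-rich East-Europe-like region with few ruminants, cattle dominating
CH4) jittered by a seeded Dirichlet draw.  It emulates structure; it does
not reproduce the restricted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .accounting import (
    EmissionInventory,
    GrasslandInventory,
    RUMINANT_SPECIES,
)
from .params import ConfigError, InputError

REGIONS = (
    "North America",
    "Latin America & Caribbean",
    "South Asia",
    "East & Southeast Asia",
    "West & Central Asia",
    "North Africa",
    "Sub-Saharan Africa",
    "West Europe",
    "East Europe",
    "South Europe",
    "Oceania",
)

CLIMATE_ZONES = (
    "cool_temperate_moist",
    "cool_temperate_dry",
    "warm_temperate_moist",
    "warm_temperate_dry",
    "tropical_moist",
    "tropical_dry",
)

SOIL_TYPES = ("high_activity_clay", "low_activity_clay", "sandy")

#: display range of enteric emission factors used for the density lattice
EF_DISPLAY_RANGE = (40.0, 160.0)
#: native Tier-1 range before rounding
EF_NATIVE_RANGE = (41.0, 138.0)


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("pulseflow.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_enteric_ef_table() -> pd.DataFrame:
    """Enteric CH4 emission factors per (region class, cattle class)."""
    return _read_bundled("enteric_ch4_ef.csv")


def enteric_ef(region_class: str, cattle_class: str) -> float:
    df = load_enteric_ef_table()
    hit = df[
        (df["region_class"] == region_class)
        & (df["cattle_class"] == cattle_class)
    ]
    if hit.empty:
        raise ConfigError(
            f"no enteric EF for ({region_class!r}, {cattle_class!r})"
        )
    return float(hit["ef_kg_head_yr"].iloc[0])


def load_reference_stocks() -> pd.DataFrame:
    """Reference SOC stocks (t C/ha, 0-30 cm) per climate zone and soil type."""
    return _read_bundled("soc_reference_stocks.csv")


def load_stock_change_factors() -> pd.DataFrame:
    """Land-use/management/input stock-change factor sets per climate zone."""
    return _read_bundled("stock_change_factors.csv")


def seq_potential(
    climate_zone: str,
    soil_type: str,
    soc_ref: float | None = None,
    factors: pd.DataFrame | None = None,
) -> float:
    """Maximum grassland sequestration potential, t C/ha.

    ``soc_ref x F_grassland - soc_ref x F_LU,crop x F_MG,full-till x
    F_I,low``: the stock difference between well-managed grassland and poorly
    managed cropland.  ``soc_ref`` defaults to the bundled reference stock
    for the combination.
    """
    if factors is None:
        factors = load_stock_change_factors()
    frow = factors[factors["climate_zone"] == climate_zone]
    if frow.empty:
        raise ConfigError(f"no stock-change factors for {climate_zone!r}")
    if soc_ref is None:
        stocks = load_reference_stocks()
        hit = stocks[
            (stocks["climate_zone"] == climate_zone)
            & (stocks["soil_type"] == soil_type)
        ]
        if hit.empty:
            raise ConfigError(
                f"no reference stock for ({climate_zone!r}, {soil_type!r})"
            )
        soc_ref = float(hit["soc_ref_t_ha"].iloc[0])
    f = frow.iloc[0]
    grass = f["f_lu_grassland"] * f["f_mg_grassland"] * f["f_i_grassland"]
    crop = f["f_lu_cropland"] * f["f_mg_cropland"] * f["f_i_cropland"]
    return float(soc_ref * (grass - crop))


def seq_potential_table() -> pd.DataFrame:
    """Potential for every bundled climate-zone x soil-type combination."""
    factors = load_stock_change_factors()
    stocks = load_reference_stocks()
    rows = [
        {
            "climate_zone": rec.climate_zone,
            "soil_type": rec.soil_type,
            "potential_t_ha": seq_potential(
                rec.climate_zone,
                rec.soil_type,
                soc_ref=rec.soc_ref_t_ha,
                factors=factors,
            ),
        }
        for rec in stocks.itertuples()
    ]
    return pd.DataFrame(rows)


def _default_species_shares() -> dict[str, float]:
    # cattle dominate ruminant CH4; buffalo/sheep/goat split the remainder
    return {"cattle": 0.75, "buffalo": 0.10, "sheep": 0.09, "goat": 0.06}


@dataclass(frozen=True)
class SyntheticInventoryConfig:
    """Controls for the synthetic GLEAM/GSOCseq-like inventory emulation.

    Totals default to the published global sector figures; ``concentration``
    scales the Dirichlet jitter around the base regional split (larger =
    tighter), ``soc_sigma`` the lognormal jitter on per-hectare stocks.  The
    same seed always yields an identical inventory.
    """

    n_regions: int = 11
    ch4_total_t: float = 110e6
    n2o_total_t: float = 2.4e6
    soc_total_t: float = 78e9
    species_shares: dict[str, float] = field(
        default_factory=_default_species_shares
    )
    concentration: float = 3000.0
    soc_sigma: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if not 1 <= self.n_regions <= len(REGIONS):
            raise InputError(f"n_regions must be within 1-{len(REGIONS)}")
        unknown = set(self.species_shares) - set(RUMINANT_SPECIES)
        if unknown:
            raise InputError(f"unknown species {sorted(unknown)}")
        if abs(sum(self.species_shares.values()) - 1.0) > 1e-9:
            raise InputError("species shares must sum to 1")
        if min(self.ch4_total_t, self.n2o_total_t, self.soc_total_t) < 0:
            raise InputError("totals must be >= 0")


def generate_inventories(
    config: SyntheticInventoryConfig | None = None,
) -> tuple[EmissionInventory, GrasslandInventory]:
    """Deterministically generate a synthetic emission + grassland inventory.

    Global sums match the configured totals exactly (regional values are
    rescaled after the jittered split).
    """
    cfg = config or SyntheticInventoryConfig()
    rng = np.random.default_rng(cfg.seed)
    base = _read_bundled("region_shares.csv").iloc[: cfg.n_regions]

    def split(shares: np.ndarray, total: float) -> np.ndarray:
        shares = shares / shares.sum()
        if cfg.concentration > 0:
            shares = rng.dirichlet(cfg.concentration * shares)
        out = shares * total
        return out * (total / out.sum()) if out.sum() > 0 else out

    ch4 = split(base["ch4_share"].to_numpy(float), cfg.ch4_total_t)
    n2o = split(base["n2o_share"].to_numpy(float), cfg.n2o_total_t)

    rows = []
    for i, region in enumerate(base["region"]):
        for gas, masses in (("CH4", ch4), ("N2O", n2o)):
            for species, share in sorted(cfg.species_shares.items()):
                rows.append(
                    {
                        "region": region,
                        "species": species,
                        "gas": gas,
                        "tonnes_per_year": masses[i] * share,
                    }
                )
    emissions = EmissionInventory.from_frame(pd.DataFrame(rows))

    area_ha = base["area_mha"].to_numpy(float) * 1e6
    soc = base["soc_t_ha"].to_numpy(float)
    if cfg.soc_sigma > 0:
        soc = soc * rng.lognormal(0.0, cfg.soc_sigma, size=len(soc))
    stock = (area_ha * soc).sum()
    if stock > 0:
        soc = soc * (cfg.soc_total_t / stock)
    grasslands = GrasslandInventory.from_frame(
        pd.DataFrame(
            {
                "region": base["region"],
                "area_ha": area_ha,
                "soc_t_per_ha": soc,
            }
        )
    )
    return emissions, grasslands
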