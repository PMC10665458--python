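"""Parameter handling for the linearized climate model.

The model is fully determined by an editable YAML file (see
``pulseflow/data/climate_params.yaml`` for the bundled AR6-consistent
defaults): per-gas radiative efficiencies and perturbation lifetimes, the
multi-exponential CO2 impulse response, the two-timescale temperature kernel,
and the discretization of the time grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

GASES = ("CO2", "CH4", "N2O")

MAX_HORIZON_YEARS = 1000


class ConfigError(ValueError):
    """Raised for an invalid or incomplete model configuration."""


class InputError(ValueError):
    """Raised for malformed user-supplied tables."""


@dataclass(frozen=True)
class TimeGrid:
    """Discrete annual (or finer) time grid.

    Grid points sit at ``t_k = k * step_years`` for ``k = 1..n``; with the
    default one-year step, point ``k`` is the end of year ``k`` ("year one"
    is ``t = 1``).  Horizons up to 1000 years are supported.
    """

    horizon_years: int
    step_years: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ConfigError("horizon_years must be >= 1")
        if self.horizon_years > MAX_HORIZON_YEARS:
            raise ConfigError(
                f"horizon_years must be <= {MAX_HORIZON_YEARS}"
            )
        if not self.step_years > 0:
            raise ConfigError("step_years must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_years / self.step_years))

    @property
    def times(self) -> np.ndarray:
        """Strictly increasing grid points, in years."""
        return self.step_years * np.arange(1, self.n_steps + 1)

    def index_of(self, year: float) -> int:
        """Index of grid point ``year``; raises if off-grid or beyond horizon."""
        if year > self.horizon_years + 1e-9:
            raise ValueError(
                f"year {year} exceeds grid horizon {self.horizon_years}"
            )
        k = int(round(year / self.step_years))
        if k < 1 or abs(k * self.step_years - year) > 1e-9:
            raise ValueError(f"year {year} is not on the grid")
        return k - 1


@dataclass(frozen=True)
class GasSpec:
    """Physical parameters of one well-mixed greenhouse gas.

    ``radiative_efficiency`` is the direct forcing per kg of atmospheric
    burden (W m-2 kg-1); ``indirect_multiplier`` folds in chemistry side
    effects (tropospheric ozone and stratospheric water vapour for CH4, the
    induced CH4-lifetime reduction for N2O).  ``carbon_cycle_feedback`` is the
    additional forcing per kelvin of induced warming (W m-2 K-1) representing
    temperature-driven CO2 outgassing; it is zero for CO2 itself, whose
    impulse response already embeds the feedback.
    """

    name: str
    molar_mass: float
    radiative_efficiency: float
    indirect_multiplier: float = 1.0
    perturbation_lifetime_years: float | None = None
    carbon_cycle_feedback: float = 0.0
    biogenic: bool = False

    def __post_init__(self) -> None:
        if self.radiative_efficiency <= 0:
            raise ConfigError(f"{self.name}: radiative_efficiency must be > 0")
        if self.indirect_multiplier <= 0:
            raise ConfigError(f"{self.name}: indirect_multiplier must be > 0")
        if (
            self.perturbation_lifetime_years is not None
            and self.perturbation_lifetime_years <= 0
        ):
            raise ConfigError(f"{self.name}: lifetime must be > 0")

    @property
    def effective_efficiency(self) -> float:
        """W m-2 kg-1 including indirect chemistry effects."""
        return self.radiative_efficiency * self.indirect_multiplier


@dataclass(frozen=True)
class CO2ResponseParams:
    """Multi-exponential CO2 impulse response (Joos-type fit).

    Fraction of a pulse remaining after t years:
    ``a0 + sum_i a_i exp(-t / tau_i)``; ``a0`` is the share that stays in the
    atmosphere practically indefinitely.
    """

    a0: float
    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.a0 > 0:
            raise ConfigError("co2_irf: a0 must be > 0")
        total = self.a0 + sum(a for a, _ in self.terms)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"co2_irf: coefficients sum to {total}, not 1")
        if any(tau <= 0 for _, tau in self.terms):
            raise ConfigError("co2_irf: all tau_i must be > 0")


@dataclass(frozen=True)
class ClimateResponseParams:
    """Temperature impulse-response kernel ``sum_j (c_j/d_j) exp(-t/d_j)``.

    At least two timescales (mixed layer + deep ocean) are required so that
    temperature lags forcing; ``sum c_j`` is the equilibrium warming per unit
    of sustained forcing, K (W m-2)-1.
    """

    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ConfigError(
                "temperature_response: need at least two timescales"
            )
        if any(c <= 0 or d <= 0 for c, d in self.terms):
            raise ConfigError("temperature_response: all c_j, d_j must be > 0")

    @property
    def equilibrium_response(self) -> float:
        """K per (W m-2) of sustained forcing."""
        return sum(c for c, _ in self.terms)


@dataclass(frozen=True)
class ClimateConfig:
    gases: dict[str, GasSpec]
    co2_irf: CO2ResponseParams
    temperature_response: ClimateResponseParams
    default_grid: TimeGrid = field(
        default_factory=lambda: TimeGrid(horizon_years=500)
    )
    source: str = "bundled"

    def gas(self, name: str) -> GasSpec:
        try:
            return self.gases[name]
        except KeyError:
            raise ConfigError(
                f"unknown gas {name!r}; configured: {sorted(self.gases)}"
            ) from None


def _gas_from_dict(name: str, d: dict) -> GasSpec:
    try:
        return GasSpec(
            name=name,
            molar_mass=float(d["molar_mass"]),
            radiative_efficiency=float(d["radiative_efficiency"]),
            indirect_multiplier=float(d.get("indirect_multiplier", 1.0)),
            perturbation_lifetime_years=(
                float(d["perturbation_lifetime_years"])
                if "perturbation_lifetime_years" in d
                else None
            ),
            carbon_cycle_feedback=float(d.get("carbon_cycle_feedback", 0.0)),
            biogenic=bool(d.get("biogenic", False)),
        )
    except KeyError as exc:
        raise ConfigError(f"gas {name!r}: missing key {exc}") from None


def config_from_dict(raw: dict, source: str = "dict") -> ClimateConfig:
    if "gases" not in raw or "co2_irf" not in raw:
        raise ConfigError("config must define 'gases' and 'co2_irf'")
    gases = {
        name: _gas_from_dict(name, spec) for name, spec in raw["gases"].items()
    }
    irf = CO2ResponseParams(
        a0=float(raw["co2_irf"]["a0"]),
        terms=tuple(
            (float(a), float(tau)) for a, tau in raw["co2_irf"]["terms"]
        ),
    )
    kernel = ClimateResponseParams(
        terms=tuple(
            (float(c), float(d))
            for c, d in raw["temperature_response"]["terms"]
        )
    )
    disc = raw.get("discretization", {})
    grid = TimeGrid(
        horizon_years=int(disc.get("horizon_years", 500)),
        step_years=float(disc.get("step_years", 1.0)),
    )
    return ClimateConfig(
        gases=gases,
        co2_irf=irf,
        temperature_response=kernel,
        default_grid=grid,
        source=source,
    )


def load_config(path: str | Path | None = None) -> ClimateConfig:
    """Load a model configuration; ``None`` loads the bundled defaults."""
    if path is None:
        text = (
            resources.files("pulseflow.data")
            .joinpath("climate_params.yaml")
            .read_text(encoding="utf-8")
        )
        source = "bundled:climate_params.yaml"
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {source}: {exc}") from None
    return config_from_dict(raw, source=source)


def config_hash(config: ClimateConfig) -> str:
    """Stable short hash of the parameter values, for output provenance."""
    canon = {
        "gases": {
            n: (
                g.molar_mass,
                g.radiative_efficiency,
                g.indirect_multiplier,
                g.perturbation_lifetime_years,
                g.carbon_cycle_feedback,
                g.biogenic,
            )
            for n, g in sorted(config.gases.items())
        },
        "co2_irf": (config.co2_irf.a0, config.co2_irf.terms),
        "kernel": config.temperature_response.terms,
    }
    digest = hashlib.sha256(repr(canon).encode()).hexdigest()
    return digest[:12]
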