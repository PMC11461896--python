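"""Gas transfer velocity estimation.

Two k600 models: a river model driven by the stream energy dissipation
rate (eD = g*S*v) and a lake model driven by wind speed at 10 m. Either
k600 is then corrected to the ambient-temperature CH4 transfer velocity
kx through Schmidt-number scaling, k600/kx = (600/Scx)^n with n = -1/2
for turbulent or wavy interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants
from .gas_physics import schmidt_number_ch4

__all__ = [
    "ChannelHydraulics",
    "GasTransferEstimate",
    "energy_dissipation",
    "k600_river",
    "k600_lake_wind",
    "schmidt_scale",
    "river_transfer",
    "lake_transfer",
]


@dataclass(frozen=True)
class ChannelHydraulics:
    """Slope, water velocity and gravitational acceleration of a reach."""

    slope: float = constants.DEFAULT_CHANNEL_SLOPE
    velocity_m_s: float = constants.DEFAULT_CHANNEL_VELOCITY_M_S
    gravity_m_s2: float = constants.DEFAULT_GRAVITY_M_S2

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("channel slope must be positive")
        if self.velocity_m_s <= 0:
            raise ValueError("water velocity must be positive")
        if not 9.7 <= self.gravity_m_s2 <= 9.9:
            raise ValueError("gravitational acceleration outside [9.7, 9.9]")


@dataclass(frozen=True)
class GasTransferEstimate:
    """k600 with its CH4 correction and the model that produced it."""

    k600_m_d: float
    kx_m_d: float
    schmidt_number: float
    exponent: float
    model: str  # "river_energy_dissipation" | "lake_wind"

    def __post_init__(self) -> None:
        if self.k600_m_d <= 0 or self.kx_m_d <= 0:
            raise ValueError("transfer velocities must be positive")
        if not -1.0 <= self.exponent <= -1.0 / 3.0:
            raise ValueError("Schmidt exponent outside [-1, -1/3]")


def energy_dissipation(h: ChannelHydraulics) -> float:
    """Stream energy dissipation rate eD = g*S*v, in W kg^-1."""
    return h.gravity_m_s2 * h.slope * h.velocity_m_s


def k600_river(ed_w_kg: float) -> float:
    """River k600 (m d^-1) from the energy dissipation rate.

    High-energy-dissipation relationship
    ln(k600) = 6.43 + 1.18 ln(eD); see
    :data:`glacialch4.constants.K600_RIVER_CITATION`.
    """
    if ed_w_kg <= 0:
        raise ValueError("energy dissipation must be positive")
    return math.exp(
        constants.K600_RIVER_INTERCEPT
        + constants.K600_RIVER_SLOPE * math.log(ed_w_kg)
    )


def k600_lake_wind(u10_m_s: float) -> float:
    """Lake k600 (m d^-1) from wind speed 10 m above the surface.

    Piecewise-linear in u10 with a break at 3.7 m s^-1 (coefficients and
    provenance in :data:`glacialch4.constants.K600_LAKE_CITATION`);
    anchored so that u10 = 3.7 m s^-1 gives 0.27 m d^-1. Nondecreasing
    in wind speed.
    """
    if u10_m_s < 0:
        raise ValueError("wind speed must be >= 0")
    if u10_m_s <= constants.K600_LAKE_BREAK_U10:
        return constants.K600_LAKE_LOW_SLOPE * u10_m_s
    return (
        constants.K600_LAKE_HIGH_SLOPE * u10_m_s
        + constants.K600_LAKE_HIGH_INTERCEPT
    )


def schmidt_scale(
    k600_m_d: float,
    schmidt_number: float,
    exponent: float = constants.DEFAULT_SCHMIDT_EXPONENT,
) -> float:
    """Convert k600 to kx for a gas with Schmidt number Scx.

    kx = k600 / (600/Scx)^n. The identity point is Scx = 600 (kx = k600
    for any n); for n = -1/2 a higher Schmidt number (colder water,
    slower-diffusing gas) gives a lower kx.
    """
    if k600_m_d <= 0:
        raise ValueError("k600 must be positive")
    if schmidt_number <= 0:
        raise ValueError("Schmidt number must be positive")
    if exponent >= 0:
        raise ValueError("Schmidt exponent must be negative")
    return k600_m_d / (600.0 / schmidt_number) ** exponent


def river_transfer(
    hydraulics: ChannelHydraulics | None = None,
    water_temp_c: float = constants.DEFAULT_WATER_TEMP_C,
    exponent: float = constants.DEFAULT_SCHMIDT_EXPONENT,
) -> GasTransferEstimate:
    """Full river chain: eD -> k600 -> CH4 kx at the water temperature."""
    hydraulics = hydraulics or ChannelHydraulics()
    k600 = k600_river(energy_dissipation(hydraulics))
    sc = schmidt_number_ch4(water_temp_c)
    return GasTransferEstimate(
        k600_m_d=k600,
        kx_m_d=schmidt_scale(k600, sc, exponent),
        schmidt_number=sc,
        exponent=exponent,
        model="river_energy_dissipation",
    )


def lake_transfer(
    u10_m_s: float = constants.DEFAULT_WIND_U10_M_S,
    water_temp_c: float = constants.DEFAULT_WATER_TEMP_C,
    exponent: float = constants.DEFAULT_SCHMIDT_EXPONENT,
) -> GasTransferEstimate:
    """Full lake chain: wind -> k600 -> CH4 kx at the water temperature."""
    k600 = k600_lake_wind(u10_m_s)
    sc = schmidt_number_ch4(water_temp_c)
    return GasTransferEstimate(
        k600_m_d=k600,
        kx_m_d=schmidt_scale(k600, sc, exponent),
        schmidt_number=sc,
        exponent=exponent,
        model="lake_wind",
    )
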