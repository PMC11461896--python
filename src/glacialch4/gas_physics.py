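"""Physical chemistry of dissolved methane.

Solubility (Henry coefficient from a Bunsen-coefficient fit), the
concentration of water in equilibrium with the atmosphere, Schmidt
numbers for air-water exchange scaling, and concentration unit
conversions. These primitives underpin the headspace inversion, the
diffusive flux calculation and the gas-transfer temperature correction.

The internal canonical concentration unit is umol L^-1 (uM); ug L^-1 and
mmol m^-3 are supported at the boundary. Note that uM and mmol m^-3 are
numerically identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants

__all__ = [
    "GasConditions",
    "ConcentrationValue",
    "ch4_solubility",
    "equilibrium_concentration",
    "schmidt_number_ch4",
    "convert_concentration",
]

#: Recognized concentration units and their factor relative to uM.
_UNIT_FACTORS = {
    "uM": 1.0,
    "umol/L": 1.0,
    "mmol/m3": 1.0,
    "ug/L": constants.CH4_MOLAR_MASS_G_PER_MOL,
}


def _canonical_unit(unit: str) -> str:
    if unit not in _UNIT_FACTORS:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(_UNIT_FACTORS)}"
        )
    return unit


@dataclass(frozen=True)
class GasConditions:
    """Ambient conditions of a water sample.

    Parameters
    ----------
    temperature_c
        Water temperature in degrees Celsius.
    pressure_atm
        Total barometric pressure in atmospheres.
    atm_ch4_ppb
        Dry-air CH4 mole fraction in parts per billion.
    """

    temperature_c: float
    pressure_atm: float = constants.DEFAULT_PRESSURE_ATM
    atm_ch4_ppb: float = constants.DEFAULT_ATM_CH4_PPB

    def __post_init__(self) -> None:
        if not -2.0 <= self.temperature_c <= 40.0:
            raise ValueError(
                f"water temperature {self.temperature_c} degC outside [-2, 40]"
            )
        if self.pressure_atm <= 0:
            raise ValueError("pressure must be positive")
        if self.atm_ch4_ppb < 0:
            raise ValueError("atmospheric CH4 mixing ratio must be >= 0")


@dataclass(frozen=True)
class ConcentrationValue:
    """A dissolved CH4 concentration with an explicit unit."""

    value: float
    unit: str = "uM"

    def __post_init__(self) -> None:
        _canonical_unit(self.unit)
        if self.value < 0:
            raise ValueError("concentration must be >= 0")

    def to(self, unit: str) -> "ConcentrationValue":
        return convert_concentration(self, unit)

    @property
    def um(self) -> float:
        """The value expressed in uM."""
        return self.value / _UNIT_FACTORS[self.unit]


def convert_concentration(c: ConcentrationValue, target_unit: str) -> ConcentrationValue:
    """Convert a concentration between uM, ug/L and mmol/m3.

    Conversion goes through the molar mass of CH4 (16.04 g mol^-1) and is
    an exact round trip: ``convert(convert(x, u), x.unit) == x``.
    """
    target_unit = _canonical_unit(target_unit)
    um = c.value / _UNIT_FACTORS[c.unit]
    return ConcentrationValue(um * _UNIT_FACTORS[target_unit], target_unit)


def ch4_solubility(conditions: GasConditions) -> float:
    """Henry-law solubility of CH4 in fresh water, in mol L^-1 atm^-1.

    Evaluates the Bunsen-coefficient fit referenced in
    :data:`glacialch4.constants.SOLUBILITY_CITATION` at salinity 0 and
    divides by the STP molar volume. The coefficient is strictly
    decreasing in temperature (warmer water holds less gas).

    Raises
    ------
    ValueError
        If the temperature is outside the fit range of the coefficient
        set (-2 to 30 degC).
    """
    lo, hi = constants.SOLUBILITY_TEMP_RANGE_C
    t = conditions.temperature_c
    if not lo <= t <= hi:
        raise ValueError(
            f"temperature {t} degC outside the solubility fit range "
            f"[{lo}, {hi}] degC"
        )
    t_k = t + 273.15
    ln_bunsen = (
        constants.SOLUBILITY_A1
        + constants.SOLUBILITY_A2 * (100.0 / t_k)
        + constants.SOLUBILITY_A3 * math.log(t_k / 100.0)
    )
    bunsen = math.exp(ln_bunsen)  # mL CH4 (STP) per mL water per atm
    return bunsen / constants.STP_MOLAR_VOLUME_L


def equilibrium_concentration(conditions: GasConditions) -> ConcentrationValue:
    """Dissolved CH4 concentration at equilibrium with the atmosphere (uM).

    Ceq = solubility(T) x partial pressure of CH4, where the partial
    pressure is the dry-air mixing ratio times total pressure. Linear in
    both the mixing ratio and the pressure.
    """
    partial_pressure_atm = conditions.atm_ch4_ppb * 1e-9 * conditions.pressure_atm
    mol_per_l = ch4_solubility(conditions) * partial_pressure_atm
    return ConcentrationValue(mol_per_l * 1e6, "uM")


def schmidt_number_ch4(temperature_c: float) -> float:
    """Schmidt number of CH4 in fresh water at a given temperature.

    Fourth-order polynomial in water temperature (degC); see
    :data:`glacialch4.constants.SCHMIDT_CITATION`. Positive and strictly
    decreasing over the fit range.
    """
    lo, hi = constants.SCHMIDT_TEMP_RANGE_C
    if not lo <= temperature_c <= hi:
        raise ValueError(
            f"temperature {temperature_c} degC outside the Schmidt polynomial "
            f"fit range [{lo}, {hi}] degC"
        )
    a0, a1, a2, a3, a4 = constants.SCHMIDT_COEFFS
    t = temperature_c
    return a0 + a1 * t + a2 * t**2 + a3 * t**3 + a4 * t**4
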