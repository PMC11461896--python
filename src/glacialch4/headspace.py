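"""Headspace-equilibration inversion.

Dissolved CH4 is measured by sealing a water sample in a vial, replacing
part of it with an inert helium headspace, letting gas partition between
the phases, and measuring the headspace mole fraction by GC. This module
recovers the original dissolved concentration by mass balance: the moles
found in the headspace (ideal gas) plus the moles still dissolved (Henry
partitioning at the equilibration temperature) are attributed to the
water volume that remained in the vial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import constants
from .gas_physics import ConcentrationValue, GasConditions, ch4_solubility

__all__ = [
    "HeadspaceVial",
    "dissolved_concentration",
    "equilibrate_headspace",
    "read_vial_table",
    "recover_table",
]

#: CSV columns expected by :func:`read_vial_table`.
VIAL_COLUMNS = [
    "site_id",
    "replicate",
    "water_volume_ml",
    "headspace_volume_ml",
    "equil_temp_c",
    "pressure_atm",
    "ch4_ppm",
]


@dataclass(frozen=True)
class HeadspaceVial:
    """One equilibrated sample vial.

    The nominal procedure: a 70 mL vial is over-filled with sample water,
    a 20 mL ultra-pure helium headspace is introduced (leaving 50 mL of
    water) and the phases equilibrate for 24 h before the headspace is
    subsampled for GC.
    """

    water_volume_ml: float = 50.0
    headspace_volume_ml: float = 20.0
    equil_temp_c: float = 20.0
    pressure_atm: float = constants.DEFAULT_PRESSURE_ATM
    ch4_ppm: float = 0.0
    nominal_vial_ml: float = 70.0

    def __post_init__(self) -> None:
        if self.water_volume_ml <= 0:
            raise ValueError("water volume must be positive")
        if self.headspace_volume_ml <= 0:
            raise ValueError("headspace volume must be positive")
        if abs(self.water_volume_ml + self.headspace_volume_ml - self.nominal_vial_ml) > 1.0:
            raise ValueError(
                "water + headspace volume differs from the nominal vial "
                f"volume {self.nominal_vial_ml} mL by more than 1 mL"
            )
        if self.ch4_ppm < 0:
            raise ValueError("headspace mole fraction must be >= 0")


def _partition_terms(vial: HeadspaceVial) -> tuple[float, float]:
    """Moles of CH4 per atm of CH4 partial pressure in each phase.

    Returns ``(gas_term, aq_term)`` where total moles
    ``= p_ch4 * (gas_term + aq_term)``.
    """
    conditions = GasConditions(
        temperature_c=vial.equil_temp_c,
        pressure_atm=vial.pressure_atm,
    )
    t_k = vial.equil_temp_c + 273.15
    gas_term = (vial.headspace_volume_ml / 1000.0) / (
        constants.R_L_ATM_PER_MOL_K * t_k
    )
    aq_term = ch4_solubility(conditions) * (vial.water_volume_ml / 1000.0)
    return gas_term, aq_term


def dissolved_concentration(vial: HeadspaceVial) -> ConcentrationValue:
    """Original dissolved CH4 concentration of the sampled water, in uM.

    The helium headspace is CH4-free before equilibration, so every mole
    now present — in the headspace (ideal gas at the equilibration T, P)
    or still dissolved (Henry's law at the same T) — came from the water.
    """
    p_ch4_atm = vial.ch4_ppm * 1e-6 * vial.pressure_atm
    gas_term, aq_term = _partition_terms(vial)
    n_total_mol = p_ch4_atm * (gas_term + aq_term)
    if n_total_mol < 0:
        raise ValueError("negative CH4 inventory; check inputs")
    umol = n_total_mol * 1e6
    return ConcentrationValue(umol / (vial.water_volume_ml / 1000.0), "uM")


def equilibrate_headspace(true_concentration_um: float, vial: HeadspaceVial) -> float:
    """Forward model: partition a known concentration, return GC ppm.

    The closed-form counterpart of :func:`dissolved_concentration`: given
    the true dissolved concentration of the water before the headspace
    was introduced, compute the CH4 mole fraction (ppm of total pressure)
    the GC would read after full equilibration. Inverting the result
    recovers the input exactly; the synthetic-data generator and the
    round-trip tests rely on this identity.
    """
    if true_concentration_um < 0:
        raise ValueError("concentration must be >= 0")
    n_total_mol = true_concentration_um * 1e-6 * (vial.water_volume_ml / 1000.0)
    gas_term, aq_term = _partition_terms(vial)
    p_ch4_atm = n_total_mol / (gas_term + aq_term)
    return p_ch4_atm / vial.pressure_atm * 1e6


def read_vial_table(path: str | Path) -> pd.DataFrame:
    """Read a per-vial measurement CSV (columns :data:`VIAL_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in VIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"vial table is missing columns: {missing}")
    return df


def recover_table(vials: pd.DataFrame) -> pd.DataFrame:
    """Apply the headspace inversion to every row of a vial table.

    Returns the input with appended columns ``ch4_um``, ``ch4_ug_l`` and
    provenance columns recording the equilibration temperature and the
    solubility coefficient set used.
    """
    out = vials.copy()
    ums = []
    for row in vials.itertuples(index=False):
        vial = HeadspaceVial(
            water_volume_ml=row.water_volume_ml,
            headspace_volume_ml=row.headspace_volume_ml,
            equil_temp_c=row.equil_temp_c,
            pressure_atm=row.pressure_atm,
            ch4_ppm=row.ch4_ppm,
            nominal_vial_ml=row.water_volume_ml + row.headspace_volume_ml,
        )
        ums.append(dissolved_concentration(vial).value)
    out["ch4_um"] = ums
    out["ch4_ug_l"] = out["ch4_um"] * constants.CH4_MOLAR_MASS_G_PER_MOL
    out["solubility_source"] = constants.SOLUBILITY_CITATION
    return out
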