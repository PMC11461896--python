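"""Net methane production/oxidation rates from sediment-water incubations.

A bottle assay pairs replicate initial-concentration vials with replicate
vials incubated in situ; the concentration difference over the incubation
period is the net balance of methanogenesis and methanotrophy. Rates are
signed: positive means net production, negative net oxidation. The same
rate is expressed per litre of incubation water, per square metre of
sediment surface, and per gram of sediment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants

__all__ = [
    "IncubationAssay",
    "NetRate",
    "net_volumetric_rate",
    "sediment_surface_area",
    "volumetric_to_areal",
    "volumetric_to_mass_specific",
    "net_rate",
    "read_assay_table",
    "rates_frame",
]

ASSAY_COLUMNS = [
    "site_id",
    "phase",
    "replicate",
    "ch4_um",
    "duration_h",
    "water_volume_ml",
    "sediment_volume_ml",
    "bulk_density_g_ml",
    "bottle_diameter_mm",
]

#: Volumetric rates whose magnitude falls below this are labelled balanced.
BALANCED_TOLERANCE_UM_PER_D = 1e-12


@dataclass(frozen=True)
class IncubationAssay:
    """One bottle incubation with replicate initial and final vials."""

    site_id: str
    initial_um: tuple[float, ...]
    final_um: tuple[float, ...]
    duration_h: float
    water_volume_l: float = 0.070
    sediment_volume_ml: float = 5.0
    bulk_density_g_ml: float = 0.96
    bottle_diameter_mm: float = 41.0

    def __post_init__(self) -> None:
        if not self.initial_um or not self.final_um:
            raise ValueError("replicate lists must be nonempty")
        if any(c < 0 for c in self.initial_um + self.final_um):
            raise ValueError("concentrations must be >= 0")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if not 0.1 < self.bulk_density_g_ml < 3.0:
            raise ValueError("bulk density outside plausible range (0.1, 3) g/mL")
        if self.water_volume_l <= 0 or self.sediment_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        if self.bottle_diameter_mm <= 0:
            raise ValueError("bottle diameter must be positive")


@dataclass(frozen=True)
class NetRate:
    """A net rate in all three reporting bases, with its direction.

    ``volumetric`` is umol CH4 L^-1 d^-1, ``areal`` umol m^-2 d^-1,
    ``mass_specific`` umol g^-1 d^-1; all signed with the same sign
    (positive = net production, negative = net oxidation).
    """

    site_id: str
    volumetric: float
    areal: float
    mass_specific: float
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        signs = {math.copysign(1, v) for v in
                 (self.volumetric, self.areal, self.mass_specific) if v != 0}
        if len(signs) > 1:
            raise ValueError("rate expressions disagree in sign")
        if abs(self.volumetric) <= BALANCED_TOLERANCE_UM_PER_D:
            d = "balanced"
        elif self.volumetric > 0:
            d = "net_production"
        else:
            d = "net_oxidation"
        object.__setattr__(self, "direction", d)


def net_volumetric_rate(assay: IncubationAssay) -> float:
    """Signed volumetric rate, umol L^-1 d^-1.

    (mean final - mean initial) / duration, normalised to per day.
    Negative values indicate net oxidation.
    """
    delta = float(np.mean(assay.final_um)) - float(np.mean(assay.initial_um))
    return delta / (assay.duration_h / 24.0)


def sediment_surface_area(bottle_inner_diameter_mm: float) -> float:
    """Circular sediment surface area of a bottle, in mm^2."""
    if bottle_inner_diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * (bottle_inner_diameter_mm / 2.0) ** 2


def volumetric_to_areal(
    rate_um_per_d: float, water_volume_l: float, sediment_area_m2: float
) -> float:
    """Re-express a volumetric rate per unit sediment surface area.

    umol L^-1 d^-1 x L of overlying water / m^2 of sediment
    -> umol m^-2 d^-1; the sign is preserved.
    """
    if water_volume_l <= 0:
        raise ValueError("water volume must be positive")
    if sediment_area_m2 <= 0:
        raise ValueError("sediment area must be positive")
    return rate_um_per_d * water_volume_l / sediment_area_m2


def volumetric_to_mass_specific(
    rate_um_per_d: float,
    water_volume_l: float,
    sediment_volume_ml: float,
    bulk_density_g_ml: float,
) -> float:
    """Re-express a volumetric rate per gram of sediment (umol g^-1 d^-1)."""
    if sediment_volume_ml <= 0 or bulk_density_g_ml <= 0:
        raise ValueError("sediment mass must be positive")
    if water_volume_l <= 0:
        raise ValueError("water volume must be positive")
    sediment_g = sediment_volume_ml * bulk_density_g_ml
    return rate_um_per_d * water_volume_l / sediment_g


def net_rate(assay: IncubationAssay) -> NetRate:
    """Full rate triple for one assay."""
    vol = net_volumetric_rate(assay)
    area_m2 = sediment_surface_area(assay.bottle_diameter_mm) * 1e-6
    return NetRate(
        site_id=assay.site_id,
        volumetric=vol,
        areal=volumetric_to_areal(vol, assay.water_volume_l, area_m2),
        mass_specific=volumetric_to_mass_specific(
            vol, assay.water_volume_l, assay.sediment_volume_ml,
            assay.bulk_density_g_ml,
        ),
    )


def read_assay_table(path: str | Path) -> list[IncubationAssay]:
    """Parse a long-format assay CSV into :class:`IncubationAssay` objects.

    One row per vial; ``phase`` is ``initial`` or ``final``; geometry
    columns must be constant within a site.
    """
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table is missing columns: {missing}")
    assays = []
    for site_id, grp in df.groupby("site_id", sort=False):
        phases = set(grp["phase"])
        if phases - {"initial", "final"}:
            raise ValueError(f"unknown phase labels for site {site_id}: {phases}")
        geometry = grp[
            ["duration_h", "water_volume_ml", "sediment_volume_ml",
             "bulk_density_g_ml", "bottle_diameter_mm"]
        ].drop_duplicates()
        if len(geometry) != 1:
            raise ValueError(f"inconsistent assay geometry within site {site_id}")
        geo = geometry.iloc[0]
        assays.append(
            IncubationAssay(
                site_id=str(site_id),
                initial_um=tuple(grp.loc[grp["phase"] == "initial", "ch4_um"]),
                final_um=tuple(grp.loc[grp["phase"] == "final", "ch4_um"]),
                duration_h=float(geo["duration_h"]),
                water_volume_l=float(geo["water_volume_ml"]) / 1000.0,
                sediment_volume_ml=float(geo["sediment_volume_ml"]),
                bulk_density_g_ml=float(geo["bulk_density_g_ml"]),
                bottle_diameter_mm=float(geo["bottle_diameter_mm"]),
            )
        )
    return assays


def rates_frame(assays: list[IncubationAssay]) -> pd.DataFrame:
    """Tabulate rate triples for a list of assays.

    Also carries the mass-equivalent of the volumetric rate in
    ug L^-1 d^-1 (x 16.04).
    """
    rows = []
    for assay in assays:
        r = net_rate(assay)
        rows.append(
            {
                "site_id": r.site_id,
                "volumetric_um_l_d": r.volumetric,
                "areal_umol_m2_d": r.areal,
                "mass_specific_umol_g_d": r.mass_specific,
                "volumetric_ug_l_d": r.volumetric * constants.CH4_MOLAR_MASS_G_PER_MOL,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
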