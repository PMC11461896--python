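"""Per-area glacier methane fluxes and global extrapolation.

Each source glacier contributes an annual CH4 flux (Mg yr^-1) and a
surface area (km^2); dividing gives a per-area flux that, multiplied by
the global glacier coverage, yields a rough global emission estimate in
Tg yr^-1. The arithmetic is deliberately simple — the point of the
exercise is the order-of-magnitude spread between source glaciers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import constants

__all__ = [
    "GlacierSource",
    "UpscaleResult",
    "per_area_flux",
    "global_upscale",
    "upscale",
    "upscale_table",
    "read_glacier_table",
    "REFERENCE_GLACIERS",
]

MG_PER_TG = 1e6


@dataclass(frozen=True)
class GlacierSource:
    """A glacier's annual CH4 flux (Mg yr^-1) and surface area (km^2)."""

    name: str
    annual_flux_mg_yr: float
    area_km2: float

    def __post_init__(self) -> None:
        if self.annual_flux_mg_yr < 0:
            raise ValueError("annual flux must be >= 0")
        if self.area_km2 <= 0:
            raise ValueError("area must be positive")


@dataclass(frozen=True)
class UpscaleResult:
    name: str
    per_area_flux_mg_km2_yr: float
    global_area_km2: float
    global_flux_tg_yr: float


#: The three published source glaciers used for the global extrapolation:
#: Leverett (Greenland Ice Sheet), the Svalbard archipelago glaciers
#: (proglacial groundwater springs), and Solheimajokull (Iceland).
REFERENCE_GLACIERS = (
    GlacierSource("Leverett", 6.3, 20.0),
    GlacierSource("Svalbard", 2310.0, 6268.0),
    GlacierSource("Solheimajokull", 2460.0, 9.0),
)


def per_area_flux(g: GlacierSource) -> float:
    """Annual flux per unit glacier area, Mg km^-2 yr^-1."""
    return g.annual_flux_mg_yr / g.area_km2


def global_upscale(
    per_area_mg_km2_yr: float,
    global_area_km2: float = constants.DEFAULT_GLOBAL_GLACIER_AREA_KM2,
) -> float:
    """Extrapolate a per-area flux to global glacier coverage, in Tg yr^-1."""
    if per_area_mg_km2_yr <= 0 or global_area_km2 <= 0:
        raise ValueError("per-area flux and global area must be positive")
    return per_area_mg_km2_yr * global_area_km2 / MG_PER_TG


def upscale(
    g: GlacierSource,
    global_area_km2: float = constants.DEFAULT_GLOBAL_GLACIER_AREA_KM2,
) -> UpscaleResult:
    pa = per_area_flux(g)
    return UpscaleResult(
        name=g.name,
        per_area_flux_mg_km2_yr=pa,
        global_area_km2=global_area_km2,
        global_flux_tg_yr=global_upscale(pa, global_area_km2),
    )


def upscale_table(
    sources: tuple[GlacierSource, ...] = REFERENCE_GLACIERS,
    global_area_km2: float = constants.DEFAULT_GLOBAL_GLACIER_AREA_KM2,
) -> pd.DataFrame:
    rows = []
    for g in sources:
        r = upscale(g, global_area_km2)
        rows.append(
            {
                "name": r.name,
                "annual_flux_mg_yr": g.annual_flux_mg_yr,
                "area_km2": g.area_km2,
                "per_area_flux_mg_km2_yr": r.per_area_flux_mg_km2_yr,
                "global_flux_tg_yr": r.global_flux_tg_yr,
            }
        )
    return pd.DataFrame(rows)


def read_glacier_table(path: str | Path) -> tuple[GlacierSource, ...]:
    """Read a glacier source CSV: name, annual_flux_mg_yr, area_km2."""
    df = pd.read_csv(path)
    required = {"name", "annual_flux_mg_yr", "area_km2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"glacier table is missing columns: {sorted(missing)}")
    return tuple(
        GlacierSource(str(r.name), float(r.annual_flux_mg_yr), float(r.area_km2))
        for r in df.itertuples(index=False)
    )
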