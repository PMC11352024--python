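"""Allometric scaling and crossvein mass estimates.

The Hawaiian fly's wing is compared with the common fruit fly's through a
linear scale factor ``k = sqrt(area ratio)``; isometry then scales masses
and volumetric flow rates as ``k³``.  The extra crossvein's mass is the sum
of the hemolymph filling its lumen and the cuticle wall occupying the
annulus between inner and outer diameters — the price paid, in wing mass,
for its pressure-loss-reducing topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import InvalidGeometryError

__all__ = [
    "AllometryParams",
    "scaling_factor",
    "isometric_wing_mass",
    "crossvein_mass",
    "mass_increase_percent",
    "reference_flow_rate",
    "mass_report",
]

KG_TO_UG = 1e9


@dataclass(frozen=True)
class AllometryParams:
    """Printed constants of the scaling comparison.

    ``k`` defaults to full precision (sqrt of the area ratio, ≈2.88); pass
    ``k=2.9`` to use the rounded printed value instead — both conventions
    are exposed because downstream rounded results differ slightly.
    """

    area_ratio: float = 8.3
    reference_wing_mass_ug: float = 2.7
    hemolymph_density: float = 1.02e3  # kg/m³
    cuticle_density: float = 1150.0  # kg/m³
    k: float | None = None

    @property
    def scale(self) -> float:
        return self.k if self.k is not None else scaling_factor(self.area_ratio)


def scaling_factor(area_ratio: float) -> float:
    """Linear scale factor k from a wing-area ratio (k² = area ratio)."""
    if area_ratio <= 0:
        raise ValueError("area ratio must be positive")
    return math.sqrt(area_ratio)


def isometric_wing_mass(reference_mass_ug: float, k: float) -> float:
    """Isometric mass prediction: masses scale as the cube of length."""
    if reference_mass_ug <= 0 or k <= 0:
        raise ValueError("mass and scale factor must be positive")
    return reference_mass_ug * k**3


def reference_flow_rate(inflow: float, k: float) -> float:
    """Back out the small-fly flow rate implied by a k³-scaled inflow."""
    return inflow / k**3


def crossvein_mass(
    length_m: float,
    inner_diameter_m: float,
    outer_diameter_m: float,
    hemolymph_density: float = 1.02e3,
    cuticle_density: float = 1150.0,
) -> tuple[float, float]:
    """(lumen hemolymph mass, cuticle wall mass) of a vein, in µg.

    Lumen mass is the inner cylinder volume times the hemolymph density;
    wall mass is the annular volume times the cuticle density.
    """
    if inner_diameter_m <= 0 or outer_diameter_m < inner_diameter_m:
        raise InvalidGeometryError("need outer diameter >= inner diameter > 0")
    if length_m < 0:
        raise InvalidGeometryError("length must be non-negative")
    area_in = math.pi / 4.0 * inner_diameter_m**2
    area_wall = math.pi / 4.0 * (outer_diameter_m**2 - inner_diameter_m**2)
    lumen = area_in * length_m * hemolymph_density * KG_TO_UG
    wall = area_wall * length_m * cuticle_density * KG_TO_UG
    return lumen, wall


def mass_increase_percent(ecv_total_mass_ug: float, wing_mass_ug: float) -> float:
    """Crossvein mass as a percentage of the whole wing mass."""
    if wing_mass_ug <= 0:
        raise ValueError("wing mass must be positive")
    return 100.0 * ecv_total_mass_ug / wing_mass_ug


def mass_report(table: pd.DataFrame, params: AllometryParams | None = None) -> dict:
    """Flat key-value report of the scaling and ECV-mass estimates."""
    params = params or AllometryParams()
    row = table.set_index("vein_id").loc["ECV"]
    lumen, wall = crossvein_mass(
        length_m=row["length_mm"] * 1e-3,
        inner_diameter_m=row["inner_diameter_mm"] * 1e-3,
        outer_diameter_m=row["outer_diameter_mm"] * 1e-3,
        hemolymph_density=params.hemolymph_density,
        cuticle_density=params.cuticle_density,
    )
    k = params.scale
    wing = isometric_wing_mass(params.reference_wing_mass_ug, k)
    return {
        "k": k,
        "wing_mass_ug": wing,
        "ecv_lumen_mass_ug": lumen,
        "ecv_wall_mass_ug": wall,
        "ecv_total_mass_ug": lumen + wall,
        "mass_increase_percent": mass_increase_percent(lumen + wall, wing),
    }
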