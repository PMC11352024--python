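"""Parametric repositioning of the extra crossvein on the real wing.

The ECV's anterior end (node A) divides the fourth connecting vein and its
posterior end (node P) divides the fifth; shifting those connections changes
the split-segment lengths and the ECV's own length while every diameter
stays fixed.  Positions are expressed as base-side length fractions
``a = l_C4B/l_C4`` and ``p = l_C5B/l_C5``.  The PCV's anterior junction sits
at a fixed fraction ``x_pcv`` of the fifth connecting vein; whenever
``p ≠ x_pcv`` a transfer segment of length ``l_P = |p − x_pcv|·l_C5`` must
carry the bypassing hemolymph between the two crossveins, adding loss.

The published planar coordinates of the simplified wing geometry are not
available, so the default geometry here places the two connecting veins as
parallel straight segments aligned at their base-side endpoints, with the
rail separation calibrated so the ECV length at the measured position
(a = 0.486, p = 0.506) equals its measured 0.62 mm.  Every printed
constraint is preserved; absolute surface values away from the measured
position carry geometry-model uncertainty, the minimum's location does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HydraulicNetwork,
    SingularNetworkError,
    VeinSegment,
    poiseuille_resistance,
    solve_nodal,
)
from .sweep import SweepSurface

__all__ = [
    "ACTUAL_A",
    "ACTUAL_P",
    "RepositionGeometry",
    "RepositionState",
    "reposition_network",
    "sweep_positions",
    "normalized_loss_at",
]

#: measured connection fractions of the ECV on the real wing
ACTUAL_A = 0.486
ACTUAL_P = 0.506

_MOVABLE = ("V_C_4_E", "V_C_4_B", "V_C_5_E", "V_C_5_B", "ECV", "PCV")


@dataclass(frozen=True)
class RepositionGeometry:
    """Planar layout of the veins surrounding the ECV (mm units).

    The fourth and fifth connecting veins are modeled as parallel straight
    segments of lengths ``l_c4`` and ``l_c5``, their base-side endpoints
    aligned, separated by ``separation`` across the rails.  ``x_pcv`` is
    the fixed PCV junction fraction along the fifth connecting vein.
    """

    l_c4: float
    l_c5: float
    separation: float
    x_pcv: float = ACTUAL_P

    def __post_init__(self) -> None:
        if min(self.l_c4, self.l_c5, self.separation) <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.x_pcv < 1:
            raise ValueError("x_pcv must lie in (0, 1)")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        a_actual: float = ACTUAL_A,
        p_actual: float = ACTUAL_P,
        x_pcv: float = ACTUAL_P,
    ) -> "RepositionGeometry":
        """Calibrate the default geometry from a measured vein table.

        Full connecting-vein lengths are the sums of their measured split
        segments; the rail separation is chosen so the straight-line ECV
        length at the measured position equals the measured ECV length.
        """
        lengths = dict(zip(table["vein_id"], table["length_mm"]))
        l_c4 = lengths["V_C_4_E"] + lengths["V_C_4_B"]
        l_c5 = lengths["V_C_5_E"] + lengths["V_C_5_B"]
        l_ecv = lengths["ECV"]
        axial = a_actual * l_c4 - p_actual * l_c5
        if abs(axial) >= l_ecv:
            raise ValueError("measured ECV shorter than the axial offset it must span")
        separation = math.sqrt(l_ecv**2 - axial**2)
        return cls(l_c4=l_c4, l_c5=l_c5, separation=separation, x_pcv=x_pcv)

    def ecv_length(self, a: float, p: float) -> float:
        """Straight-line A-P distance (mm) at connection fractions (a, p)."""
        return math.hypot(self.separation, a * self.l_c4 - p * self.l_c5)


@dataclass(frozen=True)
class RepositionState:
    """Derived segment lengths (mm) for one (a, p) connection placement."""

    geometry: RepositionGeometry
    a: float
    p: float

    def __post_init__(self) -> None:
        if not (0 < self.a < 1 and 0 < self.p < 1):
            raise ValueError("connection fractions must lie in (0, 1)")

    @property
    def l_c4b(self) -> float:
        return self.a * self.geometry.l_c4

    @property
    def l_c4e(self) -> float:
        return (1.0 - self.a) * self.geometry.l_c4

    @property
    def l_transfer(self) -> float:
        """Length l_P of the segment carrying flow between ECV and PCV."""
        return abs(self.p - self.geometry.x_pcv) * self.geometry.l_c5

    @property
    def l_anterior_shift(self) -> float:
        """Displacement l_A of node A from its measured position."""
        return abs(self.a - ACTUAL_A) * self.geometry.l_c4

    @property
    def ecv_length(self) -> float:
        return self.geometry.ecv_length(self.a, self.p)

    def c5_segments(self) -> list[tuple[str, float]]:
        """Fifth-connecting-vein pieces from base end to edge end.

        Three pieces when the posterior connection P and the PCV junction
        differ, two when they coincide; lengths always sum to l_c5.
        """
        lo = min(self.p, self.geometry.x_pcv)
        hi = max(self.p, self.geometry.x_pcv)
        segs = [("V_C_5_B", lo * self.geometry.l_c5)]
        if hi > lo:
            segs.append(("V_C_5_T", (hi - lo) * self.geometry.l_c5))
        segs.append(("V_C_5_E", (1.0 - hi) * self.geometry.l_c5))
        return segs


def reposition_network(
    base: HydraulicNetwork,
    geom: RepositionGeometry,
    a: float,
    p: float,
    fixed_ecv_length_mm: float | None = None,
) -> HydraulicNetwork:
    """Rebuild the wing network with the ECV connected at fractions (a, p).

    The movable channels (both fourth-connecting segments, the fifth
    connecting vein pieces, the ECV and the PCV attachment) are replaced;
    every other vein keeps its measured geometry.  Each sub-segment keeps
    the diameter of the side of the parent vein it lies on, and all
    resistances are recomputed from Poiseuille's law.  ``fixed_ecv_length_mm``
    freezes the ECV length regardless of position (used to isolate the
    transfer-length effect).
    """
    state = RepositionState(geometry=geom, a=a, p=p)
    by_id = base.channel_map
    for cid in _MOVABLE:
        if cid not in by_id:
            raise KeyError(f"base network lacks channel {cid!r}")
    mu = _infer_viscosity(by_id["ECV"])

    def seg(cid, na, nb, length_mm, diameter_m):
        return VeinSegment.from_geometry(
            id=cid, node_a=na, node_b=nb,
            length=length_mm * 1e-3, inner_diameter=diameter_m, viscosity=mu,
        )

    d = {cid: by_id[cid].inner_diameter for cid in _MOVABLE}
    channels = [c for c in base.channels if c.id not in _MOVABLE]
    channels.append(seg("V_C_4_E", "E4", "A", state.l_c4e, d["V_C_4_E"]))
    channels.append(seg("V_C_4_B", "A", "B4", state.l_c4b, d["V_C_4_B"]))

    # fifth connecting vein pieces, base end (B5) upward to edge end (E5);
    # the transfer piece inherits the diameter of the side it lies on
    coincide = state.l_transfer == 0.0
    node_lo = "X" if coincide else ("P" if p < geom.x_pcv else "J")
    node_hi = "X" if coincide else ("J" if p < geom.x_pcv else "P")
    segs = state.c5_segments()
    channels.append(seg("V_C_5_B", "B5", node_lo, segs[0][1], d["V_C_5_B"]))
    if not coincide:
        d_transfer = d["V_C_5_B"] if p < geom.x_pcv else d["V_C_5_E"]
        channels.append(seg("V_C_5_T", node_lo, node_hi, segs[1][1], d_transfer))
    channels.append(seg("V_C_5_E", node_hi, "E5", segs[-1][1], d["V_C_5_E"]))

    ecv_len = fixed_ecv_length_mm if fixed_ecv_length_mm is not None else state.ecv_length
    node_p = "X" if coincide else "P"
    node_j = "X" if coincide else "J"
    channels.append(seg("ECV", "A", node_p, ecv_len, d["ECV"]))
    pcv = by_id["PCV"]
    channels.append(
        seg("PCV", node_j, pcv.node_b, pcv.length * 1e3, pcv.inner_diameter)
    )
    return HydraulicNetwork(
        channels=tuple(channels), inlet=base.inlet, outlet=base.outlet,
        inflow=base.inflow,
    )


def _infer_viscosity(segment: VeinSegment) -> float:
    """Back out μ from a geometry-derived segment (r = 128 μ l / π d⁴)."""
    if not segment.length or not segment.inner_diameter:
        raise ValueError("base network channels must carry geometry metadata")
    return segment.resistance * math.pi * segment.inner_diameter**4 / (
        128.0 * segment.length
    )


def normalized_loss_at(
    base: HydraulicNetwork, geom: RepositionGeometry, a: float, p: float
) -> float:
    """Δp_total at one (a, p), normalized by the ECV-absent loss."""
    baseline = solve_nodal(base.without_channel("ECV")).total_loss
    return solve_nodal(reposition_network(base, geom, a, p)).total_loss / baseline


def sweep_positions(
    base: HydraulicNetwork,
    geom: RepositionGeometry,
    a_grid,
    p_grid,
) -> SweepSurface:
    """Map normalized total loss over a grid of ECV connection positions.

    Normalization uses the ECV-ablated loss of the *base* network.  Cells
    whose repositioned network cannot be solved are reported NaN rather
    than aborting the sweep.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    baseline = solve_nodal(base.without_channel("ECV")).total_loss
    values = np.full((len(a_grid), len(p_grid)), np.nan)
    for i, a in enumerate(a_grid):
        for j, p in enumerate(p_grid):
            try:
                net = reposition_network(base, geom, float(a), float(p))
                values[i, j] = solve_nodal(net).total_loss / baseline
            except SingularNetworkError:
                continue
    return SweepSurface(
        a_values=a_grid, p_values=p_grid, values=values, baseline_loss=baseline
    )
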