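"""Idealized microchannel circuits imitating the crossvein topology.

A four-section ladder (sections 4–7 of the wing network) built from
microchannels: rails of four full channels each (edge side E4..E7, base side
B4..B7), rungs 4–6 as half-channel pairs meeting at midpoint nodes, the PCV
resistor across rungs 5 and 6, and the ECV resistor across rungs 4 and 5.
All channels are 2 mm long except the connecting halves (1 mm); the diameter
is uniformly 10 µm.  ``R`` denotes the resistance of the initial 2 mm ECV
channel; with these dimensions every full channel is R and every connecting
half 0.5R.

Three resistance-distribution variants probe what shapes the position-sweep
surface:

``uniform``
    all channels as above — symmetric distribution;
``asymmetric``
    fifth base channel set to 0.2R and sixth edge channel to 200R, mirroring
    the extreme resistances of the real wing's fourth-to-seventh sections;
``asymmetric_highC``
    additionally the fourth/fifth connecting halves set to 10R at the
    initial ECV position (the real connecting veins are an order of
    magnitude more resistive than the ECV).

During position sweeps the connecting-resistor and ECV resistances scale
with their lengths at fixed diameter; rungs are modeled as parallel and
aligned, 2 mm apart, so the initial (midpoint-to-midpoint) ECV length is
2 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    HEMOLYMPH,
    Q_IN_DEFAULT,
    HydraulicNetwork,
    SingularNetworkError,
    VeinSegment,
    poiseuille_resistance,
    solve_nodal,
)
from .sweep import SweepSurface

__all__ = [
    "IdealizedSpec",
    "build_idealized",
    "sweep_idealized",
    "valley_steepness",
    "VARIANTS",
]

VARIANTS = ("uniform", "asymmetric", "asymmetric_highC")


@dataclass(frozen=True)
class IdealizedSpec:
    """Construction parameters of the idealized circuit.

    Lengths in mm, diameter in m.  ``v_pcv`` is the fixed PCV junction
    fraction along rung 5 (its midpoint).  Variant resistance overrides are
    applied as resistance values directly; what matters hydraulically is
    the resistance, however it was realized.
    """

    variant: str = "uniform"
    channel_length_mm: float = 2.0
    half_length_mm: float = 1.0
    diameter_m: float = 10e-6
    rung_spacing_mm: float = 2.0
    v_pcv: float = 0.5
    b5_multiplier: float = 0.2
    e6_multiplier: float = 200.0
    connecting_multiplier: float = 10.0
    viscosity: float = HEMOLYMPH.viscosity

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def R(self) -> float:
        """Reference resistance: the initial 2 mm, 10 µm ECV channel."""
        return poiseuille_resistance(
            self.channel_length_mm * 1e-3, self.diameter_m, self.viscosity
        )

    @property
    def connecting_unit(self) -> float:
        """Resistance per mm of connecting resistor (rungs 4 and 5)."""
        base = 0.5 * self.R / self.half_length_mm
        if self.variant == "asymmetric_highC":
            return base * 2.0 * self.connecting_multiplier  # 10R per initial half
        return base

    def rail_resistances(self) -> tuple[dict[str, float], dict[str, float]]:
        rE = {f"E{i}": self.R for i in range(4, 8)}
        rB = {f"B{i}": self.R for i in range(4, 8)}
        if self.variant in ("asymmetric", "asymmetric_highC"):
            rB["B5"] = self.b5_multiplier * self.R
            rE["E6"] = self.e6_multiplier * self.R
        return rE, rB

    def ecv_resistance(self, length_mm: float) -> float:
        """ECV resistance scales with its length at fixed diameter."""
        return self.R * length_mm / self.channel_length_mm

    def ecv_length(self, u: float, v: float) -> float:
        """Straight-line connection length (mm) between fractions u and v."""
        du = (u - v) * self.channel_length_mm
        return math.hypot(self.rung_spacing_mm, du)


def build_idealized(
    spec: IdealizedSpec,
    u: float = 0.5,
    v: float = 0.5,
    with_ecv: bool = True,
    inflow: float = Q_IN_DEFAULT,
) -> HydraulicNetwork:
    """Assemble the circuit with the ECV connected at fractions (u, v).

    ``u`` positions the inlet-side connection along rung 4 and ``v`` the
    outlet-side one along rung 5, both measured from the base rail; the
    initial position is (0.5, 0.5), the rung midpoints.  Rung 6 always
    splits at its midpoint.  Fractions must lie in (0, 1).
    """
    if not (0 < u < 1 and 0 < v < 1):
        raise ValueError("connection fractions must lie in (0, 1)")
    rE, rB = spec.rail_resistances()
    cunit = spec.connecting_unit
    rung_len = spec.channel_length_mm

    def res(cid, na, nb, r):
        return VeinSegment(id=cid, node_a=na, node_b=nb, resistance=r)

    channels = [
        res("E4", "IN", "e1", rE["E4"]), res("E5", "e1", "e2", rE["E5"]),
        res("E6", "e2", "e3", rE["E6"]), res("E7", "e3", "OUT", rE["E7"]),
        res("B4", "IN", "b1", rB["B4"]), res("B5", "b1", "b2", rB["B5"]),
        res("B6", "b2", "b3", rB["B6"]), res("B7", "b3", "OUT", rB["B7"]),
        res("C6E", "e3", "Y", 0.5 * spec.R), res("C6B", "Y", "b3", 0.5 * spec.R),
        res("C4E", "e1", "A", cunit * (1.0 - u) * rung_len),
        res("C4B", "A", "b1", cunit * u * rung_len),
    ]
    coincide = v == spec.v_pcv
    node_lo = "X" if coincide else ("P" if v < spec.v_pcv else "J")
    node_hi = "X" if coincide else ("J" if v < spec.v_pcv else "P")
    lo, hi = min(v, spec.v_pcv), max(v, spec.v_pcv)
    channels.append(res("C5B", "b2", node_lo, cunit * lo * rung_len))
    if not coincide:
        channels.append(res("C5T", node_lo, node_hi, cunit * (hi - lo) * rung_len))
    channels.append(res("C5E", node_hi, "e2", cunit * (1.0 - hi) * rung_len))
    channels.append(res("PCV", "X" if coincide else "J", "Y", spec.R))
    if with_ecv:
        channels.append(
            res("ECV", "A", "X" if coincide else "P",
                spec.ecv_resistance(spec.ecv_length(u, v)))
        )
    return HydraulicNetwork(
        channels=tuple(channels), inlet="IN", outlet="OUT", inflow=inflow
    )


def sweep_idealized(
    spec: IdealizedSpec,
    u_grid,
    v_grid,
    inflow: float = Q_IN_DEFAULT,
) -> SweepSurface:
    """Normalized total loss over ECV connection positions (u, v).

    Normalization is by the loss of the same variant with the ECV resistor
    absent.  Unsolvable cells are NaN.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    baseline = solve_nodal(
        build_idealized(spec, with_ecv=False, inflow=inflow)
    ).total_loss
    values = np.full((len(u_grid), len(v_grid)), np.nan)
    for i, u in enumerate(u_grid):
        for j, v in enumerate(v_grid):
            try:
                net = build_idealized(spec, float(u), float(v), inflow=inflow)
                values[i, j] = solve_nodal(net).total_loss / baseline
            except SingularNetworkError:
                continue
    return SweepSurface(
        a_values=u_grid, p_values=v_grid, values=values, baseline_loss=baseline
    )


def valley_steepness(surface: SweepSurface, line: float = 0.5) -> float:
    """Mean gradient discontinuity of the surface across the PCV line.

    A valley along ``v = line`` manifests as a kink: the one-sided slopes
    away from the line do not cancel.  For each u the jump is estimated
    from the three grid columns nearest the line,
    ``(S(u, v+h) + S(u, v−h) − 2 S(u, v)) / h``, and averaged over u.  The
    kink is the signature of the transfer-segment mechanism (extra loss
    proportional to the ECV-to-PCV pathway length switching on as the
    outlet-side connection leaves the junction), so steeper valleys mean a
    larger loss penalty for breaking crossvein contiguity.
    """
    j = int(np.argmin(np.abs(surface.p_values - line)))
    if j == 0 or j == len(surface.p_values) - 1:
        raise ValueError("valley line must be interior to the v grid")
    h = 0.5 * (surface.p_values[j + 1] - surface.p_values[j - 1])
    kink = (
        surface.values[:, j + 1] + surface.values[:, j - 1] - 2.0 * surface.values[:, j]
    ) / h
    return float(np.nanmean(kink))
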