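"""Synthetic vein networks and closed-form fixture circuits.

The analysis stages only assume ladder-with-shared-terminals topology and
positive Poiseuille resistances, so they can be exercised end to end on
generated data: random ladders with log-normal lengths and diameters (the
defaults bracket the measured wing's ranges, lengths 0.16–5.0 mm and inner
diameters 2.9–32 µm), optional crossvein insertions between rung midpoints,
and a library of tiny circuits whose flows are known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import HydraulicNetwork, VeinSegment, Q_IN_DEFAULT
from .idealized import IdealizedSpec, build_idealized

__all__ = [
    "CrossveinInsertion",
    "LadderSpec",
    "random_ladder",
    "FixtureCircuit",
    "fixture_circuits",
]


@dataclass(frozen=True)
class CrossveinInsertion:
    """Insert a crossvein between two rungs, splitting each at a fraction."""

    rung_a: int
    rung_b: int
    frac_a: float = 0.5
    frac_b: float = 0.5

    def __post_init__(self) -> None:
        if self.rung_a == self.rung_b:
            raise ValueError("crossvein must join two distinct rungs")
        if not (0 < self.frac_a < 1 and 0 < self.frac_b < 1):
            raise ValueError("connection fractions must lie in (0, 1)")


@dataclass(frozen=True)
class LadderSpec:
    """Sampling recipe for a random ladder network.

    Lengths are log-normal in mm (location/scale on the log scale), inner
    diameters log-normal in µm; outer diameters follow the 20 % lumen rule
    in reverse.  The seed fully determines the output.
    """

    n_rungs: int = 5
    seed: int = 0
    length_log_mm: float = 0.0  # median 1.0 mm
    length_sigma: float = 0.8
    diameter_log_um: float = np.log(8.0)  # median 8 µm
    diameter_sigma: float = 0.5
    crossveins: tuple[CrossveinInsertion, ...] = ()

    def __post_init__(self) -> None:
        if self.n_rungs < 1:
            raise ValueError("need at least one rung")
        if self.length_sigma <= 0 or self.diameter_sigma <= 0:
            raise ValueError("distribution scales must be positive")
        for cv in self.crossveins:
            for r in (cv.rung_a, cv.rung_b):
                if not 1 <= r <= self.n_rungs:
                    raise ValueError(f"crossvein rung {r} outside 1..{self.n_rungs}")


def random_ladder(spec: LadderSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample one ladder as (vein table, topology) frames.

    A ladder of n rungs has 2(n+1) rail channels (edge and base series
    sharing the IN and OUT terminals) plus n rungs, plus one channel per
    inserted crossvein.  Rungs crossed by an insertion are emitted as two
    half-segments around the junction node.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rungs

    def sample_len() -> float:
        return float(rng.lognormal(spec.length_log_mm, spec.length_sigma))

    def sample_diam_mm() -> float:
        return float(rng.lognormal(spec.diameter_log_um, spec.diameter_sigma)) * 1e-3

    rows: list[dict] = []
    topo: list[dict] = []

    def add(vid: str, na: str, nb: str, length: float, diam: float) -> None:
        rows.append(
            {
                "vein_id": vid,
                "length_mm": length,
                "outer_diameter_mm": diam / 0.2,
                "inner_diameter_mm": diam,
            }
        )
        topo.append({"channel_id": vid, "node_a": na, "node_b": nb})

    enodes = ["IN"] + [f"E{i}" for i in range(1, n + 1)] + ["OUT"]
    bnodes = ["IN"] + [f"B{i}" for i in range(1, n + 1)] + ["OUT"]
    for i in range(n + 1):
        add(f"V_E_{i + 1}", enodes[i], enodes[i + 1], sample_len(), sample_diam_mm())
    for i in range(n + 1):
        add(f"V_B_{i + 1}", bnodes[i], bnodes[i + 1], sample_len(), sample_diam_mm())

    split = {}
    for cv in spec.crossveins:
        split.setdefault(cv.rung_a, cv.frac_a)
        split.setdefault(cv.rung_b, cv.frac_b)
    for i in range(1, n + 1):
        length, diam = sample_len(), sample_diam_mm()
        if i in split:
            f = split[i]
            add(f"V_C_{i}_E", f"E{i}", f"K{i}", (1.0 - f) * length, diam)
            add(f"V_C_{i}_B", f"K{i}", f"B{i}", f * length, diam)
        else:
            add(f"V_C_{i}", f"E{i}", f"B{i}", length, diam)
    for cv in spec.crossveins:
        add(
            f"CV_{cv.rung_a}_{cv.rung_b}",
            f"K{cv.rung_a}",
            f"K{cv.rung_b}",
            sample_len(),
            sample_diam_mm(),
        )
    return pd.DataFrame(rows), pd.DataFrame(topo)


@dataclass(frozen=True)
class FixtureCircuit:
    """A network whose steady state is known in closed form.

    ``expected_flow`` maps channel id to the exact signed flow (node_a to
    node_b positive) at the stated inflow; ``expected_total_loss`` is the
    exact inlet-to-outlet loss.
    """

    name: str
    network: HydraulicNetwork
    expected_flow: dict[str, float]
    expected_total_loss: float


def _resistor_net(channels, inflow=1.0) -> HydraulicNetwork:
    segs = tuple(
        VeinSegment(id=cid, node_a=a, node_b=b, resistance=float(r))
        for cid, a, b, r in channels
    )
    return HydraulicNetwork(channels=segs, inlet="IN", outlet="OUT", inflow=inflow)


def fixture_circuits() -> list[FixtureCircuit]:
    """Closed-form circuits: hand-derived series/parallel/bridge solutions.

    Includes the five-resistor, three-loop bridge circuit (two parallel
    branches tied by a bridging resistor) with unit resistances — balanced,
    so the bridge carries nothing and each branch carries half — and the
    uniform idealized ladder without its extra crossvein, whose bypass
    resistor carries exactly Q_in/4 at a total loss of 15/8·R·Q_in.
    """
    fixtures = [
        FixtureCircuit(
            name="single_pipe",
            network=_resistor_net([("P", "IN", "OUT", 2.0)]),
            expected_flow={"P": 1.0},
            expected_total_loss=2.0,
        ),
        FixtureCircuit(
            name="two_in_series",
            network=_resistor_net([("S1", "IN", "M", 1.0), ("S2", "M", "OUT", 2.0)]),
            expected_flow={"S1": 1.0, "S2": 1.0},
            expected_total_loss=3.0,
        ),
        FixtureCircuit(
            name="two_in_parallel",
            network=_resistor_net([("P1", "IN", "OUT", 1.0), ("P2", "IN", "OUT", 1.0)]),
            expected_flow={"P1": 0.5, "P2": 0.5},
            expected_total_loss=0.5,
        ),
        FixtureCircuit(
            name="balanced_bridge",
            network=_resistor_net(
                [
                    ("R1", "IN", "M1", 2.0),
                    ("R2", "IN", "M2", 2.0),
                    ("R3", "M1", "M2", 5.0),
                    ("R4", "M1", "OUT", 2.0),
                    ("R5", "M2", "OUT", 2.0),
                ]
            ),
            expected_flow={"R1": 0.5, "R2": 0.5, "R3": 0.0, "R4": 0.5, "R5": 0.5},
            expected_total_loss=2.0,
        ),
        FixtureCircuit(
            name="five_resistor_three_loop",
            network=_resistor_net(
                [
                    ("R1", "IN", "M1", 1.0),
                    ("R2", "IN", "M2", 1.0),
                    ("R3", "M1", "M2", 1.0),
                    ("R4", "M1", "OUT", 1.0),
                    ("R5", "M2", "OUT", 1.0),
                ]
            ),
            expected_flow={"R1": 0.5, "R2": 0.5, "R3": 0.0, "R4": 0.5, "R5": 0.5},
            expected_total_loss=1.0,
        ),
    ]
    spec = IdealizedSpec(variant="uniform")
    ladder = build_idealized(spec, with_ecv=False, inflow=1.0)
    R = spec.R
    # mirror symmetry + one KVL loop: rails carry 1/2 except the bypassed
    # sixth pair (3/8); the bypass path drains 1/8 per rung-5 half and the
    # PCV returns 1/4 through the rung-6 halves
    expected = {
        "E4": 0.5, "B4": 0.5, "C4E": 0.0, "C4B": 0.0,
        "E5": 0.5, "B5": 0.5,
        "C5E": -0.125, "C5B": 0.125, "PCV": 0.25,
        "E6": 0.375, "B6": 0.375,
        "C6E": -0.125, "C6B": 0.125,
        "E7": 0.5, "B7": 0.5,
    }
    fixtures.append(
        FixtureCircuit(
            name="uniform_idealized_ladder_no_ecv",
            network=ladder,
            expected_flow=expected,
            expected_total_loss=float(Fraction(15, 8)) * R,
        )
    )
    return fixtures
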