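"""Steady-state flow in hydraulic resistor networks.

A vein (or microchannel) network is modeled as a planar graph of cylindrical
conduits carrying laminar Poiseuille flow.  Each conduit behaves as a linear
hydraulic resistor, ``Δp = r·q`` with ``r = 128 μ l / (π d⁴)``, and the network
obeys Kirchhoff's laws: mass conservation at every node and zero net pressure
loss around every closed loop.  A fixed volumetric rate ``Q_in`` enters at the
inlet node and leaves at the outlet; the quantity of interest is the total
inlet-to-outlet frictional pressure loss and the per-channel flow distribution.

Two independent formulations are provided:

``solve_nodal``
    node-potential (conductance-Laplacian) formulation with the outlet
    grounded at zero pressure — the workhorse solver;
``solve_mesh``
    loop-flow (mesh) formulation built on a spanning-tree cycle basis — an
    independent cross-check that must agree with the nodal solution to
    round-off.

At the micrometre scales considered the Reynolds number is far below unity,
so inertial ("minor") losses at bends and junctions are neglected by
construction; only frictional loss enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "FluidProperties",
    "VeinSegment",
    "HydraulicNetwork",
    "FlowSolution",
    "InvalidGeometryError",
    "SingularNetworkError",
    "DegenerateNetworkError",
    "MalformedTableError",
    "poiseuille_resistance",
    "reynolds_number",
    "resistance_uncertainty_bounds",
    "solve_nodal",
    "solve_mesh",
    "HEMOLYMPH",
    "Q_IN_DEFAULT",
    "PICOLITER",
]

#: m³ per picolitre; hemolymph inflow rates are conventionally quoted in pl/s.
PICOLITER = 1e-15


class InvalidGeometryError(ValueError):
    """A conduit has non-physical geometry (non-positive diameter, etc.)."""


class SingularNetworkError(ValueError):
    """The linear system has no unique solution (e.g. inlet cut off from outlet)."""


class DegenerateNetworkError(ValueError):
    """The network contains a zero-resistance loop or inlet-outlet short."""


class MalformedTableError(ValueError):
    """A vein table or topology listing violates its contract."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian working-fluid constants.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity μ in Pa·s.
    density : float
        Mass density ρ in kg/m³.
    """

    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise InvalidGeometryError("viscosity and density must be positive")


#: Insect hemolymph at rest: μ measured in *D. melanogaster*, ρ in *M. sexta*.
HEMOLYMPH = FluidProperties(viscosity=1.3e-3, density=1.02e3)

#: Boundary inflow imposed on the Hawaiian-fly network, 12 pl/s in m³/s.
Q_IN_DEFAULT = 12.0 * PICOLITER


def poiseuille_resistance(length: float, diameter: float, viscosity: float) -> float:
    """Hydraulic resistance ``128 μ l / (π d⁴)`` of a cylindrical conduit.

    Parameters are SI: ``length`` and ``diameter`` in metres, ``viscosity``
    in Pa·s.  Returns Pa·s/m³.  A zero-length conduit has zero resistance.
    """
    if diameter <= 0:
        raise InvalidGeometryError(f"diameter must be positive, got {diameter}")
    if viscosity <= 0:
        raise InvalidGeometryError(f"viscosity must be positive, got {viscosity}")
    if length < 0:
        raise InvalidGeometryError(f"length must be non-negative, got {length}")
    return 128.0 * viscosity * length / (math.pi * diameter**4)


def reynolds_number(props: FluidProperties, velocity: float, diameter: float) -> float:
    """Pipe-flow Reynolds number ``ρ v d / μ`` (dimensionless)."""
    if velocity < 0 or diameter <= 0:
        raise InvalidGeometryError("velocity must be >= 0 and diameter > 0")
    return props.density * velocity * diameter / props.viscosity


def resistance_uncertainty_bounds(
    diameter_rel_error: float, length_rel_error: float = 0.0
) -> tuple[float, float]:
    """Multiplicative bounds on a computed resistance under measurement error.

    With ``r ∝ l / d⁴``, a relative diameter error ``e_d`` and length error
    ``e_l`` bound the ratio computed/true resistance by
    ``(1/(1+e_d))⁴ (1−e_l)`` from below and ``(1/(1−e_d))⁴ (1+e_l)`` from
    above.  For the wing-image measurement errors (20 % diameter, 1.4 %
    length) these evaluate to roughly 0.48 and 2.5.
    """
    e_d, e_l = diameter_rel_error, length_rel_error
    if not (0 <= e_d < 1 and 0 <= e_l < 1):
        raise ValueError("relative errors must lie in [0, 1)")
    low = (1.0 / (1.0 + e_d)) ** 4 * (1.0 - e_l)
    high = (1.0 / (1.0 - e_d)) ** 4 * (1.0 + e_l)
    return low, high


@dataclass(frozen=True)
class VeinSegment:
    """One conduit of the network.

    ``resistance`` (Pa·s/m³) is what the solvers consume; it is either
    supplied directly (idealized resistors) or derived from geometry via
    :func:`poiseuille_resistance` (see :meth:`from_geometry`).  Geometry
    fields, when present, are SI metres.
    """

    id: str
    node_a: str
    node_b: str
    resistance: float
    length: float | None = None
    inner_diameter: float | None = None
    outer_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise InvalidGeometryError(f"{self.id}: resistance must be >= 0")
        if self.length is not None and self.length < 0:
            raise InvalidGeometryError(f"{self.id}: length must be >= 0")
        if self.inner_diameter is not None and self.inner_diameter <= 0:
            raise InvalidGeometryError(f"{self.id}: inner diameter must be > 0")
        if (
            self.outer_diameter is not None
            and self.inner_diameter is not None
            and self.outer_diameter < self.inner_diameter
        ):
            raise InvalidGeometryError(f"{self.id}: outer diameter < inner diameter")
        if self.node_a == self.node_b:
            raise InvalidGeometryError(f"{self.id}: self-loop channel")

    @classmethod
    def from_geometry(
        cls,
        id: str,
        node_a: str,
        node_b: str,
        length: float,
        inner_diameter: float,
        viscosity: float,
        outer_diameter: float | None = None,
    ) -> "VeinSegment":
        """Build a segment whose resistance follows from Poiseuille's law."""
        return cls(
            id=id,
            node_a=node_a,
            node_b=node_b,
            resistance=poiseuille_resistance(length, inner_diameter, viscosity),
            length=length,
            inner_diameter=inner_diameter,
            outer_diameter=outer_diameter,
        )


@dataclass(frozen=True)
class HydraulicNetwork:
    """A resistor network with designated inlet/outlet and boundary inflow.

    ``inflow`` is the volumetric rate (m³/s) entering at ``inlet`` and
    leaving at ``outlet``; steady state forces Q_in = Q_out.
    """

    channels: tuple[VeinSegment, ...]
    inlet: str
    outlet: str
    inflow: float = Q_IN_DEFAULT

    def __post_init__(self) -> None:
        if self.inlet == self.outlet:
            raise MalformedTableError("inlet and outlet must differ")
        object.__setattr__(self, "channels", tuple(self.channels))
        seen: set[str] = set()
        for ch in self.channels:
            if ch.id in seen:
                raise MalformedTableError(f"duplicate channel id {ch.id!r}")
            seen.add(ch.id)
        nodes = self.nodes
        if self.inlet not in nodes or self.outlet not in nodes:
            raise MalformedTableError("inlet/outlet must appear among channel end nodes")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for ch in self.channels for n in (ch.node_a, ch.node_b))

    @property
    def channel_map(self) -> dict[str, VeinSegment]:
        return {ch.id: ch for ch in self.channels}

    def graph(self) -> nx.MultiGraph:
        """Undirected multigraph view (parallel channels allowed)."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for ch in self.channels:
            g.add_edge(ch.node_a, ch.node_b, key=ch.id, segment=ch)
        return g

    def without_channel(self, channel_id: str) -> "HydraulicNetwork":
        """A copy with one channel deleted (virtual ablation)."""
        if channel_id not in self.channel_map:
            raise KeyError(f"no channel named {channel_id!r}")
        return replace(
            self, channels=tuple(c for c in self.channels if c.id != channel_id)
        )

    def with_channel(self, segment: VeinSegment) -> "HydraulicNetwork":
        """A copy with one channel added."""
        return replace(self, channels=self.channels + (segment,))


@dataclass(frozen=True)
class FlowSolution:
    """Solved steady state of a :class:`HydraulicNetwork`.

    ``channel_flow[i]`` is signed positive from ``node_a`` to ``node_b``;
    ``channel_loss[i] = r_i q_i`` carries the same sign (it equals the
    pressure difference p(node_a) − p(node_b)).  Pressures are relative to
    the outlet, so ``total_loss == node_pressure[inlet]``.
    """

    channel_flow: Mapping[str, float]
    channel_loss: Mapping[str, float]
    node_pressure: Mapping[str, float]
    total_loss: float

    def flow_fraction(self, channel_id: str, inflow: float) -> float:
        """|q| for one channel as a fraction of the boundary inflow."""
        return abs(self.channel_flow[channel_id]) / inflow


# ---------------------------------------------------------------------------
# zero-resistance handling (node coalescing)

def _coalesce_zero_resistance(net: HydraulicNetwork):
    """Merge nodes joined by zero-resistance channels.

    Returns (supernode-of-node map, list of resistive channels, list of
    zero-resistance channels).  A cycle of zero-resistance channels leaves
    individual flows undetermined, and a zero-resistance inlet-outlet short
    leaves the loss trivially zero; both are rejected as degenerate.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    zero = [c for c in net.channels if c.resistance == 0.0]
    resistive = [c for c in net.channels if c.resistance > 0.0]
    for ch in zero:
        ra, rb = find(ch.node_a), find(ch.node_b)
        if ra == rb:
            raise DegenerateNetworkError(
                f"zero-resistance loop through channel {ch.id!r}"
            )
        parent[ra] = rb
    for n in net.nodes:
        find(n)
    super_of = {n: find(n) for n in net.nodes}
    if super_of[net.inlet] == super_of[net.outlet]:
        raise DegenerateNetworkError("inlet and outlet joined by zero-resistance path")
    return super_of, resistive, zero


def _recover_zero_flows(
    net: HydraulicNetwork,
    zero: list[VeinSegment],
    flows: dict[str, float],
) -> None:
    """Fill in flows on zero-resistance channels by nodal mass balance.

    The zero-resistance channels form a forest (cycles were rejected), so
    peeling leaves determines every flow uniquely.  ``flows`` already holds
    the resistive-channel flows and is updated in place.
    """
    imbalance: dict[str, float] = {}
    for ch in net.channels:
        if ch.resistance > 0.0:
            q = flows[ch.id]
            imbalance[ch.node_a] = imbalance.get(ch.node_a, 0.0) - q
            imbalance[ch.node_b] = imbalance.get(ch.node_b, 0.0) + q
    imbalance[net.inlet] = imbalance.get(net.inlet, 0.0) + net.inflow
    imbalance[net.outlet] = imbalance.get(net.outlet, 0.0) - net.inflow

    remaining = {ch.id: ch for ch in zero}
    incident: dict[str, list[str]] = {}
    for cid, ch in remaining.items():
        incident.setdefault(ch.node_a, []).append(cid)
        incident.setdefault(ch.node_b, []).append(cid)
    leaves = [n for n, cs in incident.items() if len(cs) == 1]
    while leaves:
        n = leaves.pop()
        cids = [c for c in incident.get(n, []) if c in remaining]
        if not cids:
            continue
        (cid,) = cids
        ch = remaining.pop(cid)
        # net inflow at n must exit through the last zero-resistance edge
        q = imbalance.get(n, 0.0)
        if ch.node_a == n:
            flows[cid] = q
            other = ch.node_b
        else:
            flows[cid] = -q
            other = ch.node_a
        imbalance[n] = 0.0
        imbalance[other] = imbalance.get(other, 0.0) + q
        if len([c for c in incident.get(other, []) if c in remaining]) == 1:
            leaves.append(other)


def _split_components(net: HydraulicNetwork):
    """Channels in the inlet-outlet component vs. isolated appendages."""
    g = net.graph()
    comps = list(nx.connected_components(g))
    main = next((c for c in comps if net.inlet in c), None)
    if main is None or net.outlet not in main:
        raise SingularNetworkError("inlet is not connected to outlet")
    in_main = [c for c in net.channels if c.node_a in main]
    outside = [c for c in net.channels if c.node_a not in main]
    return main, in_main, outside


# ---------------------------------------------------------------------------
# nodal (conductance-Laplacian) formulation

def solve_nodal(network: HydraulicNetwork) -> FlowSolution:
    """Solve the network by nodal analysis with the outlet grounded.

    Assembles the weighted graph Laplacian of conductances ``g = 1/r``,
    imposes the boundary injection (+Q_in at the inlet, −Q_in at the
    outlet), grounds the outlet at zero pressure and solves the reduced
    dense system.  Channels outside the inlet-outlet component carry zero
    flow and get NaN pressures.
    """
    main, in_main, outside = _split_components(network)
    sub = replace(network, channels=tuple(in_main))
    super_of, resistive, zero = _coalesce_zero_resistance(sub)

    supers = sorted(set(super_of.values()))
    idx = {s: i for i, s in enumerate(supers)}
    n = len(supers)
    lap = np.zeros((n, n))
    for ch in resistive:
        g = 1.0 / ch.resistance
        i, j = idx[super_of[ch.node_a]], idx[super_of[ch.node_b]]
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    rhs = np.zeros(n)
    rhs[idx[super_of[network.inlet]]] += network.inflow
    rhs[idx[super_of[network.outlet]]] -= network.inflow

    o = idx[super_of[network.outlet]]
    keep = [i for i in range(n) if i != o]
    reduced = lap[np.ix_(keep, keep)]
    try:
        if reduced.size and np.linalg.cond(reduced) > 1e13:
            raise SingularNetworkError("conductance matrix is ill-conditioned")
        sol = np.linalg.solve(reduced, rhs[keep]) if reduced.size else np.empty(0)
    except np.linalg.LinAlgError as exc:
        raise SingularNetworkError("conductance matrix is singular") from exc
    pressure = np.zeros(n)
    pressure[keep] = sol

    node_pressure = {nd: float(pressure[idx[super_of[nd]]]) for nd in sub.nodes}
    flows: dict[str, float] = {}
    for ch in resistive:
        dp = node_pressure[ch.node_a] - node_pressure[ch.node_b]
        flows[ch.id] = dp / ch.resistance
    _recover_zero_flows(sub, zero, flows)

    for ch in outside:
        flows[ch.id] = 0.0
    for nd in network.nodes - sub.nodes:
        node_pressure[nd] = math.nan

    losses = {c.id: c.resistance * flows[c.id] for c in network.channels}
    return FlowSolution(
        channel_flow=flows,
        channel_loss=losses,
        node_pressure=node_pressure,
        total_loss=node_pressure[network.inlet],
    )


# ---------------------------------------------------------------------------
# mesh (loop-flow) formulation

def solve_mesh(network: HydraulicNetwork) -> FlowSolution:
    """Solve the network by loop analysis on a spanning-tree cycle basis.

    The boundary source drives a known loop flow Q_in around the tree path
    outlet→inlet; every chord contributes one unknown loop flow around its
    fundamental cycle.  Requiring the signed resistive losses to vanish
    around each chord cycle yields a dense symmetric system in the loop
    flows.  Entirely independent of :func:`solve_nodal`, which it serves to
    cross-check.
    """
    main, in_main, outside = _split_components(network)
    sub = replace(network, channels=tuple(in_main))
    # reject the same degeneracies as the nodal route
    _coalesce_zero_resistance(sub)

    # simple graph on distinct node pairs; parallel channels become chords
    tree_edge: dict[frozenset, VeinSegment] = {}
    chords: list[VeinSegment] = []
    g = nx.Graph()
    g.add_nodes_from(sub.nodes)
    for ch in sub.channels:
        key = frozenset((ch.node_a, ch.node_b))
        if g.has_edge(ch.node_a, ch.node_b):
            chords.append(ch)
        else:
            g.add_edge(ch.node_a, ch.node_b)
            tree_edge[key] = ch
    tree = nx.minimum_spanning_tree(g)
    for key, ch in list(tree_edge.items()):
        a, b = tuple(key)
        if not tree.has_edge(a, b):
            chords.append(ch)
            del tree_edge[key]

    def tree_path_signs(src: str, dst: str) -> dict[str, float]:
        """Map channel id -> ±1 for tree channels along the src→dst path."""
        path = nx.shortest_path(tree, src, dst)
        signs: dict[str, float] = {}
        for a, b in zip(path, path[1:]):
            ch = tree_edge[frozenset((a, b))]
            signs[ch.id] = 1.0 if (ch.node_a, ch.node_b) == (a, b) else -1.0
        return signs

    m = len(chords)
    # loop orientation of chord k: along the chord a->b, closing b->a in tree
    basis: list[dict[str, float]] = []
    for ch in chords:
        loop = tree_path_signs(ch.node_b, ch.node_a)
        loop[ch.id] = 1.0
        basis.append(loop)
    source_loop = tree_path_signs(sub.inlet, sub.outlet)

    res = {c.id: c.resistance for c in sub.channels}
    amat = np.zeros((m, m))
    bvec = np.zeros(m)
    for i, loop_i in enumerate(basis):
        for cid, s_i in loop_i.items():
            r = res[cid]
            if r == 0.0:
                continue
            bvec[i] -= s_i * r * source_loop.get(cid, 0.0) * sub.inflow
            for j, loop_j in enumerate(basis):
                s_j = loop_j.get(cid, 0.0)
                if s_j:
                    amat[i, j] += s_i * r * s_j
    try:
        if amat.size and np.linalg.cond(amat) > 1e13:
            raise SingularNetworkError("mesh matrix is ill-conditioned")
        x = np.linalg.solve(amat, bvec) if m else np.empty(0)
    except np.linalg.LinAlgError as exc:
        raise SingularNetworkError("mesh matrix is singular") from exc

    flows = {c.id: source_loop.get(c.id, 0.0) * sub.inflow for c in sub.channels}
    for k, loop in enumerate(basis):
        for cid, s in loop.items():
            flows[cid] += s * x[k]

    # pressures by integrating r·q along tree paths from the grounded outlet
    node_pressure: dict[str, float] = {}
    for nd in sub.nodes:
        p = 0.0
        for cid, s in tree_path_signs(nd, sub.outlet).items():
            p += s * res[cid] * flows[cid]
        node_pressure[nd] = p

    for ch in outside:
        flows[ch.id] = 0.0
    for nd in network.nodes - sub.nodes:
        node_pressure[nd] = math.nan

    losses = {c.id: c.resistance * flows[c.id] for c in network.channels}
    return FlowSolution(
        channel_flow=flows,
        channel_loss=losses,
        node_pressure=node_pressure,
        total_loss=node_pressure[network.inlet],
    )
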