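"""Solver contracts: Poiseuille resistance, nodal/mesh duality, invariants."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veinflow.core import (
    DegenerateNetworkError,
    FluidProperties,
    HydraulicNetwork,
    InvalidGeometryError,
    SingularNetworkError,
    VeinSegment,
    poiseuille_resistance,
    resistance_uncertainty_bounds,
    reynolds_number,
    solve_mesh,
    solve_nodal,
)
from veinflow.io import network_from_tables
from veinflow.synth import CrossveinInsertion, LadderSpec, fixture_circuits, random_ladder

SOLVERS = [solve_nodal, solve_mesh]


def _resistors(channels, inflow=1.0):
    segs = tuple(VeinSegment(c, a, b, resistance=r) for c, a, b, r in channels)
    return HydraulicNetwork(channels=segs, inlet="IN", outlet="OUT", inflow=inflow)


class TestPoiseuilleResistance:
    def test_measured_crossvein_value(self):
        # 0.62 mm long, 7.4 µm lumen, hemolymph viscosity
        r = poiseuille_resistance(6.2e-4, 7.4e-6, 1.3e-3)
        assert r == pytest.approx(1.10e16, rel=5e-3)

    def test_fourth_power_diameter_scaling(self):
        r1 = poiseuille_resistance(1e-3, 5e-6, 1.3e-3)
        r2 = poiseuille_resistance(1e-3, 10e-6, 1.3e-3)
        assert r1 / r2 == pytest.approx(16.0)

    def test_zero_length_has_zero_resistance(self):
        assert poiseuille_resistance(0.0, 5e-6, 1.3e-3) == 0.0

    @pytest.mark.parametrize("length,diam,mu", [(1e-3, 0.0, 1e-3), (1e-3, -1e-6, 1e-3), (1e-3, 1e-6, 0.0), (-1e-3, 1e-6, 1e-3)])
    def test_invalid_geometry_rejected(self, length, diam, mu):
        with pytest.raises(InvalidGeometryError):
            poiseuille_resistance(length, diam, mu)

    @settings(derandomize=True, max_examples=50)
    @given(
        length=st.floats(1e-6, 1e-2), diam=st.floats(1e-6, 1e-4),
        mu=st.floats(1e-4, 1e-2), c=st.floats(1.1, 10.0),
    )
    def test_linearity_in_length_and_viscosity(self, length, diam, mu, c):
        r = poiseuille_resistance(length, diam, mu)
        assert poiseuille_resistance(c * length, diam, mu) == pytest.approx(c * r)
        assert poiseuille_resistance(length, diam, c * mu) == pytest.approx(c * r)


class TestReynoldsNumber:
    def test_hemolymph_conditions_are_viscous(self):
        props = FluidProperties(viscosity=1.3e-3, density=1.02e3)
        re = reynolds_number(props, velocity=1e-4, diameter=1e-5)
        assert re == pytest.approx(7.8e-4, rel=1e-2)
        assert re < 1e-3

    def test_zero_velocity(self):
        props = FluidProperties(1.3e-3, 1.02e3)
        assert reynolds_number(props, 0.0, 1e-5) == 0.0


class TestUncertaintyBounds:
    def test_diameter_error_alone(self):
        low, high = resistance_uncertainty_bounds(0.20)
        assert low == pytest.approx((1 / 1.2) ** 4, rel=1e-9)
        assert high == pytest.approx((1 / 0.8) ** 4, rel=1e-9)

    def test_combined_image_resolution_errors(self):
        # 20 % diameter and 1.4 % length errors round to the quoted 0.48-2.5x
        low, high = resistance_uncertainty_bounds(0.20, 0.014)
        assert round(low, 2) == 0.48
        assert round(high, 1) == 2.5

    def test_no_error_is_identity(self):
        assert resistance_uncertainty_bounds(0.0, 0.0) == (1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(e_d=st.floats(0.0, 0.5), e_l=st.floats(0.0, 0.5))
    def test_bounds_bracket_unity(self, e_d, e_l):
        low, high = resistance_uncertainty_bounds(e_d, e_l)
        assert low <= 1.0 <= high


@pytest.mark.parametrize("solver", SOLVERS, ids=["nodal", "mesh"])
class TestClosedFormCircuits:
    @pytest.mark.parametrize("fixture", fixture_circuits(), ids=lambda f: f.name)
    def test_matches_closed_form(self, solver, fixture):
        sol = solver(fixture.network)
        scale = max(abs(v) for v in fixture.expected_flow.values())
        for cid, expected in fixture.expected_flow.items():
            assert sol.channel_flow[cid] == pytest.approx(expected, abs=1e-10 * scale)
        assert sol.total_loss == pytest.approx(fixture.expected_total_loss, rel=1e-10)

    def test_parallel_identical_channels_split_evenly(self, solver):
        net = _resistors([("P1", "IN", "OUT", 3.0), ("P2", "IN", "OUT", 3.0)], inflow=2.0)
        sol = solver(net)
        assert sol.channel_flow["P1"] == pytest.approx(1.0)
        assert sol.channel_flow["P2"] == pytest.approx(1.0)

    def test_single_loop_series(self, solver):
        net = _resistors([("S1", "IN", "M", 1.5), ("S2", "M", "OUT", 2.5)])
        assert solver(net).total_loss == pytest.approx(4.0)

    def test_zero_resistance_channel_in_series(self, solver):
        net = _resistors([("S1", "IN", "M", 2.0), ("Z", "M", "OUT", 0.0)])
        sol = solver(net)
        assert sol.channel_flow["Z"] == pytest.approx(1.0)
        assert sol.total_loss == pytest.approx(2.0)

    def test_disconnected_outlet_is_singular(self, solver):
        net = _resistors([("S1", "IN", "M", 1.0), ("S2", "Q", "OUT", 1.0)])
        with pytest.raises(SingularNetworkError):
            solver(net)

    def test_zero_resistance_loop_is_degenerate(self, solver):
        net = _resistors(
            [("S1", "IN", "M", 1.0), ("Z1", "M", "OUT", 0.0), ("Z2", "M", "OUT", 0.0)]
        )
        with pytest.raises(DegenerateNetworkError):
            solver(net)

    def test_zero_resistance_short_is_degenerate(self, solver):
        net = _resistors([("Z", "IN", "OUT", 0.0), ("S", "IN", "OUT", 1.0)])
        with pytest.raises(DegenerateNetworkError):
            solver(net)

    def test_dangling_appendage_carries_no_flow(self, solver):
        net = _resistors(
            [("S1", "IN", "OUT", 2.0), ("D", "OUT", "T", 1.0)]
        )
        sol = solver(net)
        assert sol.channel_flow["D"] == 0.0
        assert sol.total_loss == pytest.approx(2.0)


def _random_network(seed, with_crossvein=False):
    cv = (CrossveinInsertion(2, 3, 0.4, 0.6),) if with_crossvein else ()
    spec = LadderSpec(n_rungs=4, seed=seed, crossveins=cv)
    table, topo = random_ladder(spec)
    return network_from_tables(table, topo)


class TestNetworkInvariants:
    """Conservation, loop-consistency, energy and duality on random ladders."""

    SEEDS = range(25)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_mass_conserved_at_every_node(self, seed):
        net = _random_network(seed, with_crossvein=seed % 2 == 0)
        sol = solve_nodal(net)
        balance = {n: 0.0 for n in net.nodes}
        for ch in net.channels:
            balance[ch.node_a] -= sol.channel_flow[ch.id]
            balance[ch.node_b] += sol.channel_flow[ch.id]
        balance[net.inlet] += net.inflow
        balance[net.outlet] -= net.inflow
        assert max(abs(v) for v in balance.values()) <= 1e-9 * net.inflow

    @pytest.mark.parametrize("seed", SEEDS)
    def test_loop_losses_sum_to_zero(self, seed):
        net = _random_network(seed, with_crossvein=seed % 3 == 0)
        sol = solve_nodal(net)
        g = nx.Graph()
        seg_of = {}
        for ch in net.channels:
            g.add_edge(ch.node_a, ch.node_b)
            seg_of[frozenset((ch.node_a, ch.node_b))] = ch
        for cycle in nx.cycle_basis(g):
            total = 0.0
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                ch = seg_of[frozenset((a, b))]
                sign = 1.0 if (ch.node_a, ch.node_b) == (a, b) else -1.0
                total += sign * sol.channel_loss[ch.id]
            assert abs(total) <= 1e-9 * sol.total_loss

    @pytest.mark.parametrize("seed", SEEDS)
    def test_energy_identity(self, seed):
        # power delivered by the source equals total frictional dissipation
        net = _random_network(seed)
        sol = solve_nodal(net)
        dissipated = sum(
            ch.resistance * sol.channel_flow[ch.id] ** 2 for ch in net.channels
        )
        assert dissipated == pytest.approx(sol.total_loss * net.inflow, rel=1e-8)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_nodal_and_mesh_formulations_agree(self, seed):
        net = _random_network(seed, with_crossvein=True)
        a, b = solve_nodal(net), solve_mesh(net)
        assert a.total_loss == pytest.approx(b.total_loss, rel=1e-8)
        for cid in a.channel_flow:
            assert a.channel_flow[cid] == pytest.approx(
                b.channel_flow[cid], rel=1e-8, abs=1e-8 * net.inflow
            )

    @pytest.mark.parametrize("seed", SEEDS)
    def test_rayleigh_monotonicity_under_channel_insertion(self, seed):
        plain = _random_network(seed, with_crossvein=False)
        crossed = _random_network(seed, with_crossvein=True)
        assert solve_nodal(crossed).total_loss <= solve_nodal(plain).total_loss * (
            1 + 1e-12
        )

    def test_resistance_scaling_scales_pressures_only(self):
        net = _random_network(7)
        scaled = HydraulicNetwork(
            channels=tuple(
                VeinSegment(c.id, c.node_a, c.node_b, resistance=3.0 * c.resistance)
                for c in net.channels
            ),
            inlet=net.inlet, outlet=net.outlet, inflow=net.inflow,
        )
        a, b = solve_nodal(net), solve_nodal(scaled)
        assert b.total_loss == pytest.approx(3.0 * a.total_loss, rel=1e-10)
        for cid in a.channel_flow:
            assert b.channel_flow[cid] == pytest.approx(
                a.channel_flow[cid], abs=1e-12 * net.inflow
            )

    def test_removing_a_zero_flow_channel_changes_nothing(self):
        bridge = next(f for f in fixture_circuits() if f.name == "balanced_bridge")
        full = solve_nodal(bridge.network)
        cut = solve_nodal(bridge.network.without_channel("R3"))
        assert cut.total_loss == pytest.approx(full.total_loss, rel=1e-12)
        for cid in cut.channel_flow:
            assert cut.channel_flow[cid] == pytest.approx(full.channel_flow[cid], rel=1e-12)

    def test_solution_independent_of_channel_ordering(self):
        net = _random_network(11)
        shuffled = HydraulicNetwork(
            channels=tuple(reversed(net.channels)),
            inlet=net.inlet, outlet=net.outlet, inflow=net.inflow,
        )
        a, b = solve_nodal(net), solve_nodal(shuffled)
        for cid in a.channel_flow:
            assert a.channel_flow[cid] == pytest.approx(b.channel_flow[cid], rel=1e-12)


class TestDomainTypes:
    def test_fluid_properties_must_be_positive(self):
        with pytest.raises(InvalidGeometryError):
            FluidProperties(viscosity=0.0, density=1e3)

    def test_segment_rejects_outer_smaller_than_inner(self):
        with pytest.raises(InvalidGeometryError):
            VeinSegment("V", "a", "b", resistance=1.0,
                        inner_diameter=2e-5, outer_diameter=1e-5)

    def test_segment_rejects_self_loop(self):
        with pytest.raises(InvalidGeometryError):
            VeinSegment("V", "a", "a", resistance=1.0)

    def test_network_rejects_duplicate_ids(self):
        with pytest.raises(Exception):
            _resistors([("P", "IN", "OUT", 1.0), ("P", "IN", "OUT", 2.0)])

    def test_total_loss_equals_inlet_pressure(self):
        net = _resistors([("S1", "IN", "M", 1.0), ("S2", "M", "OUT", 1.0)])
        sol = solve_nodal(net)
        assert sol.total_loss == sol.node_pressure["IN"]
        assert sol.node_pressure["OUT"] == 0.0
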