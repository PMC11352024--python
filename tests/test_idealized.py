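"""Idealized microchannel circuits: exact shares, sweeps and variants."""

from fractions import Fraction

import numpy as np
import pytest

from veinflow.core import solve_mesh, solve_nodal
from veinflow.idealized import (
    VARIANTS,
    IdealizedSpec,
    build_idealized,
    sweep_idealized,
    valley_steepness,
)


@pytest.fixture(scope="module")
def uniform():
    return IdealizedSpec(variant="uniform")


class TestUniformCircuit:
    def test_bypass_share_without_crossvein(self, uniform):
        net = build_idealized(uniform, with_ecv=False)
        sol = solve_nodal(net)
        assert sol.flow_fraction("PCV", net.inflow) == pytest.approx(0.25, abs=1e-12)

    def test_total_loss_without_crossvein(self, uniform):
        net = build_idealized(uniform, with_ecv=False)
        expected = float(Fraction(15, 8)) * uniform.R * net.inflow
        assert solve_nodal(net).total_loss == pytest.approx(expected, rel=1e-12)

    def test_crossvein_diverts_two_sevenths(self, uniform):
        net = build_idealized(uniform)
        sol = solve_nodal(net)
        assert sol.flow_fraction("ECV", net.inflow) == pytest.approx(2 / 7, abs=1e-12)
        assert sol.flow_fraction("PCV", net.inflow) == pytest.approx(2 / 7, abs=1e-12)

    def test_fifth_connecting_resistor_loses_flow(self, uniform):
        net = build_idealized(uniform)
        sol = solve_nodal(net)
        assert sol.flow_fraction("C5E", net.inflow) == pytest.approx(0.0, abs=1e-12)
        assert sol.flow_fraction("C5B", net.inflow) == pytest.approx(0.0, abs=1e-12)

    def test_loss_reduction_is_six_seventieths(self, uniform):
        with_net = build_idealized(uniform)
        without = build_idealized(uniform, with_ecv=False)
        lw = solve_nodal(with_net).total_loss
        lo = solve_nodal(without).total_loss
        assert lw == pytest.approx(float(Fraction(12, 7)) * uniform.R * with_net.inflow, rel=1e-12)
        assert (lo - lw) / lo == pytest.approx(float(Fraction(6, 70)), abs=1e-12)

    def test_mirror_symmetry_of_rail_flows(self, uniform):
        net = build_idealized(uniform, with_ecv=False)
        sol = solve_nodal(net)
        for i in range(4, 8):
            assert sol.channel_flow[f"E{i}"] == pytest.approx(
                sol.channel_flow[f"B{i}"], rel=1e-12
            )
        for cid in ("C4E", "C4B"):
            assert sol.flow_fraction(cid, net.inflow) == pytest.approx(0.0, abs=1e-12)

    def test_both_formulations_agree(self, uniform):
        net = build_idealized(uniform)
        a, b = solve_nodal(net), solve_mesh(net)
        assert a.total_loss == pytest.approx(b.total_loss, rel=1e-10)


class TestVariants:
    def test_asymmetric_overrides(self):
        spec = IdealizedSpec(variant="asymmetric")
        net = build_idealized(spec)
        by_id = net.channel_map
        assert by_id["B5"].resistance == pytest.approx(0.2 * spec.R)
        assert by_id["E6"].resistance == pytest.approx(200 * spec.R)
        assert by_id["C4E"].resistance == pytest.approx(0.5 * spec.R)

    def test_high_connecting_resistance_overrides(self):
        spec = IdealizedSpec(variant="asymmetric_highC")
        net = build_idealized(spec)
        by_id = net.channel_map
        assert by_id["C4E"].resistance == pytest.approx(10 * spec.R)
        assert by_id["C5B"].resistance == pytest.approx(10 * spec.R)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            IdealizedSpec(variant="bogus")

    def test_fraction_bounds(self, uniform):
        with pytest.raises(ValueError):
            build_idealized(uniform, u=0.0, v=0.5)


class TestSweeps:
    GRID = np.round(np.arange(0.05, 1.0, 0.05), 6)

    def test_uniform_minimum_at_initial_position(self, uniform):
        surface = sweep_idealized(uniform, self.GRID, self.GRID)
        assert surface.argmin() == (0.5, 0.5)

    def test_uniform_point_symmetry(self, uniform):
        surface = sweep_idealized(uniform, self.GRID, self.GRID)
        np.testing.assert_allclose(
            surface.values, surface.values[::-1, ::-1], rtol=1e-9
        )

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_best_outlet_connection_is_the_junction(self, variant):
        surface = sweep_idealized(IdealizedSpec(variant), self.GRID, self.GRID)
        assert np.all(surface.argmin_along_p() == 0.5)

    def test_high_connecting_resistance_steepens_the_valley(self):
        # penalty for leaving the junction at fixed inlet-side position
        for u in (0.25, 0.5, 0.75):
            pens = {}
            for variant in ("asymmetric", "asymmetric_highC"):
                spec = IdealizedSpec(variant)
                base = solve_nodal(build_idealized(spec, u, 0.5)).total_loss
                off = solve_nodal(build_idealized(spec, u, 0.3)).total_loss
                ref = solve_nodal(build_idealized(spec, with_ecv=False)).total_loss
                pens[variant] = (off - base) / ref
            assert pens["asymmetric_highC"] > pens["asymmetric"]

    def test_valley_steepness_ordering(self):
        u_grid = np.arange(0.1, 1.0, 0.1)
        v_grid = np.array([0.49, 0.5, 0.51])
        steep = {
            variant: valley_steepness(
                sweep_idealized(IdealizedSpec(variant), u_grid, v_grid)
            )
            for variant in VARIANTS
        }
        assert steep["uniform"] < steep["asymmetric"] < steep["asymmetric_highC"]
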