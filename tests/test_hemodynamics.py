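import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from portalwss.errors import ConfigError, DomainError, ValidationError
from portalwss.geometry import apply_splenectomy
from portalwss.hemodynamics import (
    MMHG_TO_PA,
    BoundaryConditions,
    FlowSplit,
    assign_inlet_flows,
    compute_pressures,
    compute_wss_field,
    solve_flows,
)
from portalwss.rheology import CarreauParams

from conftest import make_tree

NEWTONIAN = CarreauParams(mu0=0.0035, mu_inf=0.0035, n=1.0)
SPLIT = {"SMV": 0.40, "SV": 0.45, "LGV": 0.05, "IMV": 0.10}


def poiseuille_tau(Q, R, mu=0.0035):
    return 4.0 * mu * Q / (math.pi * R**3)


class TestFlowSplit:
    def test_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            FlowSplit({"SMV": 0.5, "SV": 0.4, "LGV": 0.05, "IMV": 0.1})

    def test_missing_inlet_is_config_error(self):
        split = FlowSplit({"SMV": 0.5, "SV": 0.5, "LGV": 0.0, "IMV": 0.0})
        with pytest.raises(ConfigError):
            split["PV"]


class TestAssignInletFlows:
    def test_total_pv_flow_from_velocity_and_diameter(self):
        tree = make_tree(diameters={"PV": 0.012})
        bc = BoundaryConditions(pv_velocity=0.15, flow_split=FlowSplit(SPLIT))
        flows = assign_inlet_flows(tree, bc)
        q_total = 0.15 * math.pi * 0.012**2 / 4
        assert q_total == pytest.approx(1.696e-5, rel=1e-3)
        assert sum(flows.values()) == pytest.approx(q_total, rel=1e-12)
        assert flows["SMV"] == pytest.approx(0.40 * q_total, rel=1e-12)
        assert flows["SMV"] == pytest.approx(6.79e-6, rel=1e-3)

    def test_postoperative_sv_share_removed(self):
        post = apply_splenectomy(make_tree(diameters={"PV": 0.012}))
        bc = BoundaryConditions(pv_velocity=0.15, flow_split=FlowSplit(SPLIT))
        flows = assign_inlet_flows(post, bc)
        q_total = 0.15 * math.pi * 0.012**2 / 4
        assert "SV" not in flows
        assert sum(flows.values()) == pytest.approx(0.55 * q_total, rel=1e-12)
        assert sum(flows.values()) == pytest.approx(9.33e-6, rel=1e-3)

    def test_postoperative_renormalize_mode_keeps_total(self):
        post = apply_splenectomy(make_tree(diameters={"PV": 0.012}))
        bc = BoundaryConditions(
            pv_velocity=0.15, flow_split=FlowSplit(SPLIT), flow_mode="renormalize"
        )
        flows = assign_inlet_flows(post, bc)
        q_total = 0.15 * math.pi * 0.012**2 / 4
        assert sum(flows.values()) == pytest.approx(q_total, rel=1e-12)
        assert flows["SMV"] / flows["IMV"] == pytest.approx(4.0, rel=1e-12)


class TestSolveFlows:
    def test_outlet_carries_sum_of_inlets(self, pre_tree):
        flows = solve_flows(
            pre_tree, {"SMV": 1e-6, "SV": 2e-6, "LGV": 3e-6, "IMV": 0.0}
        )
        assert flows.outflow("PV") == pytest.approx(6e-6, rel=1e-12)

    def test_stump_flow_is_zero(self, post_tree):
        flows = solve_flows(post_tree, {"SMV": 1e-6, "LGV": 1e-6, "IMV": 1e-6})
        assert flows.outflow("SV") == 0.0
        assert flows.flow_at("SV", 0.5) == 0.0

    def test_type3_smv_picks_up_imv_downstream_of_junction(self):
        tree = make_tree(anatomy_type=3)
        q = {"SMV": 4e-6, "SV": 2e-6, "LGV": 1e-6, "IMV": 3e-6}
        flows = solve_flows(tree, q)
        junction = tree.attachments[tree.segment("IMV").distal_node][1]
        assert flows.flow_at("SMV", junction - 0.01) == pytest.approx(4e-6)
        assert flows.flow_at("SMV", junction + 0.01) == pytest.approx(7e-6)
        assert flows.outflow("PV") == pytest.approx(1e-5, rel=1e-12)

    def test_type2_pv_picks_up_lgv_downstream_of_junction(self):
        tree = make_tree(anatomy_type=2)
        q = {"SMV": 4e-6, "SV": 2e-6, "LGV": 1e-6, "IMV": 3e-6}
        flows = solve_flows(tree, q)
        junction = tree.attachments[tree.segment("LGV").distal_node][1]
        assert flows.flow_at("PV", junction - 0.01) == pytest.approx(9e-6)
        assert flows.flow_at("PV", junction + 0.01) == pytest.approx(1e-5)

    def test_negative_inflow_rejected(self, pre_tree):
        with pytest.raises(DomainError):
            solve_flows(pre_tree, {"SMV": -1e-6, "SV": 0, "LGV": 0, "IMV": 0})

    @given(
        atype=st.sampled_from([1, 2, 3]),
        qs=st.lists(st.floats(0.0, 1e-4), min_size=4, max_size=4),
    )
    def test_mass_conservation(self, atype, qs):
        """Junction mass balance: the outlet carries exactly the inlet sum."""
        tree = make_tree(anatomy_type=atype)
        inflows = dict(zip(("SMV", "SV", "LGV", "IMV"), qs))
        flows = solve_flows(tree, inflows)
        total = sum(qs)
        assert flows.outflow("PV") == pytest.approx(total, rel=1e-12, abs=1e-30)
        # each tributary delivers its full flow to its host
        for name in ("SMV", "SV", "LGV", "IMV"):
            assert flows.outflow(name) >= inflows[name] * (1 - 1e-12)


class TestWSSField:
    def test_newtonian_end_to_end_poiseuille(self, post_tree):
        """Every flowing strip matches the Poiseuille closed form exactly."""
        flows = solve_flows(post_tree, {"SMV": 6e-6, "LGV": 1e-6, "IMV": 2e-6})
        field = compute_wss_field(post_tree, flows, NEWTONIAN, dx=2e-3)
        for strip, tau in field.strips:
            seg = post_tree.segment(strip.segment_id)
            q = flows.flow_at(seg.name, strip.axial_position)
            if q > 0:
                expected = poiseuille_tau(q, float(seg.radius_at(strip.axial_position)))
                assert tau == pytest.approx(expected, rel=1e-6)
            else:
                assert tau == 0.0

    def test_tapered_segment_higher_wss_at_smaller_radius(self):
        tree = make_tree(radius_profiles={"PV": [(0.0, 0.007), (1.0, 0.004)]})
        post = apply_splenectomy(tree)
        flows = solve_flows(post, {"SMV": 6e-6, "LGV": 1e-6, "IMV": 2e-6})
        field = compute_wss_field(post, flows, dx=2e-3)
        pv = [(s.axial_position, t) for s, t in field.strips if s.segment_id == "PV"]
        taus = [t for _, t in sorted(pv)]
        assert all(b > a for a, b in zip(taus, taus[1:]))

    def test_stasis_stump_is_zero_everywhere(self, post_tree):
        flows = solve_flows(post_tree, {"SMV": 6e-6, "LGV": 1e-6, "IMV": 2e-6})
        field = compute_wss_field(post_tree, flows, dx=2e-3, stump_model="stasis")
        sv = [t for s, t in field.strips if s.segment_id == "SV"]
        assert sv and all(t == 0.0 for t in sv)

    def test_decay_stump_decreases_away_from_junction(self, post_tree):
        flows = solve_flows(post_tree, {"SMV": 6e-6, "LGV": 1e-6, "IMV": 2e-6})
        field = compute_wss_field(post_tree, flows, dx=2e-3, stump_model="decay")
        sv = sorted(
            (s.axial_position, t) for s, t in field.strips if s.segment_id == "SV"
        )
        taus = [t for _, t in sv]
        assert all(t > 0 for t in taus)
        assert all(b > a for a, b in zip(taus, taus[1:]))  # grows toward the junction
        # penetration length is one stump diameter: decay over the 100 mm
        # stump leaves the tip at a tiny fraction of the junction stress
        assert taus[0] < 1e-2 * taus[-1]


class TestPressures:
    def test_zero_flow_gives_flat_pressure(self, pre_tree):
        flows = solve_flows(pre_tree, {"SMV": 0, "SV": 0, "LGV": 0, "IMV": 0})
        pressures = compute_pressures(pre_tree, flows, outlet_pressure=3000.0)
        assert all(p == pytest.approx(3000.0) for p in pressures.values())

    def test_newtonian_tube_pressure_drop(self):
        """ΔP over the PV equals 2·τ_w·L/R for a constant-radius tube."""
        tree = make_tree(diameters={"PV": 0.010}, lengths={"PV": 0.100})
        post = apply_splenectomy(tree)
        q = {"SMV": 8e-6, "LGV": 1e-6, "IMV": 1e-6}
        flows = solve_flows(post, q)
        pressures = compute_pressures(post, flows, NEWTONIAN, 3333.0, dx=1e-3)
        tau_pv = poiseuille_tau(1e-5, 0.005)
        expected_drop = 2 * tau_pv * 0.100 / 0.005
        got = pressures["C"] - pressures["PV_out"]
        assert got == pytest.approx(expected_drop, rel=1e-9)

    def test_newtonian_drop_linear_in_flow(self, post_tree):
        def drop(scale):
            q = {"SMV": 6e-6 * scale, "LGV": 1e-6 * scale, "IMV": 2e-6 * scale}
            flows = solve_flows(post_tree, q)
            p = compute_pressures(post_tree, flows, NEWTONIAN, 3333.0, dx=2e-3)
            return p["SMV_in"] - p["PV_out"]

        assert drop(2.0) == pytest.approx(2.0 * drop(1.0), rel=1e-9)

    def test_all_pressures_at_or_above_outlet(self, post_tree):
        flows = solve_flows(post_tree, {"SMV": 6e-6, "LGV": 1e-6, "IMV": 2e-6})
        pressures = compute_pressures(post_tree, flows, outlet_pressure=3333.0)
        assert min(pressures.values()) >= 3333.0
        # stump tip sits at the junction pressure (no flow, no drop)
        assert pressures["SV_in"] == pytest.approx(pressures["C"], rel=1e-12)

    def test_default_outlet_is_25_mmhg(self):
        bc = BoundaryConditions(pv_velocity=0.1)
        assert bc.outlet_pressure == pytest.approx(25 * MMHG_TO_PA)
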