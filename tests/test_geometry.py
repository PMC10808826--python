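import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from portalwss.errors import (
    DiscretizationError,
    ParseError,
    StateError,
    ValidationError,
)
from portalwss.geometry import (
    VesselSegment,
    apply_splenectomy,
    build_tree,
    discretize_surface,
    distance_metric,
    read_tree,
    tree_from_dict,
    tree_to_dict,
    write_tree,
)

from conftest import DIAMETERS, LENGTHS, make_tree


class TestBuildTree:
    @pytest.mark.parametrize(
        "anatomy_type,lgv_host,imv_host",
        [(1, "SV", "SV"), (2, "PV", "SV"), (3, "SV", "SMV")],
    )
    def test_anatomy_attachment_rules(self, anatomy_type, lgv_host, imv_host):
        """The three anatomical variants wire LGV/IMV to their defined hosts."""
        tree = make_tree(anatomy_type=anatomy_type)
        assert tree.host_of("LGV") == lgv_host
        assert tree.host_of("IMV") == imv_host

    def test_type2_imv_and_type3_lgv_stay_on_sv(self):
        t2 = make_tree(anatomy_type=2)
        # LGV joins the PV at a genuine mid-course junction
        host, pos = t2.attachments[t2.segment("LGV").distal_node]
        assert host == "PV" and 0 < pos < 1
        t3 = make_tree(anatomy_type=3)
        host, pos = t3.attachments[t3.segment("IMV").distal_node]
        assert host == "SMV" and 0 < pos < 1

    def test_five_segments_four_inlets_one_outlet(self):
        for atype in (1, 2, 3):
            tree = make_tree(anatomy_type=atype)
            assert len(tree.segments) == 5
            assert len(tree.inlets()) == 4
            assert tree.segment("PV").distal_node == tree.outlet_node

    @pytest.mark.parametrize(
        "bad",
        [
            {"diameters": {"SV": -0.01}},
            {"diameters": {"PV": 0.0}},
            {"lengths": {"IMV": -1.0}},
        ],
    )
    def test_nonpositive_dimension_rejected(self, bad):
        with pytest.raises(ValidationError):
            make_tree(anatomy_type=1, **bad)

    def test_unknown_anatomy_type_rejected(self):
        with pytest.raises(ValidationError):
            make_tree(anatomy_type=4)

    @given(
        atype=st.sampled_from([1, 2, 3]),
        d_sv=st.floats(0.007, 0.020),
        l_sv=st.floats(0.05, 0.18),
        tort=st.floats(1.0, 2.0),
    )
    def test_invariants_hold_over_parameter_space(self, atype, d_sv, l_sv, tort):
        tree = make_tree(
            anatomy_type=atype,
            diameters={"SV": d_sv},
            lengths={"SV": l_sv},
            tortuosities={"SV": tort},
        )
        assert tree.state == "preoperative"
        assert {s.name for s in tree.inlets()} == {"SMV", "SV", "LGV", "IMV"}


class TestSplenectomy:
    def test_postoperative_inlets(self, pre_tree):
        post = apply_splenectomy(pre_tree)
        assert post.state == "postoperative"
        assert post.segment("SV").role == "stump"
        assert {s.name for s in post.inlets()} == {"SMV", "LGV", "IMV"}

    def test_geometry_untouched(self, pre_tree):
        post = apply_splenectomy(pre_tree)
        for name in ("PV", "SMV", "SV", "LGV", "IMV"):
            a, b = pre_tree.segment(name), post.segment(name)
            assert a.radius_profile == b.radius_profile
            assert a.length == b.length
            assert a.tortuosity == b.tortuosity
        assert dict(pre_tree.attachments) == dict(post.attachments)

    def test_double_splenectomy_is_an_error(self, post_tree):
        with pytest.raises(StateError):
            apply_splenectomy(post_tree)


class TestDiscretization:
    def test_cylinder_lateral_area(self):
        """Constant radius 5 mm over 100 mm: strips must sum to 2πRL."""
        tree = make_tree(diameters={"SV": 0.010}, lengths={"SV": 0.100})
        strips = [s for s in discretize_surface(tree, 1.0e-3) if s.segment_id == "SV"]
        total = sum(s.area for s in strips)
        assert total == pytest.approx(2 * math.pi * 0.005 * 0.100, rel=1e-3)

    def test_linear_taper_mean_radius_area(self):
        """R: 6→4 mm over 100 mm gives the mean-radius (frustum) area."""
        tree = make_tree(radius_profiles={"SV": [(0.0, 0.006), (1.0, 0.004)]})
        sv_len = LENGTHS["SV"]
        strips = [s for s in discretize_surface(tree, 1.0e-3) if s.segment_id == "SV"]
        assert sum(s.area for s in strips) == pytest.approx(
            2 * math.pi * 0.005 * sv_len, rel=1e-3
        )

    def test_refinement_consistency(self, pre_tree):
        a1 = sum(s.area for s in discretize_surface(pre_tree, 1.0e-3))
        a2 = sum(s.area for s in discretize_surface(pre_tree, 0.5e-3))
        assert abs(a1 - a2) / a2 < 1e-3

    def test_all_segments_covered(self, pre_tree):
        strips = discretize_surface(pre_tree, 1.0e-3)
        for seg in pre_tree.segments:
            mine = [s for s in strips if s.segment_id == seg.id]
            assert sum(s.area for s in mine) == pytest.approx(
                seg.lateral_area(), rel=1e-3
            )

    def test_dx_larger_than_shortest_segment_rejected(self, pre_tree):
        with pytest.raises(DiscretizationError):
            discretize_surface(pre_tree, 0.05)  # LGV is only 40 mm long


class TestDistanceMetric:
    @pytest.mark.parametrize(
        "length,tort,expected",
        [(0.120, 1.5, 0.080), (0.123, 1.0, 0.123), (0.100, 2.0, 0.050)],
    )
    def test_straight_line_distance(self, length, tort, expected):
        seg = VesselSegment(
            id="SV",
            name="SV",
            proximal_node="a",
            distal_node="b",
            length=length,
            radius_profile=((0.0, 0.005), (1.0, 0.005)),
            tortuosity=tort,
            role="inlet",
        )
        assert distance_metric(seg) == pytest.approx(expected)


class TestSerialization:
    @pytest.mark.parametrize("atype", [1, 2, 3])
    def test_round_trip_identity(self, tmp_path, atype):
        tree = make_tree(anatomy_type=atype)
        path = tmp_path / "tree.json"
        write_tree(path, tree)
        assert read_tree(path) == tree

    def test_postoperative_round_trip_preserves_stump(self, tmp_path, post_tree):
        path = tmp_path / "post.json"
        write_tree(path, post_tree)
        back = read_tree(path)
        assert back.segment("SV").role == "stump"
        assert back == post_tree

    def test_missing_field_named_in_error(self, pre_tree):
        data = tree_to_dict(pre_tree)
        del data["anatomy_type"]
        with pytest.raises(ParseError, match="anatomy_type"):
            tree_from_dict(data)

    def test_bad_segment_field_reports_path(self, pre_tree):
        data = tree_to_dict(pre_tree)
        del data["segments"][0]["length_m"]
        with pytest.raises(ParseError, match=r"segments\[0\]"):
            tree_from_dict(data)
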