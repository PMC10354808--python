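"""Geometry construction, the soma-compensation formula, spine neck
resistance, and SWC round-tripping."""

import math

import numpy as np
import pytest

from dendroplast import morphology as mo
from dendroplast.solver import discretize


class TestBallAndStick:
    def test_default_discretization(self):
        m = mo.build_ball_and_stick()
        dend = m.section("b0")
        assert dend.nseg == 50
        assert dend.length / dend.nseg == pytest.approx(4.0)
        assert m.soma.nseg == 1  # isopotential soma

    def test_single_cylinder_degenerate(self):
        m = mo.build_ball_and_stick(nseg=1)
        assert m.section("b0").nseg == 1

    def test_zero_length_rejected(self):
        with pytest.raises(mo.InvalidGeometryError):
            mo.build_ball_and_stick(dend_len=0.0)


class TestSymmetricTree:
    @pytest.mark.parametrize("order,n_sections,tip_um", [
        (0, 1, 50.0), (2, 7, 150.0), (3, 15, 200.0)])
    def test_section_count_and_tip_distance(self, order, n_sections, tip_um):
        m = mo.build_symmetric_tree(order=order)
        assert len(m.sections) == n_sections == 2 ** (order + 1) - 1
        tips = [s for s in m.sections if len(s.name) == 2 + order]
        assert len(tips) == 2 ** order
        for tip in tips:
            assert m.section_path_distance(tip.name, 1.0) == pytest.approx(tip_um)

    def test_negative_order_rejected(self):
        with pytest.raises(mo.InvalidGeometryError):
            mo.build_symmetric_tree(order=-1)

    def test_tree_invariant_one_root(self):
        m = mo.build_symmetric_tree(order=3)
        roots = [s for s in m.all_sections if s.parent is None]
        assert roots == [m.soma]
        # |sections| parent links, all resolving inside the tree
        assert all(s.parent is not None for s in m.sections)

    def test_cycle_detection(self):
        a = mo.SectionSpec("a", 10, 1, parent="b")
        b = mo.SectionSpec("b", 10, 1, parent="a")
        soma = mo.SectionSpec("soma", 23, 718)
        with pytest.raises(mo.InvalidGeometryError):
            mo.Morphology(soma=soma, sections=[a, b])


class TestSomaCompensation:
    def test_reference_input_resistance(self):
        # RN = Rm / (pi d L), evaluated independently: 57.8 MOhm
        assert mo.soma_input_resistance(718, 23, 30) == pytest.approx(57.8, abs=0.05)

    def test_round_trip(self):
        rn = mo.soma_input_resistance(718, 23, 30)
        assert mo.compensated_soma_diameter(rn, 30, 23) == pytest.approx(718)

    def test_linearity_in_rm(self):
        d1 = mo.compensated_soma_diameter(50.0, 30, 23)
        d2 = mo.compensated_soma_diameter(50.0, 60, 23)
        assert d2 == pytest.approx(2 * d1)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(mo.InvalidGeometryError):
            mo.compensated_soma_diameter(0.0, 30, 23)


class TestSpineNeck:
    def test_closed_form_at_printed_diameter(self):
        # the printed 0.07 um diameter gives ~257 MOhm, not the printed
        # 226.6 MOhm -- the printed diameter is the fitted one rounded
        g = mo.SpineGeometry(neck_diameter=0.07)
        r = mo.spine_neck_resistance(g, 150.0)
        expected = 4 * 150 * 0.66e-4 / (math.pi * (0.07e-4) ** 2) / 1e6
        assert r == pytest.approx(expected)
        assert r == pytest.approx(257.3, abs=0.5)

    def test_default_geometry_hits_fitted_resistance(self):
        assert mo.spine_neck_resistance(mo.SpineGeometry()) == pytest.approx(226.6)

    def test_inverse_fit_rounds_to_printed_value(self):
        d = mo.fit_neck_diameter(226.6, 0.66, 150.0)
        assert d == pytest.approx(0.0746, abs=5e-4)
        assert round(d, 2) == 0.07

    def test_zero_length_neck(self):
        g = mo.SpineGeometry(neck_length=1e-12)
        assert mo.spine_neck_resistance(g) == pytest.approx(0.0, abs=1e-6)


class TestSpines:
    def test_head_membrane_area_equals_sphere(self):
        g = mo.SpineGeometry(head_diameter=0.4)
        assert g.head_area == pytest.approx(math.pi * 0.16)  # ~0.503 um^2

    def test_attach_adds_two_compartments_each(self):
        m = mo.build_ball_and_stick()
        base = discretize(m).n_comp
        for i in range(3):
            m = mo.attach_spine(m, mo.SpineSite("b0", 0.25 + 0.2 * i))
        assert discretize(m).n_comp == base + 6

    def test_path_distance_midpoint(self):
        m = mo.build_ball_and_stick()
        m = mo.attach_spine(m, mo.SpineSite("b0", 0.5))
        assert m.spines[0].path_distance == pytest.approx(100.0)

    def test_position_outside_unit_interval_rejected(self):
        with pytest.raises(mo.InvalidGeometryError):
            mo.SpineSite("b0", 1.5)


class TestPathDistance:
    def test_soma_is_origin(self):
        m = mo.build_symmetric_tree()
        assert m.section_path_distance("soma") == 0.0

    def test_tip_of_order3(self):
        m = mo.build_symmetric_tree()
        site = mo.SpineSite("b0LLL", 1.0)
        assert mo.path_distance(m, site) == pytest.approx(200.0)

    def test_midpoint_of_second_order_branch(self):
        m = mo.build_symmetric_tree()
        assert mo.path_distance(m, mo.SpineSite("b0LR", 0.5)) == pytest.approx(125.0)

    def test_unknown_section(self):
        m = mo.build_ball_and_stick()
        with pytest.raises(KeyError):
            mo.path_distance(m, mo.SpineSite("b9", 0.5))


def test_area_conserved_under_refinement():
    coarse = mo.build_ball_and_stick(nseg=10)
    fine = mo.build_ball_and_stick(nseg=200)
    a, b = coarse.total_area(), fine.total_area()
    assert abs(a - b) / a < 1e-9
    # and the discretized graphs agree with the morphology-level sum
    assert discretize(fine).total_area() == pytest.approx(b, rel=1e-9)


class TestSWC:
    def test_round_trip_preserves_tree(self):
        m = mo.build_symmetric_tree()
        m = mo.attach_spine(m, mo.SpineSite("b0LL", 0.5, has_synapse=True))
        text = mo.to_swc(m)
        back = mo.from_swc(text)
        assert len(back.sections) == 15
        for sec in m.sections:
            assert back.section_path_distance(sec.name, 1.0) == pytest.approx(
                m.section_path_distance(sec.name, 1.0), abs=1e-3)
        assert len(back.spines) == 1
        assert back.spines[0].path_distance == pytest.approx(125.0, abs=1e-3)

    def test_idempotent(self):
        m = mo.build_ball_and_stick()
        once = mo.to_swc(mo.from_swc(mo.to_swc(m)))
        assert once == mo.to_swc(m)

    def test_minimum_node_count(self):
        text = mo.to_swc(mo.build_ball_and_stick())
        samples = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert len(samples) >= 2  # soma + dendrite

    def test_malformed_line_reports_number(self):
        bad = "1 1 0 0 0 5 -1\n2 3 oops\n"
        with pytest.raises(mo.SWCParseError) as exc:
            mo.from_swc(bad)
        assert exc.value.line_number == 2
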