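"""Guide solids: closedness, slots, screw holes, seating, preview."""
import numpy as np
import pytest

from osteoguide import guides, planning, solids
from osteoguide.errors import ConstructionError, GeometryError, PlacementError
from osteoguide.planning import CuttingPlane, GuideSpec


class TestFibulaGuide:
    def test_watertight_and_positive(self, fibula_guide):
        assert fibula_guide.is_watertight
        assert fibula_guide.volume > 0

    def test_four_slots_for_two_grafts(self, fibula_guide):
        assert guides.count_open_slots(fibula_guide) == 4

    def test_two_slots_for_one_graft(self, fibula_guide_1):
        assert guides.count_open_slots(fibula_guide_1) == 2

    def test_slot_width_exact(self, fibula_guide, plan2):
        expected = plan2.guide_spec.slot_width(plan2.kerf)
        for p in plan2.fibula_planes:
            width = guides.measure_slot_width(fibula_guide, p.index)
            assert width == pytest.approx(expected, abs=1e-3)

    def test_does_not_penetrate_bone(self, fibula_guide, plan2):
        vol = guides.guide_bone_intersection_volume(fibula_guide, plan2.fibula, pitch=1.2)
        assert vol <= 1e-3

    def test_min_wall_thickness(self, fibula_guide):
        assert guides.min_wall_thickness_fraction(fibula_guide) >= 0.95

    def test_guide_smaller_than_unslotted_shell(self, plan2, fibula_guide):
        spec = plan2.guide_spec
        ctx = fibula_guide.metadata["sweep_context"]
        span = ctx.grid.s[-1] - ctx.grid.s[0]
        arc = ctx.theta_max * 2
        r_mid = float(np.median(ctx.grid.r)) + spec.seat_clearance + spec.wall_thickness / 2
        shell_estimate = span * arc * r_mid * spec.wall_thickness
        assert 0 < fibula_guide.volume < shell_estimate

    def test_slot_missing_shell_is_construction_error(self, plan2):
        import copy

        plan = copy.copy(plan2)
        plan.fibula_planes = list(plan2.fibula_planes) + [
            CuttingPlane(origin=(0, 300.0, 0), normal=(0, 1, 0), blade_thickness=1.0,
                         role="fibula-osteotomy", index=99)
        ]
        with pytest.raises((ConstructionError, GeometryError)):
            guides.build_fibula_guide(plan)


class TestMandibleGuide:
    def test_watertight_with_two_slots(self, mandible_guide):
        assert mandible_guide.is_watertight
        assert guides.count_open_slots(mandible_guide) == 2

    def test_slot_width_exact(self, mandible_guide, plan2):
        expected = plan2.guide_spec.slot_width(plan2.kerf)
        for p in plan2.resection_planes:
            width = guides.measure_slot_width(mandible_guide, p.index)
            assert width == pytest.approx(expected, abs=1e-3)

    def test_does_not_penetrate_bone(self, mandible_guide, plan2):
        vol = guides.guide_bone_intersection_volume(mandible_guide, plan2.mandible, pitch=1.2)
        assert vol <= 1e-3


class TestScrewHoles:
    def test_default_clearance_in_band(self, fibula_guide, plan2):
        spec = plan2.guide_spec
        for k in range(2):
            d = guides.measure_hole_diameter(fibula_guide, k)
            clearance = d - spec.screw_diameter
            assert 0.1 <= clearance <= 0.2 + 1e-6
            assert d == pytest.approx(spec.screw_diameter + spec.screw_clearance, abs=0.02)

    def test_no_positions_is_bit_identical_noop(self, fibula_guide, plan2):
        out = guides.add_screw_holes(fibula_guide, plan2.fibula, plan2.guide_spec, positions=[])
        assert np.array_equal(out.vertices, fibula_guide.vertices)
        assert np.array_equal(out.faces, fibula_guide.faces)

    def test_hole_through_slot_rejected(self, fibula_guide, plan2):
        ctx = fibula_guide.metadata["sweep_context"]
        slot_station = float(plan2.fibula_planes[0].origin[1])
        with pytest.raises(PlacementError):
            guides.add_screw_holes(
                fibula_guide, plan2.fibula, plan2.guide_spec,
                positions=[(slot_station, 0.0)],
            )

    def test_extra_hole_drilled(self, fibula_guide, plan2):
        ctx = fibula_guide.metadata["sweep_context"]
        station = float(ctx.grid.s[0]) + 2.5
        out = guides.add_screw_holes(
            fibula_guide, plan2.fibula, plan2.guide_spec,
            positions=[(station, np.degrees(0.9))],
        )
        assert out.is_watertight
        new_ctx = out.metadata["sweep_context"]
        assert len(new_ctx.holes) == len(ctx.holes) + 1
        d = guides.measure_hole_diameter(out, len(new_ctx.holes) - 1)
        assert d == pytest.approx(plan2.guide_spec.hole_diameter, abs=0.02)

    def test_nonstandard_clearance_needs_flag(self):
        with pytest.raises(Exception):
            GuideSpec(screw_clearance=0.5)
        spec = GuideSpec(screw_clearance=0.5, allow_nonstandard_screw_clearance=True)
        assert spec.hole_diameter == pytest.approx(2.5)


class TestNeomandiblePreview:
    def test_piece_count_one_graft(self, plan1):
        pieces = guides.cut_neomandible_preview(plan1)
        assert len(pieces) == 3  # two mandible remnants + one graft

    def test_pieces_watertight(self, plan2):
        pieces = guides.cut_neomandible_preview(plan2)
        assert len(pieces) == 4
        for p in pieces:
            assert p.is_watertight

    def test_mating_faces_parallel(self, plan2):
        """Terminal graft end faces mate flush with the resection planes."""
        for gi, res in ((0, plan2.resection_planes[0]), (plan2.n_grafts - 1, plan2.resection_planes[1])):
            g = plan2.grafts[gi]
            end = 0 if gi == 0 else 1
            n_mand = g.pose_in_mandible.apply_vector(g.end_normals_local[end])
            cross = np.linalg.norm(np.cross(n_mand, res.normal))
            assert cross < 1e-6

    def test_assembly_pieces_disjoint(self, plan2):
        pieces = guides.cut_neomandible_preview(plan2)
        for i in range(len(pieces)):
            for j in range(i + 1, len(pieces)):
                vol = solids.intersection_volume_sampled(pieces[i], pieces[j], pitch=1.0)
                assert vol <= 1e-3
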