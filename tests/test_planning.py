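"""Plan arithmetic: graft initialisation, kerf compensation, packing."""
import copy
import json

import numpy as np
import pytest

from osteoguide import fixtures, planning
from osteoguide.errors import (
    CapacityError,
    GeometryError,
    ParameterError,
    PlanConflictError,
)
from osteoguide.frames import RigidTransform
from osteoguide.planning import CuttingPlane


def square_plan(norm_mandible, norm_fibula, n_grafts, kerf, chord=40.0):
    """Plan with untilted resection planes a fixed chord apart."""
    o0 = np.array([-chord / 2, 60.0, 14.0])
    o1 = np.array([chord / 2, 60.0, 14.0])
    planes = (
        CuttingPlane(origin=o0, normal=(1, 0, 0), role="mandible-resection"),
        CuttingPlane(origin=o1, normal=(-1, 0, 0), role="mandible-resection", index=1),
    )
    return planning.init_plan(
        norm_mandible, norm_fibula, n_grafts=n_grafts, kerf=kerf,
        resection_planes=planes,
    )


class TestPlaneCounts:
    def test_one_graft_two_osteotomies(self, plan1):
        assert len(plan1.fibula_planes) == 2

    def test_two_grafts_four_osteotomies(self, plan2):
        assert len(plan2.fibula_planes) == 4

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_plane_count_is_twice_graft_count(self, norm_mandible, norm_fibula, n):
        plan = square_plan(norm_mandible, norm_fibula, n, kerf=1.0, chord=80.0)
        assert len(plan.fibula_planes) == 2 * n

    def test_zero_grafts_rejected(self, norm_mandible, norm_fibula):
        with pytest.raises(ParameterError):
            planning.init_plan(norm_mandible, norm_fibula, n_grafts=0, kerf=1.0)


class TestGraftInitialisation:
    def test_chord_subdivision_single(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=1.0, chord=40.0)
        assert plan.grafts[0].length == pytest.approx(40.0)
        centre = plan.grafts[0].pose_in_mandible.translation
        assert np.allclose(centre, [0.0, 60.0, 14.0], atol=1e-9)

    def test_chord_subdivision_two_equal(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 2, kerf=1.0, chord=40.0)
        assert [g.length for g in plan.grafts] == pytest.approx([20.0, 20.0])
        # graft axes collinear with the chord at initialisation
        for g in plan.grafts:
            axis_mand = g.pose_in_mandible.apply_vector([0.0, 1.0, 0.0])
            assert abs(abs(axis_mand @ np.array([1.0, 0, 0])) - 1) < 1e-9

    def test_coincident_resection_origins_rejected(self, norm_mandible, norm_fibula):
        o = np.array([0.0, 60.0, 14.0])
        planes = (
            CuttingPlane(origin=o, normal=(1, 0, 0), role="mandible-resection"),
            CuttingPlane(origin=o, normal=(-1, 0, 0), role="mandible-resection", index=1),
        )
        with pytest.raises(GeometryError):
            planning.init_plan(norm_mandible, norm_fibula, 1, 1.0, resection_planes=planes)


class TestKerfCompensation:
    def test_blade_centre_separation_single_graft(self, norm_mandible, norm_fibula):
        # designed 40 mm + 2 x kerf/2 outward offsets -> 41 mm
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=1.0)
        s = [p.origin[1] for p in plan.fibula_planes]
        assert max(s) - min(s) == pytest.approx(41.0, abs=1e-9)

    def test_zero_kerf_planes_on_end_faces(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=0.0)
        s = [p.origin[1] for p in plan.fibula_planes]
        assert max(s) - min(s) == pytest.approx(40.0, abs=1e-9)

    def test_two_graft_packing(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 2, kerf=1.0)
        s = sorted(p.origin[1] for p in plan.fibula_planes)
        assert s[1] - s[0] == pytest.approx(21.0)  # 20 + kerf
        assert s[3] - s[2] == pytest.approx(21.0)
        assert s[2] - s[1] >= 1.0  # blade-centre separation >= kerf

    def test_kerf_monotonicity(self, norm_mandible, norm_fibula):
        spans = []
        for kerf in (0.0, 0.5, 1.0, 1.5):
            plan = square_plan(norm_mandible, norm_fibula, 2, kerf=kerf)
            s = [p.origin[1] for p in plan.fibula_planes]
            spans.append(max(s) - min(s))
        assert all(b > a for a, b in zip(spans, spans[1:]))

    def test_kerf_conservation_on_cut_cylinder(self, norm_mandible, norm_fibula):
        """Oracle: cut the bone with the derived blade-centre planes; every
        surviving segment's axial extent equals its designed length."""
        from osteoguide import solids

        plan = square_plan(norm_mandible, norm_fibula, 2, kerf=1.0)
        for g in plan.grafts:
            seg = plan.fibula
            for e in (0, 1):
                seg = solids.plane_cut(seg, plan.fibula_planes[2 * g.index + e],
                                       keep="negative")
            extent = seg.bounds[1][1] - seg.bounds[0][1]
            assert extent == pytest.approx(g.length, abs=1e-3)


class TestPoseUpdates:
    def test_identity_update_is_noop(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 2, kerf=1.0)
        before = [(p.origin.copy(), p.normal.copy()) for p in plan.fibula_planes]
        planning.set_graft_pose(plan, 0, plan.grafts[0].pose_in_mandible)
        for (o0, n0), p in zip(before, plan.fibula_planes):
            assert np.abs(p.origin - o0).max() < 1e-9
            assert np.abs(p.normal - n0).max() < 1e-9

    def test_end_face_tilt_propagates(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=1.0)
        tilt = RigidTransform.from_axis_angle([0, 0, 1], np.deg2rad(10.0))
        planning.set_graft_end_face(plan, 0, 1, tilt.apply_vector([0.0, 1.0, 0.0]))
        n = plan.fibula_planes[1].normal
        angle = np.degrees(np.arccos(np.clip(n @ np.array([0, 1.0, 0]), -1, 1)))
        assert angle == pytest.approx(10.0, abs=1e-6)

    def test_angle_between_end_planes_frame_invariant(self, plan2):
        for g in plan2.grafts:
            n_local = g.end_normals_local
            local_angle = np.arccos(np.clip(n_local[0] @ n_local[1], -1, 1))
            n_mand = g.pose_in_mandible.apply_vector(n_local)
            mand_angle = np.arccos(np.clip(n_mand[0] @ n_mand[1], -1, 1))
            p0 = plan2.fibula_planes[2 * g.index].normal
            p1 = plan2.fibula_planes[2 * g.index + 1].normal
            fib_angle = np.arccos(np.clip(p0 @ p1, -1, 1))
            assert mand_angle == pytest.approx(local_angle, abs=1e-9)
            assert fib_angle == pytest.approx(local_angle, abs=1e-6)

    def test_overlapping_pinned_stations_conflict(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 2, kerf=1.0)
        s0 = plan.grafts[0].pose_in_fibula.translation[1] - plan.grafts[0].length / 2
        plan.grafts[0].pinned_station = s0
        with pytest.raises(PlanConflictError, match="0 and 1|1 and 0"):
            planning.set_graft_station(plan, 1, s0 + 5.0)

    def test_capacity_error(self, norm_mandible, norm_fibula):
        with pytest.raises(CapacityError):
            square_plan(norm_mandible, norm_fibula, 4, kerf=1.0, chord=1000.0)


class TestPerforator:
    def test_default_offset_90mm(self, plan1):
        marker = plan1.perforator
        assert marker.axial_position == pytest.approx(90.0)
        v = plan1.fibula.vertices.view(np.ndarray)
        assert marker.world_point[1] == pytest.approx(v[:, 1].min() + 90.0, abs=1e-9)

    def test_marker_inside_graft_no_warning(self, plan1):
        assert not any("perforator" in w for w in plan1.warnings)

    def test_marker_outside_graft_warns(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=1.0)
        v = plan.fibula.vertices.view(np.ndarray)
        ymin = v[:, 1].min()
        planning.set_graft_station(plan, 0, ymin + 150.0)  # interval [150, 190]
        assert any("perforator" in w for w in plan.warnings)

    def test_offset_outside_bone_rejected(self, plan1):
        with pytest.raises(ParameterError):
            planning.place_perforator_marker(plan1, axial_offset=400.0)


class TestSummary:
    def test_square_cut_angles_and_harvest(self, norm_mandible, norm_fibula):
        plan = square_plan(norm_mandible, norm_fibula, 1, kerf=1.0)
        rep = planning.plan_summary(plan)
        assert rep["grafts"][0]["end_face_angles_deg"] == pytest.approx([90.0, 90.0])
        assert rep["total_harvest_length_mm"] == pytest.approx(41.0)
        assert rep["warnings"] == []

    def test_stations_strictly_increasing(self, plan2):
        s = planning.plan_summary(plan2)["fibula_plane_stations_mm"]
        assert all(b > a for a, b in zip(s, s[1:]))

    def test_summary_deterministic(self, norm_mandible, norm_fibula):
        a = planning.plan_summary(square_plan(norm_mandible, norm_fibula, 2, 1.0))
        b = planning.plan_summary(square_plan(norm_mandible, norm_fibula, 2, 1.0))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestSerialisation:
    def test_roundtrip(self, plan2, tmp_path):
        path = tmp_path / "plan.json"
        planning.save_plan(plan2, path)
        again = planning.load_plan(path, mandible=plan2.mandible, fibula=plan2.fibula)
        a = planning.plan_summary(plan2)
        b = planning.plan_summary(again)
        for ka, kb in zip(a["fibula_plane_stations_mm"], b["fibula_plane_stations_mm"]):
            assert kb == pytest.approx(ka, abs=1e-6)
        assert a["n_grafts"] == b["n_grafts"]
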