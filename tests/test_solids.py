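"""Boolean kernel contract: volume identities, watertightness, plane cuts."""
import numpy as np
import pytest
import trimesh

from osteoguide import solids
from osteoguide.errors import GeometryError, ParameterError
from osteoguide.planning import CuttingPlane


def random_solid(rng):
    if rng.random() < 0.5:
        m = solids.make_cylinder(rng.uniform(3, 8), rng.uniform(10, 30), sections=32)
    else:
        m = solids.make_box(rng.uniform(5, 20, 3))
    M = trimesh.transformations.random_rotation_matrix(rng.random(3))
    M[:3, 3] = rng.uniform(-5, 5, 3)
    m.apply_transform(M)
    return m


class TestBooleanExamples:
    def test_disjoint_difference_unchanged(self):
        a = solids.make_box((10, 10, 10))
        b = solids.make_box((10, 10, 10))
        b.apply_translation([30, 0, 0])
        assert solids.boolean(a, b, "difference").volume == pytest.approx(1000.0)

    def test_corner_nested_difference(self):
        # 5 mm cube nested in a corner of a 10 mm cube: 1000 - 125 = 875
        a = solids.make_box((10, 10, 10))
        b = solids.make_box((5, 5, 5))
        b.apply_translation([2.5, 2.5, 2.5])
        out = solids.boolean(a, b, "difference")
        assert out.volume == pytest.approx(875.0, rel=1e-9)
        assert out.is_watertight

    def test_self_intersection_idempotent(self):
        a = solids.make_cylinder(5.0, 20.0)
        out = solids.boolean(a, a.copy(), "intersection")
        assert out.volume == pytest.approx(a.volume, rel=1e-6)

    def test_disjoint_intersection_is_explicit_empty(self):
        a = solids.make_box((10, 10, 10))
        b = solids.make_box((10, 10, 10))
        b.apply_translation([30, 0, 0])
        out = solids.boolean(a, b, "intersection")
        assert len(out.faces) == 0

    def test_piercing_slab_subtraction(self):
        cyl = solids.make_cylinder(8.0, 100.0)
        slab = solids.make_box((40.0, 40.0, 1.0))
        out = solids.boolean(cyl, slab, "difference")
        assert out.is_watertight
        removed = cyl.volume - out.volume
        assert removed == pytest.approx(cyl.volume / 100.0, rel=1e-6)

    def test_non_watertight_operand_rejected(self):
        a = solids.make_box((10, 10, 10))
        holed = trimesh.Trimesh(a.vertices.copy(), a.faces[1:].copy(), process=False)
        with pytest.raises(GeometryError, match="watertight"):
            solids.boolean(holed, a, "union")


class TestBooleanIdentities:
    def test_volume_identities_50_random_pairs(self, rng):
        """vol(A-B) + vol(A&B) = vol(A) and inclusion-exclusion for the
        union, to 1e-6 relative, with watertight outputs throughout."""
        for _ in range(50):
            a, b = random_solid(rng), random_solid(rng)
            d = solids.boolean(a, b, "difference")
            x = solids.boolean(a, b, "intersection")
            u = solids.boolean(a, b, "union")
            xv = x.volume if len(x.faces) else 0.0
            assert abs(d.volume + xv - a.volume) < 1e-6 * a.volume
            assert abs(u.volume - (a.volume + b.volume - xv)) < 1e-6 * a.volume
            for m in (d, x, u):
                assert len(m.faces) == 0 or m.is_watertight


class TestPlaneCut:
    def test_mid_cut_halves_cylinder(self):
        cyl = solids.make_cylinder(8.0, 100.0)
        plane = CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1))
        pos, neg = solids.plane_cut(cyl, plane, keep="both")
        assert pos.volume == pytest.approx(cyl.volume / 2, rel=1e-9)
        assert neg.volume == pytest.approx(cyl.volume / 2, rel=1e-9)
        assert pos.is_watertight and neg.is_watertight

    def test_zero_kerf_conserves_volume(self, rng):
        cyl = solids.make_cylinder(6.0, 60.0)
        plane = CuttingPlane(origin=(0.7, -0.3, 4.2), normal=rng.standard_normal(3))
        pos, neg = solids.plane_cut(cyl, plane, keep="both")
        assert pos.volume + neg.volume == pytest.approx(cyl.volume, rel=1e-6)

    def test_kerf_removes_analytic_slab(self):
        cyl = solids.make_cylinder(8.0, 100.0)
        plane = CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1), blade_thickness=1.0)
        pos, neg = solids.plane_cut(cyl, plane, keep="both")
        # each piece has axial extent 49.5; deficit equals one kerf disc
        assert pos.bounds[1][2] - pos.bounds[0][2] == pytest.approx(49.5, abs=1e-9)
        assert neg.bounds[1][2] - neg.bounds[0][2] == pytest.approx(49.5, abs=1e-9)
        deficit = cyl.volume - pos.volume - neg.volume
        disc = cyl.volume / 100.0  # tessellated section area x 1 mm
        assert deficit == pytest.approx(disc, rel=1e-2)

    def test_plane_missing_mesh(self):
        cyl = solids.make_cylinder(8.0, 100.0)
        plane = CuttingPlane(origin=(0, 0, 200), normal=(0, 0, 1))
        pos, neg = solids.plane_cut(cyl, plane, keep="both")
        assert len(pos.faces) == 0
        assert neg.volume == pytest.approx(cyl.volume, rel=1e-12)


class TestPrimitives:
    def test_box_volume(self):
        assert solids.make_box((10, 10, 10)).volume == pytest.approx(1000.0)

    def test_cylinder_volume_tessellation(self):
        cyl = solids.make_cylinder(1.1, 20.0)
        assert cyl.volume == pytest.approx(np.pi * 1.1**2 * 20.0, rel=5e-3)

    def test_posed_volume_invariant(self, rng):
        from osteoguide.frames import RigidTransform

        M = trimesh.transformations.random_rotation_matrix(rng.random(3))
        pose = RigidTransform(M[:3, :3], rng.uniform(-20, 20, 3))
        assert solids.make_box((3, 4, 5), pose).volume == pytest.approx(60.0, rel=1e-9)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ParameterError):
            solids.make_box((0, 1, 1))
        with pytest.raises(ParameterError):
            solids.make_cylinder(-1.0, 5.0)
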