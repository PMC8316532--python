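"""Rigid transforms and anatomical-frame normalisation."""
import numpy as np
import pytest
import trimesh

from osteoguide import fixtures, frames
from osteoguide.errors import GeometryError
from osteoguide.frames import RigidTransform


def random_transform(rng):
    M = trimesh.transformations.random_rotation_matrix(rng.random(3))
    return RigidTransform(M[:3, :3], rng.uniform(-40, 40, 3))


class TestRigidTransform:
    def test_compose_inverse_closure(self, rng):
        for _ in range(50):
            a, b = random_transform(rng), random_transform(rng)
            c = a.compose(b)
            assert np.abs(c.rotation.T @ c.rotation - np.eye(3)).max() < 1e-9
            ident = c.compose(c.inverse())
            assert ident.is_identity(1e-9)

    def test_apply_matches_matrix(self, rng):
        t = random_transform(rng)
        pts = rng.uniform(-10, 10, (20, 3))
        hom = np.column_stack([pts, np.ones(20)])
        assert np.allclose(t.apply(pts), (hom @ t.matrix.T)[:, :3], atol=1e-10)

    def test_reflection_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rigid_preserves_volume_and_distances(self, rng):
        mesh = fixtures.synthetic_fibula(length=120.0, ring_spacing=8.0)
        t = random_transform(rng)
        moved = mesh.copy()
        moved.apply_transform(t.matrix)
        assert moved.volume == pytest.approx(mesh.volume, rel=1e-9)
        idx = rng.integers(0, len(mesh.vertices), (30, 2))
        d0 = np.linalg.norm(mesh.vertices[idx[:, 0]] - mesh.vertices[idx[:, 1]], axis=1)
        d1 = np.linalg.norm(moved.vertices[idx[:, 0]] - moved.vertices[idx[:, 1]], axis=1)
        assert np.abs(d0 - d1).max() < 1e-9 * max(1.0, d0.max())


class TestPrincipalAxis:
    def test_cylinder_long_axis(self):
        cyl = trimesh.creation.cylinder(radius=8.0, height=100.0, sections=48)
        cyl.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0]))
        axis = frames.principal_axis(cyl)
        assert np.abs(np.abs(axis) - [0, 1, 0]).max() < 1e-6

    def test_rotated_cylinder(self):
        cyl = trimesh.creation.cylinder(radius=8.0, height=100.0, sections=48)
        cyl.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0]))
        R = trimesh.transformations.rotation_matrix(np.deg2rad(30), [1, 0, 0])
        rotated = cyl.copy()
        rotated.apply_transform(R)
        expected = R[:3, :3] @ np.array([0.0, 1.0, 0.0])
        got = frames.principal_axis(rotated)
        assert min(np.abs(got - expected).max(), np.abs(got + expected).max()) < 1e-6

    def test_sphere_does_not_crash(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        axis = frames.principal_axis(sphere)
        assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-9)


class TestNormalizeFibula:
    def test_identity_on_convention_pose(self, fibula):
        _, xf = frames.normalize_fibula(fibula)
        assert np.abs(xf.rotation - np.eye(3)).max() < 1e-6

    def test_idempotent(self, fibula):
        once, _ = frames.normalize_fibula(fibula)
        _, xf = frames.normalize_fibula(once)
        assert xf.is_identity(1e-6)

    def test_translation_recovered(self, fibula):
        shifted = fibula.copy()
        shifted.vertices = shifted.vertices + [50.0, 0.0, 0.0]
        _, xf = frames.normalize_fibula(shifted)
        assert xf.translation[0] == pytest.approx(-50.0, abs=1e-6)

    def test_distal_end_at_negative_y(self, norm_fibula):
        v = norm_fibula.vertices.view(np.ndarray)
        lo = v[v[:, 1] < v[:, 1].min() + 20]
        hi = v[v[:, 1] > v[:, 1].max() - 20]
        r = lambda p: np.hypot(p[:, 0], p[:, 2] - p[:, 2].mean()).mean()
        assert r(lo) < r(hi)

    def test_rotation_recovery_100_seeded(self, fibula, rng):
        base, base_xf = frames.normalize_fibula(fibula)
        worst = 0.0
        for _ in range(100):
            M = trimesh.transformations.random_rotation_matrix(rng.random(3))
            M[:3, 3] = rng.uniform(-30, 30, 3)
            moved = fibula.copy()
            moved.apply_transform(M)
            _, xf = frames.normalize_fibula(moved)
            comp = xf.compose(RigidTransform(M[:3, :3], M[:3, 3])).compose(base_xf.inverse())
            worst = max(worst, np.abs(comp.matrix - np.eye(4)).max())
        assert worst < 1e-5


class TestNormalizeMandible:
    def test_identity_on_convention_pose(self, mandible_with_defect):
        _, xf = frames.normalize_mandible(mandible_with_defect[0])
        assert xf.is_identity(1e-6)

    def test_flip_about_z_recovered(self, mandible_with_defect):
        F = np.diag([-1.0, -1.0, 1.0])
        flipped = mandible_with_defect[0].copy()
        flipped.vertices = flipped.vertices @ F.T
        _, xf = frames.normalize_mandible(flipped)
        assert np.abs(xf.rotation - F).max() < 1e-6

    def test_floor_alignment(self, mandible_with_defect):
        raised = mandible_with_defect[0].copy()
        raised.vertices = raised.vertices + [0.0, 0.0, 10.0]
        out, xf = frames.normalize_mandible(raised)
        assert xf.translation[2] == pytest.approx(-10.0, abs=1e-3)
        assert out.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-6)
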