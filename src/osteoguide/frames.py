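"""Coordinate conventions and rigid-transform arithmetic.

The pipeline works in two normalised anatomical frames:

* **fibula frame** — long axis along +y, centroid at the origin, distal end
  (the smaller cross-section) at negative y. Roll about the long axis is
  deliberately left free: the clinically meaningful roll (which side faces
  posteriorly) is the user's call via the graft control transforms.
* **mandible frame** — inferior border resting on the x-y plane (lowest
  z = 0), symmetry plane at x = 0, anterior arch pointing to +y.

Normalisation replaces the manual orient-and-check step of interactive
workflows with a PCA alignment; callers that trust their segmentation pose
can skip it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R @ x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_axis_angle(cls, axis, angle_rad, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=np.float64))

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=np.float64) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def is_identity(self, tol=1e-9) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() < tol
            and np.abs(self.translation).max() < tol
        )


def _vertex_pca(mesh):
    v = mesh.vertices.view(np.ndarray)
    if len(v) < 3:
        raise GeometryError("mesh has fewer than 3 vertices")
    centroid = v.mean(axis=0)
    cov = np.cov((v - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return centroid, evals[::-1], evecs[:, ::-1]  # descending


def _canonical_sign(vec):
    """Flip an eigenvector so y >= 0 (ties: z >= 0, then x >= 0)."""
    # components below ~1e-3 are treated as ties: on near-axis-aligned
    # meshes they are surface noise, not anatomy, and must not decide signs
    for k in (1, 2, 0):
        if vec[k] > 1e-3:
            return vec
        if vec[k] < -1e-3:
            return -vec
    return vec


def principal_axis(mesh) -> np.ndarray:
    """Unit eigenvector of the vertex covariance with the largest eigenvalue.

    Degenerate (collinear) vertex sets raise; isotropic meshes (a sphere)
    return an arbitrary but deterministic unit vector.
    """
    centroid, evals, evecs = _vertex_pca(mesh)
    if evals[1] < 1e-12 * max(evals[0], 1.0):
        raise GeometryError("vertex set is collinear; principal axis undefined")
    return _canonical_sign(evecs[:, 0])


def _pca_rotation(evecs, order):
    """Build a proper rotation whose rows are the chosen (sign-fixed) axes."""
    rows = [_canonical_sign(evecs[:, k]) for k in order]
    R = np.vstack(rows)
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    return R


def _finish(mesh, v, xf):
    out = type(mesh)(v, mesh.faces.copy(), process=False)
    out.metadata.update(mesh.metadata)
    return out, xf


def normalize_fibula(mesh, distal_end: str = "auto"):
    """Return (normalised mesh, transform original -> normalised).

    Long axis to +y, vertex centroid to the origin, distal end (smaller mean
    cross-section over the terminal 10 % of length) to negative y. The roll
    about the long axis is fixed intrinsically by the bone's bow (the bow
    apex faces +z), which makes the normalisation equivariant under rigid
    motions of the input; a straight tube has no defined roll (documented
    degeneracy). ``distal_end`` may force 'neg_y'/'pos_y' when the
    cross-section heuristic misleads (e.g. a retained malleolus).
    """
    centroid, evals, evecs = _vertex_pca(mesh)
    if evals[1] < 1e-12 * max(evals[0], 1.0):
        raise GeometryError("degenerate fibula principal axis")
    v0 = mesh.vertices.view(np.ndarray) - centroid
    yhat = evecs[:, 0]
    s = v0 @ yhat
    span = s.max() - s.min()
    lo = v0[s < s.min() + 0.1 * span]
    hi = v0[s > s.max() - 0.1 * span]

    def cross_r2(pts):
        rel = pts - pts.mean(axis=0)
        rad = rel - np.outer(rel @ yhat, yhat)
        return float(np.mean(np.einsum("ij,ij->i", rad, rad)))

    if distal_end == "auto":
        flip = cross_r2(hi) < cross_r2(lo)  # smaller end currently at +s
    elif distal_end in ("neg_y", "pos_y"):
        flip = distal_end == "pos_y"
    else:
        raise GeometryError(f"unknown distal_end {distal_end!r}")
    if flip:
        yhat = -yhat
        s = -s
    # roll: the bow displaces mid-shaft cross-section centres off the
    # end-to-end chord; +z points from the chord toward the bow apex.
    smid = (s.max() + s.min()) / 2
    mid_sel = np.abs(s - smid) < 0.2 * span
    end_sel = np.abs(s - smid) > 0.35 * span
    m = [
        float(np.mean((v0 @ evecs[:, k])[mid_sel]) - np.mean((v0 @ evecs[:, k])[end_sel]))
        for k in (1, 2)
    ]
    k_bow = 1 if abs(m[0]) >= abs(m[1]) else 2
    zhat = evecs[:, k_bow] * (np.sign(m[k_bow - 1]) or 1.0)
    zhat = zhat - (zhat @ yhat) * yhat
    zhat = zhat / np.linalg.norm(zhat)
    xhat = np.cross(yhat, zhat)
    R = np.vstack([xhat, yhat, zhat])
    xf = RigidTransform(R, -R @ centroid)
    return _finish(mesh, xf.apply(mesh.vertices.view(np.ndarray)), xf)


def normalize_mandible(mesh):
    """Return (normalised mesh, transform original -> normalised).

    Flattest principal direction to z (signed so the body widens towards
    the alveolar side, +z), the fore-aft asymmetric horizontal direction to
    y (arch apex to +y), x completing the right-handed frame; then the
    inferior surface is dropped onto z = 0. All sign choices are intrinsic
    third moments, so the normalisation is equivariant under rigid motions.
    """
    centroid, evals, evecs = _vertex_pca(mesh)
    if evals[1] < 1e-12 * max(evals[0], 1.0):
        raise GeometryError("degenerate mandible principal axes")
    v0 = mesh.vertices.view(np.ndarray) - centroid
    # of the two widest axes, the anterior-posterior one carries the arch's
    # fore/aft asymmetry (third moment); left-right is symmetric.
    skew = [float(np.mean((v0 @ evecs[:, k]) ** 3)) for k in (0, 1)]
    ky = 0 if abs(skew[0]) > abs(skew[1]) else 1
    # the arch apex is the thin single end: mass (hence the skew tail) sits
    # posteriorly, so +y points against the skew
    yhat = evecs[:, ky] * (-np.sign(skew[ky]) if skew[ky] != 0 else 1.0)
    zvec = evecs[:, 2]
    mz = float(np.mean(np.einsum("ij,ij->i", v0, v0) * (v0 @ zvec)))
    zhat = zvec * (np.sign(mz) if mz != 0 else 1.0)
    xhat = np.cross(yhat, zhat)
    R = np.vstack([xhat, yhat, zhat])
    xf = RigidTransform(R, -R @ centroid)
    v = xf.apply(mesh.vertices.view(np.ndarray))
    lift = -v[:, 2].min()
    xf = RigidTransform(np.eye(3), [0, 0, lift]).compose(xf)
    v = v + [0, 0, lift]
    return _finish(mesh, v, xf)
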