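"""Boolean solid modelling: primitives, plane cuts and mesh Booleans.

This is the computational substrate the guide generation runs on. The
contract is watertight-in / watertight-out with the usual volume
identities (vol(A-B) + vol(A&B) = vol(A), inclusion-exclusion for the
union). The kernel supports the pipeline's structured Boolean domain:
convex operand pairs exactly, and convex "piercing" tools (slabs, boxes
extended through the target) against arbitrary watertight solids.
Subtractions are expected to use tools extended ~0.01 mm beyond every
surface they must pierce so that coplanar-face configurations never arise
by accident.
"""
from __future__ import annotations

import numpy as np
import trimesh

from . import _clip
from ._raycast import contains_points
from .errors import GeometryError, ParameterError

CYLINDER_SECTIONS = 64


def empty_mesh() -> trimesh.Trimesh:
    """The explicit empty solid (e.g. a disjoint intersection)."""
    return trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), process=False)


def _require_watertight(mesh, label):
    if len(mesh.faces) == 0:
        return
    if not mesh.is_watertight:
        raise GeometryError(f"Boolean operand {label!r} is not watertight")
    if mesh.volume < 0:
        raise GeometryError(f"Boolean operand {label!r} is inward-wound (negative volume)")


def _aabb_disjoint(a, b, margin=0.0) -> bool:
    lo_a, hi_a = a.bounds
    lo_b, hi_b = b.bounds
    return bool((hi_a < lo_b - margin).any() or (hi_b < lo_a - margin).any())


def boolean(a: trimesh.Trimesh, b: trimesh.Trimesh, op: str) -> trimesh.Trimesh:
    """Union / difference / intersection of two watertight solids.

    Empty results are returned as an explicit empty mesh, never an error.
    """
    if op not in ("union", "difference", "intersection"):
        raise ParameterError(f"unknown Boolean op {op!r}")
    _require_watertight(a, "a")
    _require_watertight(b, "b")
    if len(a.faces) == 0:
        return b.copy() if op == "union" else empty_mesh()
    if len(b.faces) == 0:
        return empty_mesh() if op == "intersection" else a.copy()
    if _aabb_disjoint(a, b):
        if op == "union":
            return _clip.weld_triangles(
                list(a.vertices.view(np.ndarray)[a.faces])
                + list(b.vertices.view(np.ndarray)[b.faces])
            )
        if op == "difference":
            return a.copy()
        return empty_mesh()
    pa = _clip.convex_planes(a)
    pb = _clip.convex_planes(b)
    if pa is not None and pb is not None:
        return _clip.convex_boolean(a, b, op)
    if pb is not None:
        return _clip.piercing_boolean(a, b, op)
    if pa is not None and op in ("union", "intersection"):
        return _clip.piercing_boolean(b, a, op)
    raise GeometryError(
        "unsupported Boolean operand pair: at least one operand must be convex "
        "(convex tools may pierce arbitrary watertight targets)"
    )


def plane_cut(mesh: trimesh.Trimesh, plane, keep: str = "both"):
    """Cut a watertight mesh with a (possibly kerf-bearing) cutting plane.

    With ``blade_thickness > 0`` the removed region is the slab of that
    width centred on the blade-centre plane. ``keep`` selects the
    'positive' side (along the plane normal), the 'negative' side, or
    'both' (returned as a (positive, negative) tuple).
    """
    _require_watertight(mesh, "mesh")
    n = _clip.unit(plane.normal)
    origin = np.asarray(plane.origin, dtype=np.float64)
    half = plane.blade_thickness / 2.0
    if keep not in ("positive", "negative", "both"):
        raise ParameterError("keep must be positive|negative|both")
    pieces = {}
    if keep in ("positive", "both"):
        pieces["positive"] = _clip.clip_halfspace(mesh, origin + half * n, n, keep="positive")
    if keep in ("negative", "both"):
        pieces["negative"] = _clip.clip_halfspace(mesh, origin - half * n, n, keep="negative")
    if keep == "both":
        return pieces["positive"], pieces["negative"]
    return pieces[keep]


def _posed(mesh, pose):
    if pose is not None:
        mesh.apply_transform(pose.matrix if hasattr(pose, "matrix") else np.asarray(pose))
    return mesh


def make_box(extents, pose=None) -> trimesh.Trimesh:
    extents = np.asarray(extents, dtype=np.float64)
    if (extents <= 0).any():
        raise ParameterError("box extents must be positive")
    box = trimesh.creation.box(extents)
    return _posed(trimesh.Trimesh(box.vertices.copy(), box.faces.copy(), process=False), pose)


def make_cylinder(radius, length, pose=None, sections: int = CYLINDER_SECTIONS) -> trimesh.Trimesh:
    if radius <= 0 or length <= 0:
        raise ParameterError("cylinder dimensions must be positive")
    cyl = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    return _posed(trimesh.Trimesh(cyl.vertices.copy(), cyl.faces.copy(), process=False), pose)


def intersection_volume_sampled(a, b, *, pitch: float = 1.0, seed: int = 0) -> float:
    """Deterministic sampled estimate of vol(A & B) in mm^3.

    Samples a jittered grid over the overlap of the two bounding boxes and
    counts points contained in both solids. Used for validation checks whose
    expected value is zero (e.g. guide/bone penetration); an estimate of 0.0
    means no sample penetrated both solids.
    """
    lo = np.maximum(a.bounds[0], b.bounds[0])
    hi = np.minimum(a.bounds[1], b.bounds[1])
    if (hi <= lo).any():
        return 0.0
    rng = np.random.default_rng(seed)
    # cap the sample count so large overlap boxes stay tractable
    vol_box = float(np.prod(hi - lo))
    pitch = max(pitch, (vol_box / 12000.0) ** (1.0 / 3.0))
    axes = [np.arange(lo[k] + pitch / 2, hi[k], pitch) for k in range(3)]
    if any(len(ax) == 0 for ax in axes):
        axes = [np.linspace(lo[k], hi[k], 4) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.uniform(-pitch / 4, pitch / 4, pts.shape)
    inside = contains_points(a, pts)
    if inside.any():
        inside[inside] = contains_points(b, pts[inside])
    cell = np.prod(np.clip(hi - lo, 0, None)) / len(pts)
    return float(inside.sum() * cell)
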