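"""Printable cutting-guide solids and the virtual-surgery preview.

Both guides follow the same recipe: a partial-ring shell swept along the
bone (inner surface ``seat_clearance`` off the bone, ``wall_thickness``
thick, wrapping ``flange_height`` of arc past the bone's equator), with
one through-slot per cutting plane (width = kerf + ``slot_clearance``,
centred on the blade-centre plane) and clearance-fitted screw holes. The
fibular guide spans all 2 x n_grafts osteotomy planes; the mandibular
guide spans the two resection planes.
"""
from __future__ import annotations

import numpy as np
import trimesh

from . import _sweep, solids
from ._raycast import contains_points, first_hit_distance
from .errors import GeometryError, ParameterError
from .frames import RigidTransform
from .planning import GraftPlan, GuideSpec

__all__ = [
    "GuideSpec",
    "build_fibula_guide",
    "build_mandible_guide",
    "add_screw_holes",
    "cut_neomandible_preview",
    "measure_slot_width",
    "measure_hole_diameter",
    "count_open_slots",
    "guide_bone_intersection_volume",
    "min_wall_thickness_fraction",
]

_DS = 2.0  # station sampling (mm) along the sweep


def _theta_max(spec: GuideSpec, r_out: float) -> float:
    """Wrap angle: past the equator by the flange arc, capped at 135 deg."""
    return float(min(np.pi / 2 + spec.flange_height / max(r_out, 1.0), np.deg2rad(135)))


def _fibula_grid(fibula, spec, s_lo, s_hi, n_theta=49):
    s = np.arange(s_lo, s_hi + _DS / 2, _DS)
    v = fibula.vertices.view(np.ndarray)
    C = np.empty((len(s), 3))
    for i, y in enumerate(s):
        near = v[np.abs(v[:, 1] - y) < 4.0]
        if len(near) < 3:
            raise GeometryError("guide span extends beyond the fibula")
        C[i] = [near[:, 0].mean(), y, near[:, 2].mean()]
    axis = np.tile([0.0, 1.0, 0.0], (len(s), 1))
    up = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    grid = _sweep.SweepGrid(s=s, C=C, axis=axis, up=up)
    r_est = float(np.median(np.hypot(v[:, 0], v[:, 2] - v[:, 2].mean())))
    th_max = _theta_max(spec, r_est + spec.seat_clearance + spec.wall_thickness)
    _sweep.probe_radius(fibula, grid, np.linspace(-th_max, th_max, n_theta))
    return grid


def _mandible_arch(mandible, n=181):
    """Polar sampling of the arch centreline about the vertical axis through
    the occlusal-plane centroid; returns (beta, centres, arc_length)."""
    v = mandible.vertices.view(np.ndarray)
    pivot = np.array([0.0, v[:, 1].mean(), 0.0])
    beta = np.arctan2(v[:, 0] - pivot[0], v[:, 1] - pivot[1])
    bgrid = np.linspace(beta.min() + 0.02, beta.max() - 0.02, n)
    width = (bgrid[1] - bgrid[0]) * 1.5
    C = np.empty((n, 3))
    for i, b in enumerate(bgrid):
        sel = np.abs(beta - b) < width
        if sel.sum() < 3:
            sel = np.argsort(np.abs(beta - b))[:24]
        C[i] = v[sel].mean(axis=0)
    # light smoothing to stabilise tangents on coarse meshes
    for k in range(3):
        C[1:-1, k] = (C[:-2, k] + 2 * C[1:-1, k] + C[2:, k]) / 4
    seg = np.linalg.norm(np.diff(C, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return bgrid, C, s


def _mandible_grid(mandible, spec, planes, n_theta=97):
    # the mandibular body cross-section is coarsely faceted; dense angular
    # probing keeps the bilinear radius interpolation's convexity
    # undershoot well below the seat clearance
    beta, C_all, s_all = _mandible_arch(mandible)
    # stations of the resection planes along the arch, padded by the reach
    # of tilted slots across the body cross-section
    stations, reach = [], []
    for p in planes:
        k = int(np.argmin(np.linalg.norm(C_all - p.origin, axis=1)))
        stations.append(s_all[k])
        tang = C_all[min(k + 1, len(C_all) - 1)] - C_all[max(k - 1, 0)]
        tang /= np.linalg.norm(tang)
        r_out = 10.0 + spec.seat_clearance + spec.wall_thickness
        reach.append(_slot_reach(p, tang, r_out, spec))
    lo = min(s - r for s, r in zip(stations, reach)) - spec.end_margin
    hi = max(s + r for s, r in zip(stations, reach)) + spec.end_margin
    if lo < s_all[0] or hi > s_all[-1]:
        raise GeometryError("guide span extends beyond the mandibular arch")
    s = np.arange(lo, hi + _DS / 2, _DS)
    C = np.column_stack([np.interp(s, s_all, C_all[:, k]) for k in range(3)])
    d = np.gradient(C, s, axis=0)
    axis = d / np.linalg.norm(d, axis=1, keepdims=True)
    up = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    up = up - axis * (up * axis).sum(axis=1, keepdims=True)
    up /= np.linalg.norm(up, axis=1, keepdims=True)
    grid = _sweep.SweepGrid(s=s, C=C, axis=axis, up=up)
    r_est = 10.0
    th_max = _theta_max(spec, r_est + spec.seat_clearance + spec.wall_thickness)
    _sweep.probe_radius(mandible, grid, np.linspace(-th_max, th_max, n_theta))
    eff = (min(s - r for s, r in zip(stations, reach)),
           max(s + r for s, r in zip(stations, reach)))
    return grid, eff


def _auto_screws(spec, s_planes, s_lo, s_hi):
    """Default screw placement: one hole in each end flange, on the crest."""
    lo = (s_lo + min(s_planes)) / 2
    hi = (s_hi + max(s_planes)) / 2
    return [(float(lo), 0.0), (float(hi), 0.0)]


def _slot_reach(p, axis, r_out, spec):
    """Station half-extent a (possibly tilted) slot sweeps across the shell."""
    axial = abs(float(p.normal @ axis))
    lateral = float(np.sqrt(max(0.0, 1.0 - axial**2)))
    return r_out * lateral / max(axial, 1e-6) + spec.slot_width(p.blade_thickness) / 2


def build_fibula_guide(plan: GraftPlan) -> trimesh.Trimesh:
    """Watertight fibular guide with one through-slot per osteotomy plane."""
    if not plan.fibula.is_watertight:
        raise GeometryError("fibula mesh is not watertight")
    if not plan.fibula_planes:
        raise ParameterError("plan has no derived fibular planes")
    spec = plan.guide_spec
    v = plan.fibula.vertices.view(np.ndarray)
    r_out = float(np.median(np.hypot(v[:, 0], v[:, 2] - v[:, 2].mean()))) + \
        spec.seat_clearance + spec.wall_thickness
    yhat = np.array([0.0, 1.0, 0.0])
    eff_lo = min(float(p.origin[1]) - _slot_reach(p, yhat, r_out, spec)
                 for p in plan.fibula_planes)
    eff_hi = max(float(p.origin[1]) + _slot_reach(p, yhat, r_out, spec)
                 for p in plan.fibula_planes)
    grid = _fibula_grid(plan.fibula, spec, eff_lo - spec.end_margin,
                        eff_hi + spec.end_margin)
    screws = list(spec.screw_positions_fibula) or _auto_screws(
        spec, [eff_lo, eff_hi], grid.s[0], grid.s[-1]
    )
    mesh, ctx = _sweep.build_swept_guide(plan.fibula, grid, spec, plan.fibula_planes, screws)
    mesh.metadata["name"] = "fibula_guide"
    mesh.metadata["bone"] = plan.fibula
    return mesh


def build_mandible_guide(plan: GraftPlan) -> trimesh.Trimesh:
    """Watertight mandibular guide with one through-slot per resection plane."""
    if not plan.mandible.is_watertight:
        raise GeometryError("mandible mesh is not watertight")
    spec = plan.guide_spec
    grid, eff = _mandible_grid(plan.mandible, spec, plan.resection_planes)
    screws = list(spec.screw_positions_mandible) or _auto_screws(
        spec, list(eff), grid.s[0], grid.s[-1]
    )
    mesh, ctx = _sweep.build_swept_guide(
        plan.mandible, grid, spec, plan.resection_planes, screws
    )
    mesh.metadata["name"] = "mandible_guide"
    mesh.metadata["bone"] = plan.mandible
    return mesh


def add_screw_holes(guide: trimesh.Trimesh, bone, spec: GuideSpec,
                    positions=None) -> trimesh.Trimesh:
    """Drill clearance-fitted screw holes into a guide built by this module.

    Holes are through-cylinders of diameter screw_diameter + screw_clearance
    with axes along the local bone-surface normal, realised by re-running
    the guide's recorded parametric build (the build context travels in the
    mesh metadata); holes that would cross a cutting slot are rejected.
    With no positions requested the guide is returned bit-identical.
    """
    ctx = guide.metadata.get("sweep_context")
    if ctx is None:
        raise GeometryError(
            "guide carries no build context; screw holes can only be drilled "
            "into guides produced by build_fibula_guide/build_mandible_guide"
        )
    positions = list(positions) if positions is not None else []
    if not positions:
        return guide.copy()
    mesh, _ = _sweep.build_swept_guide(bone, ctx.grid, spec, ctx.planes,
                                       list(ctx.screws) + positions)
    mesh.metadata["name"] = guide.metadata.get("name", "guide")
    mesh.metadata["bone"] = bone
    return mesh


def cut_neomandible_preview(plan: GraftPlan) -> list:
    """Virtual surgery: resected mandible remnants plus the fibular grafts
    rigidly re-posed into the mandible frame."""
    # sequential cuts partition the arch: each resection normal faces into
    # the defect, so the 'negative' side is the remnant to keep
    p0, p1 = plan.resection_planes
    remnant0 = solids.plane_cut(plan.mandible, p0, keep="negative")
    rest = solids.plane_cut(plan.mandible, p0, keep="positive")
    remnant1 = solids.plane_cut(rest, p1, keep="negative")
    pieces = [remnant0, remnant1]
    for g in plan.grafts:
        seg = plan.fibula
        for e in (0, 1):
            seg = solids.plane_cut(seg, plan.fibula_planes[2 * g.index + e], keep="negative")
        xf = g.pose_in_mandible.compose(g.pose_in_fibula.inverse())
        seg = seg.copy()
        seg.apply_transform(xf.matrix)
        seg.metadata["name"] = f"graft_{g.index}"
        pieces.append(seg)
    return pieces


# ---------------------------------------------------------------------------
# geometric measurement / validation helpers


def _context(guide):
    ctx = guide.metadata.get("sweep_context")
    if ctx is None:
        raise GeometryError("mesh carries no sweep context")
    return ctx


def measure_slot_width(guide, plane_index: int, th: float = 0.35) -> float:
    """Distance between a slot's two walls along the plane normal, measured
    by ray casting from inside the slot void at mid-wall depth."""
    ctx = _context(guide)
    feat = next(s for s in ctx.slots if s.plane_index == plane_index)
    mid_off = ctx.spec.seat_clearance + ctx.spec.wall_thickness / 2
    c_mid = 0.5 * (feat.c_minus + feat.c_plus)
    u0 = _sweep.solve_plane_station(ctx.grid, feat.normal, c_mid, th, mid_off)
    if u0 is None:
        raise GeometryError("slot probe failed")
    p0 = ctx.grid.point(u0, th, mid_off)
    d = feat.normal
    w = first_hit_distance(guide, [p0, p0], [d, -d])
    if np.isinf(w).any():
        raise GeometryError("slot probe ray escaped the guide")
    return float(w.sum())


def measure_hole_diameter(guide, hole_index: int = 0, n_dirs: int = 48) -> float:
    """Maximal inscribed-circle diameter of a screw hole's cross-section at
    mid-wall depth (ray-cast from the hole axis)."""
    ctx = _context(guide)
    feat = next(h for h in ctx.holes if h.hole_index == hole_index)
    centre = feat.centre3 + 0.5 * (feat.rho_in + feat.rho_out) * feat.axis3
    psi = np.linspace(0, 2 * np.pi, n_dirs, endpoint=False)
    dirs = np.cos(psi)[:, None] * feat.e1 + np.sin(psi)[:, None] * feat.e2
    dist = first_hit_distance(guide, np.tile(centre, (n_dirs, 1)), dirs)
    if np.isinf(dist).any():
        raise GeometryError("hole probe ray escaped the guide")
    return float(2.0 * dist.min())


def count_open_slots(guide, planes=None) -> int:
    """Number of cutting planes whose slot is realised as an open channel
    (void on the blade plane, walls present beside it)."""
    ctx = _context(guide)
    planes = planes if planes is not None else ctx.planes
    mid_off = ctx.spec.seat_clearance + ctx.spec.wall_thickness / 2
    n_open = 0
    for p in planes:
        feat = next(s for s in ctx.slots if s.plane_index == p.index)
        c_mid = 0.5 * (feat.c_minus + feat.c_plus)
        ths = np.linspace(-feat.half_wrap * 0.8, feat.half_wrap * 0.8, 7)
        u0 = _sweep.solve_plane_stations(ctx.grid, p.normal, c_mid, ths, mid_off)
        ok = ~np.isnan(u0)
        if not ok.any():
            continue
        void_pts = ctx.grid.points_v(u0[ok], ths[ok], mid_off)
        # probe the slot walls just beyond the void, but short of any
        # neighbouring slot (inter-slot material can be ~1 kerf wide)
        w = ctx.spec.slot_width(p.blade_thickness)
        wall_pts = np.vstack([void_pts + p.normal * (w / 2 + 0.35),
                              void_pts - p.normal * (w / 2 + 0.35)])
        in_void = contains_points(guide, void_pts)
        in_wall = contains_points(guide, wall_pts)
        if not in_void.any() and in_wall.mean() > 0.5:
            n_open += 1
    return n_open


def guide_bone_intersection_volume(guide, bone=None, pitch=0.8, seed=0) -> float:
    """Sampled intersection volume (mm^3) between a guide and the undilated
    bone; 0.0 when no sample penetrates both."""
    bone = bone if bone is not None else guide.metadata.get("bone")
    if bone is None:
        raise ParameterError("bone mesh required")
    return solids.intersection_volume_sampled(guide, bone, pitch=pitch, seed=seed)


def min_wall_thickness_fraction(guide, threshold_factor=0.8, n_samples=400, seed=0) -> float:
    """Fraction of sampled seat-surface points whose local radial thickness
    reaches ``threshold_factor * wall_thickness``."""
    ctx = _context(guide)
    rng = np.random.default_rng(seed)
    spec = ctx.spec
    grid = ctx.grid
    u = rng.uniform(grid.s[0] + 1, grid.s[-1] - 1, n_samples)
    th = rng.uniform(grid.theta[0] + 0.05, grid.theta[-1] - 0.05, n_samples)
    origins = _sweep_points(grid, u, th, spec.seat_clearance + 0.05)
    dirs = _sweep_points(grid, u, th, spec.seat_clearance + 1.05) - origins
    dist = first_hit_distance(guide, origins, dirs)
    finite = np.isfinite(dist)  # rays escaping through slots/holes are legitimately thin
    if not finite.any():
        return 0.0
    good = dist[finite] >= threshold_factor * spec.wall_thickness - 0.05
    return float(good.mean())


def _sweep_points(grid, u, th, offset):
    return grid.points_v(np.asarray(u), np.asarray(th), offset)
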