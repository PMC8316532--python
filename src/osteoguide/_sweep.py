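"""Conforming swept-shell construction of cutting-guide solids.

A guide is a partial ring of ``wall_thickness`` swept along the bone: its
inner surface sits ``seat_clearance`` off the bone surface (probed by ray
casting from the sweep centreline), its outer surface one wall further out.
The sweep lives on a 2D parameter domain (u = station along the bone,
theta = angle around the cross-section, 0 = the 'up' direction). Cutting
slots and screw holes are trimmed out of that domain as 2D regions
(shapely), the trimmed domain is meshed cell-by-cell with constrained
Delaunay triangles, and every 2D vertex is lifted twice (inner/outer
sheet); boundary edges grow wall quads. The construction is therefore
watertight by connectivity, while tagged boundary vertices are lifted onto
the *exact* feature geometry: slot walls onto the kerf-offset planes
(slot width is exact), hole rims onto the true screw cylinder (hole
diameter is exact).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box as shp_box

from ._clip import triangulate_region
from ._raycast import first_hit_distance
from .errors import ConstructionError, GeometryError, PlacementError

_KEY_DECIMALS = 7


def _unit_rows(a):
    return a / np.linalg.norm(a, axis=-1, keepdims=True)


@dataclass
class SweepGrid:
    """Discrete sweep frames plus the probed bone-surface radius field."""

    s: np.ndarray  # (n,) arc-length stations
    C: np.ndarray  # (n,3) centreline points
    axis: np.ndarray  # (n,3) sweep tangents
    up: np.ndarray  # (n,3) theta=0 directions (unit, perp to axis)
    theta: np.ndarray = field(default=None)  # (m,) angles
    r: np.ndarray = field(default=None)  # (n,m) bone radius from centreline

    @property
    def side(self):
        return _unit_rows(np.cross(self.axis, self.up))

    # -- interpolation helpers -------------------------------------------
    def _interp_rows(self, arr, u):
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(u, self.s, arr[:, k])
        return out

    def frame(self, u):
        c = self._interp_rows(self.C, u)
        ax = self._interp_rows(self.axis, u)
        ax /= np.linalg.norm(ax)
        up = self._interp_rows(self.up, u)
        up -= (up @ ax) * ax
        up /= np.linalg.norm(up)
        return c, ax, up

    def dir(self, u, th):
        c, ax, up = self.frame(u)
        side = np.cross(ax, up)
        return c, ax, np.cos(th) * up + np.sin(th) * side

    def radius(self, u, th):
        """Bilinear interpolation of the probed radius field."""
        i = np.clip(np.searchsorted(self.s, u) - 1, 0, len(self.s) - 2)
        j = np.clip(np.searchsorted(self.theta, th) - 1, 0, len(self.theta) - 2)
        fu = (u - self.s[i]) / (self.s[i + 1] - self.s[i])
        ft = (th - self.theta[j]) / (self.theta[j + 1] - self.theta[j])
        fu, ft = np.clip(fu, 0, 1), np.clip(ft, 0, 1)
        return (
            self.r[i, j] * (1 - fu) * (1 - ft)
            + self.r[i + 1, j] * fu * (1 - ft)
            + self.r[i, j + 1] * (1 - fu) * ft
            + self.r[i + 1, j + 1] * fu * ft
        )

    def point(self, u, th, radial_offset):
        c, _, d = self.dir(u, th)
        return c + (self.radius(u, th) + radial_offset) * d

    # vectorised variants (u, th arrays of equal shape)
    def frames_v(self, u):
        u = np.asarray(u, dtype=np.float64)
        C = np.column_stack([np.interp(u, self.s, self.C[:, k]) for k in range(3)])
        ax = np.column_stack([np.interp(u, self.s, self.axis[:, k]) for k in range(3)])
        ax = _unit_rows(ax)
        up = np.column_stack([np.interp(u, self.s, self.up[:, k]) for k in range(3)])
        up = up - ax * np.einsum("ij,ij->i", up, ax)[:, None]
        up = _unit_rows(up)
        return C, ax, up

    def radius_v(self, u, th):
        u = np.asarray(u, dtype=np.float64)
        th = np.asarray(th, dtype=np.float64)
        i = np.clip(np.searchsorted(self.s, u) - 1, 0, len(self.s) - 2)
        j = np.clip(np.searchsorted(self.theta, th) - 1, 0, len(self.theta) - 2)
        fu = np.clip((u - self.s[i]) / (self.s[i + 1] - self.s[i]), 0, 1)
        ft = np.clip((th - self.theta[j]) / (self.theta[j + 1] - self.theta[j]), 0, 1)
        return (
            self.r[i, j] * (1 - fu) * (1 - ft)
            + self.r[i + 1, j] * fu * (1 - ft)
            + self.r[i, j + 1] * (1 - fu) * ft
            + self.r[i + 1, j + 1] * fu * ft
        )

    def points_v(self, u, th, radial_offset):
        C, ax, up = self.frames_v(u)
        side = _unit_rows(np.cross(ax, up))
        th = np.asarray(th, dtype=np.float64)
        d = np.cos(th)[:, None] * up + np.sin(th)[:, None] * side
        return C + (self.radius_v(u, th) + radial_offset)[:, None] * d


def probe_radius(bone, grid: SweepGrid, theta) -> np.ndarray:
    """Fill grid.r by casting radial rays from the centreline at each
    (station, angle); misses inherit the nearest valid neighbour."""
    n, m = len(grid.s), len(theta)
    side = grid.side
    origins = np.repeat(grid.C, m, axis=0)
    dirs = np.empty((n * m, 3))
    for i in range(n):
        dirs[i * m : (i + 1) * m] = (
            np.cos(theta)[:, None] * grid.up[i] + np.sin(theta)[:, None] * side[i]
        )
    dist = first_hit_distance(bone, origins, dirs).reshape(n, m)
    if np.isinf(dist).all():
        raise GeometryError("sweep centreline lies outside the bone")
    # fill misses column-wise then row-wise
    for j in range(m):
        col = dist[:, j]
        bad = np.isinf(col)
        if bad.all():
            continue
        idx = np.arange(n)
        col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
    for i in range(n):
        row = dist[i]
        bad = np.isinf(row)
        if bad.any():
            idx = np.arange(m)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    grid.theta = np.asarray(theta, dtype=np.float64)
    grid.r = dist
    return dist


# ---------------------------------------------------------------------------
# feature curves in the parameter domain


def solve_plane_stations(grid: SweepGrid, normal, offset, ths, radial_offset, bracket=None):
    """Stations u at which the swept surface (at each angle in ``ths`` and a
    radial offset) crosses the plane n . x = offset; nan where it never does.
    Vectorised bisection after a 33-point bracketing scan."""
    ths = np.asarray(ths, dtype=np.float64)
    lo, hi = bracket if bracket else (grid.s[0], grid.s[-1])
    us = np.linspace(lo, hi, 33)
    m, n = len(ths), len(us)
    U = np.repeat(us, m)
    T = np.tile(ths, n)
    F = (grid.points_v(U, T, radial_offset) @ normal - offset).reshape(n, m)
    sign = np.sign(F)
    cross = sign[:-1] * sign[1:] <= 0
    out = np.full(m, np.nan)
    any_cross = cross.any(axis=0)
    if not any_cross.any():
        return out
    # bracket with the smallest |F| per angle
    absF = np.where(cross, np.minimum(np.abs(F[:-1]), np.abs(F[1:])), np.inf)
    k = np.argmin(absF, axis=0)
    cols = np.nonzero(any_cross)[0]
    a = us[k[cols]]
    b = us[k[cols] + 1]
    fa = F[k[cols], cols]
    for _ in range(40):
        mid = 0.5 * (a + b)
        fm = grid.points_v(mid, ths[cols], radial_offset) @ normal - offset
        left = fa * fm <= 0
        b = np.where(left, mid, b)
        a = np.where(left, a, mid)
        fa = np.where(left, fa, fm)
    out[cols] = 0.5 * (a + b)
    return out


def solve_plane_station(grid: SweepGrid, normal, offset, th, radial_offset, bracket=None):
    """Scalar convenience wrapper around :func:`solve_plane_stations`."""
    u = solve_plane_stations(grid, normal, offset, np.array([th]), radial_offset, bracket)[0]
    return None if np.isnan(u) else float(u)


@dataclass
class SlotFeature:
    plane_index: int
    normal: np.ndarray
    c_minus: float  # plane offsets of the two slot walls
    c_plus: float
    half_wrap: float  # angular half-extent of the slot
    polygon: Polygon = None
    boundary = None

    def wall_offset(self, which):
        return self.c_minus if which == "minus" else self.c_plus


@dataclass
class HoleFeature:
    hole_index: int
    station: float
    angle: float
    radius: float
    r_ref: float  # angle scaling (mm per radian) used for the 2D disc
    centre3: np.ndarray = None
    axis3: np.ndarray = None
    e1: np.ndarray = None
    e2: np.ndarray = None
    rho_in: float = 0.0
    rho_out: float = 0.0
    polygon: Polygon = None
    boundary = None


def slot_polygon(grid, feat: SlotFeature, th_grid, offsets):
    """2D strip removed for a slot: the full parametric shadow of the kerf
    slab, i.e. per theta the min/max of the wall-plane crossings over both
    the inner and outer surface radius. Removing the shadow (rather than a
    single-radius band) keeps tilted-slot boundary vertices stretching only
    into already-removed cells, so the sheets can never fold over
    themselves."""
    ths = th_grid[(th_grid >= -feat.half_wrap - 1e-12) & (th_grid <= feat.half_wrap + 1e-12)]
    crossings = np.stack(
        [
            solve_plane_stations(grid, feat.normal, c, ths, off)
            for c in (feat.c_minus, feat.c_plus)
            for off in offsets
        ]
    )
    ok = (~np.isnan(crossings)).sum(axis=0) >= 2
    if ok.sum() < 2:
        return None
    lo = np.nanmin(crossings[:, ok], axis=0)
    hi = np.nanmax(crossings[:, ok], axis=0)
    tt = ths[ok]
    ring = list(zip(lo, tt)) + list(zip(hi[::-1], tt[::-1]))
    return Polygon(ring)


def hole_polygon(feat: HoleFeature, n_seg=32):
    psi = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    pts = np.column_stack(
        [feat.station + feat.radius * np.cos(psi),
         feat.angle + feat.radius * np.sin(psi) / feat.r_ref]
    )
    return Polygon(pts)


# ---------------------------------------------------------------------------
# the builder


@dataclass
class SweepContext:
    grid: SweepGrid
    spec: object
    planes: list
    slots: list
    holes: list
    theta_max: float
    screws: list


def _cell_mesh(domain, s_lo, s_hi, th_lo, th_hi, du, dth):
    """Triangulate ``domain`` conforming to its boundary: cell-by-cell clip
    plus constrained Delaunay, full cells fast-pathed."""
    us = np.arange(s_lo, s_hi + du * 0.5, du)
    ths = np.arange(th_lo, th_hi + dth * 0.5, dth)
    prep = shapely.prepared.prep(domain)
    tris2 = []
    for i in range(len(us) - 1):
        for j in range(len(ths) - 1):
            cell = shp_box(us[i], ths[j], us[i + 1], ths[j + 1])
            if prep.contains_properly(cell):
                a = (us[i], ths[j])
                b = (us[i + 1], ths[j])
                c = (us[i + 1], ths[j + 1])
                d = (us[i], ths[j + 1])
                tris2.append(np.array([a, b, c]))
                tris2.append(np.array([a, c, d]))
                continue
            if not prep.intersects(cell):
                continue
            piece = domain.intersection(cell)
            for geom in getattr(piece, "geoms", [piece]):
                if geom.is_empty or geom.geom_type != "Polygon" or geom.area <= 1e-14:
                    continue
                shell = np.asarray(geom.exterior.coords)[:-1]
                holes = [np.asarray(r.coords)[:-1] for r in geom.interiors]
                tris2.extend(triangulate_region(shell, holes))
    return tris2


def build_swept_guide(bone, grid: SweepGrid, spec, planes, screws):
    """Assemble the watertight guide solid; returns (mesh, SweepContext)."""
    import trimesh

    seat = spec.seat_clearance
    wall = spec.wall_thickness
    s_lo, s_hi = float(grid.s[0]), float(grid.s[-1])
    theta_max = float(grid.theta[-1])
    mid_offset = seat + wall / 2

    slot_half = min(np.deg2rad(getattr(spec, "slot_wrap_deg", 200.0)) / 2, theta_max - 0.15)
    slots = []
    for p in planes:
        w = spec.slot_width(p.blade_thickness)
        c0 = float(p.origin @ p.normal)
        feat = SlotFeature(
            plane_index=p.index, normal=p.normal, c_minus=c0 - w / 2, c_plus=c0 + w / 2,
            half_wrap=slot_half,
        )
        feat.polygon = slot_polygon(grid, feat, grid.theta, (seat, seat + wall))
        if feat.polygon is None or not feat.polygon.intersects(
            shp_box(s_lo, -theta_max, s_hi, theta_max)
        ):
            raise ConstructionError(
                f"cutting slot for plane {p.index} misses the guide shell"
            )
        feat.boundary = feat.polygon.exterior
        slots.append(feat)

    r_typ = float(np.median(grid.r))
    holes = []
    for k, (sh, ph_deg) in enumerate(screws):
        ph = np.deg2rad(ph_deg)
        if not (s_lo + 1 < sh < s_hi - 1) or not (-theta_max + 0.1 < ph < theta_max - 0.1):
            raise PlacementError(f"screw hole {k} lies off the guide body")
        c3, ax3, d3 = grid.dir(sh, ph)
        e1 = ax3 - (ax3 @ d3) * d3
        e1 /= np.linalg.norm(e1)
        # e2 must point along +theta on the surface (the 2D disc's theta
        # offset maps to it), i.e. along cross(axis, d)
        e2 = np.cross(e1, d3)
        rho_in = float(grid.radius(sh, ph)) + seat
        feat = HoleFeature(
            hole_index=k, station=sh, angle=ph, radius=spec.hole_diameter / 2,
            r_ref=rho_in + wall / 2, centre3=c3, axis3=d3, e1=e1, e2=e2,
            rho_in=rho_in, rho_out=rho_in + wall,
        )
        feat.polygon = hole_polygon(feat)
        feat.boundary = feat.polygon.exterior
        for slot in slots:
            if feat.polygon.distance(slot.polygon) < 0.4:
                raise PlacementError(
                    f"screw hole {k} intersects cutting slot {slot.plane_index}"
                )
        holes.append(feat)

    rect = shp_box(s_lo, -theta_max, s_hi, theta_max)
    domain = rect
    for feat in slots + holes:
        domain = domain.difference(feat.polygon)
    if domain.is_empty:
        raise ConstructionError("slots consumed the entire guide body")

    # --- 2D mesh ---------------------------------------------------------
    # angular resolution adapts to the probed surface's curvature: a chord
    # across dth must sag less than ~0.04 mm (well under seat_clearance),
    # which matters on ridge-like cross-sections (e.g. a mandibular crest)
    du = 2.0
    dth = 2.0 / max(r_typ + mid_offset, 1.0)
    h = grid.theta[1] - grid.theta[0]
    surf = grid.r + mid_offset  # (n, m) radii
    pts_t = (
        grid.C[:, None, :]
        + surf[:, :, None]
        * (np.cos(grid.theta)[None, :, None] * grid.up[:, None, :]
           + np.sin(grid.theta)[None, :, None] * grid.side[:, None, :])
    )
    dd = np.linalg.norm(pts_t[:, 2:] - 2 * pts_t[:, 1:-1] + pts_t[:, :-2], axis=2)
    dd_max = float(dd.max()) if dd.size else 0.0
    if dd_max > 1e-9:
        dth = min(dth, h * np.sqrt(8 * 0.04 / dd_max))
    dth = max(dth, 0.015)
    tris2 = _cell_mesh(domain, s_lo, s_hi, -theta_max, theta_max, du, dth)

    key2id: dict = {}
    coords2: list = []
    tri_ids = []
    for t in tris2:
        ids = []
        for p in t:
            key = (round(p[0], _KEY_DECIMALS), round(p[1], _KEY_DECIMALS))
            idx = key2id.get(key)
            if idx is None:
                idx = len(coords2)
                key2id[key] = idx
                coords2.append((p[0], p[1]))
            ids.append(idx)
        if len(set(ids)) == 3:
            tri_ids.append(ids)
    coords2 = np.asarray(coords2)
    tri_ids = np.asarray(tri_ids, dtype=np.int64)

    # --- vertex tagging and lifting -------------------------------------
    pts = shapely.points(coords2)
    tags = [None] * len(coords2)
    for feat in slots:
        # the two wall curves: split the exterior by theta extremes is
        # fiddly; tag by which wall plane the solved station matches
        dist = shapely.distance(pts, feat.boundary)
        for vi in np.nonzero(dist < 1e-6)[0]:
            if tags[vi] is None:
                tags[vi] = ("slot", feat)
    for feat in holes:
        dist = shapely.distance(pts, feat.boundary)
        for vi in np.nonzero(dist < 1e-6)[0]:
            if tags[vi] is None:
                tags[vi] = ("hole", feat)

    n2 = len(coords2)
    uu, tt = coords2[:, 0], coords2[:, 1]

    def lift_sheet(off):
        pts = grid.points_v(uu, tt, off)
        # slot-tagged vertices: project onto the nearest wall plane exactly
        for feat in slots:
            sel = np.array([t is not None and t[0] == "slot" and t[1] is feat for t in tags])
            if not sel.any():
                continue
            idx = np.nonzero(sel)[0]
            side = np.abs(pts[idx] @ feat.normal - feat.c_minus) <= np.abs(
                pts[idx] @ feat.normal - feat.c_plus
            )
            for which, mask in (("minus", side), ("plus", ~side)):
                sub = idx[mask]
                if not len(sub):
                    continue
                u_ex = solve_plane_stations(
                    grid, feat.normal, feat.wall_offset(which), tt[sub], off
                )
                good = ~np.isnan(u_ex)
                if good.any():
                    pts[sub[good]] = grid.points_v(u_ex[good], tt[sub[good]], off)
        # hole-tagged vertices: exact circle on the screw cylinder
        for feat in holes:
            sel = np.array([t is not None and t[0] == "hole" and t[1] is feat for t in tags])
            if not sel.any():
                continue
            idx = np.nonzero(sel)[0]
            psi = np.arctan2((tt[idx] - feat.angle) * feat.r_ref, uu[idx] - feat.station)
            rho = feat.rho_in if off == seat else feat.rho_out
            pts[idx] = (
                feat.centre3
                + rho * feat.axis3
                + feat.radius * (np.cos(psi)[:, None] * feat.e1 + np.sin(psi)[:, None] * feat.e2)
            )
        return pts

    inner = lift_sheet(seat)
    outer = lift_sheet(seat + wall)

    faces = []
    directed = set()
    for a, b, c in tri_ids:
        faces.append([a, b, c])  # inner sheet, outward normal toward bone
        faces.append([c + n2, b + n2, a + n2])  # outer sheet
        for e in ((a, b), (b, c), (c, a)):
            directed.add(e)
    for a, b in list(directed):
        if (b, a) in directed:
            continue
        faces.append([a, a + n2, b + n2])
        faces.append([a, b + n2, b])
    verts = np.vstack([inner, outer])
    mesh = trimesh.Trimesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    if mesh.volume < 0:
        mesh.invert()
    ctx = SweepContext(
        grid=grid, spec=spec, planes=list(planes), slots=slots, holes=holes,
        theta_max=theta_max, screws=list(screws),
    )
    mesh.metadata["sweep_context"] = ctx
    return mesh, ctx
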