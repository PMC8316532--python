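"""Plane-clipping kernel behind the solid-modelling operations.

The pipeline's Boolean needs are narrow and structured: half-space cuts of
watertight bone meshes (osteotomies), Booleans between convex primitives,
and subtraction of convex "piercing" tools (slabs, boxes) whose edges stay
clear of the target. This kernel implements exactly that domain with
watertight-in/watertight-out guarantees:

* ``clip_halfspace`` — cut a watertight mesh with a plane and cap the
  section (caps triangulated with shapely's constrained Delaunay, which
  introduces no Steiner points, so cap boundaries weld exactly).
* ``convex_boolean`` — union/difference/intersection of two convex solids,
  with explicit handling of coplanar face contact.
* ``piercing_boolean`` — Boolean of a general watertight solid with a
  convex tool whose edges and vertices lie outside the solid (the tool
  pierces fully through); raises when that precondition fails.

Numerical policy: signed distances within ``EPS`` of a plane are snapped to
zero before classification; crossing points on shared mesh edges are
computed once per edge (canonical operand order) so adjacent faces emit
bit-identical coordinates and the final weld is exact.
"""
from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import GeometryError

EPS = 1e-8
WELD_TOL = 1e-6


# ---------------------------------------------------------------------------
# small geometric helpers


def unit(v):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length direction vector")
    return v / n


def plane_basis(normal):
    """Deterministic right-handed in-plane basis (e1, e2) with e1 x e2 = n."""
    n = unit(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    return e1, e2


def _interp(pa, da, pb, db):
    """Edge/plane crossing with canonical operand order for bit-stable output."""
    if pb.tobytes() < pa.tobytes():
        pa, da, pb, db = pb, db, pa, da
    t = da / (da - db)
    return pa + t * (pb - pa)


def _snap(d, eps=EPS):
    d = np.asarray(d, dtype=np.float64).copy()
    d[np.abs(d) < eps] = 0.0
    return d


def split_poly(P, d):
    """Split a planar-ish polygon by a plane given per-vertex snapped distances.

    Returns (negative-side pts, positive-side pts); on-plane vertices appear
    on both sides.
    """
    neg: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    k = len(P)
    for i in range(k):
        j = (i + 1) % k
        di, dj = d[i], d[j]
        if di <= 0:
            neg.append(P[i])
        if di >= 0:
            pos.append(P[i])
        if (di < 0 < dj) or (dj < 0 < di):
            x = _interp(P[i], di, P[j], dj)
            neg.append(x)
            pos.append(x)
    return neg, pos


def _fan(poly):
    return [(poly[0], poly[k], poly[k + 1]) for k in range(1, len(poly) - 1)]


def _tri_normal(tri):
    return np.cross(tri[1] - tri[0], tri[2] - tri[0])


# ---------------------------------------------------------------------------
# cap construction (loop nesting + constrained Delaunay)


def _nest_loops(loops_2d):
    """Group oriented loops into (shell, holes) tuples by containment depth."""
    polys = [Polygon(loop) for loop in loops_2d]
    areas = [p.area for p in polys]
    order = sorted(range(len(polys)), key=lambda i: -areas[i])
    parent = [-1] * len(polys)
    for oi, i in enumerate(order):
        rep = polys[i].representative_point()
        # smallest loop that still contains this one
        for j in reversed(order[:oi]):
            if polys[j].contains(rep):
                parent[i] = j
                break
    depth = [0] * len(polys)
    for i in order:
        depth[i] = 0 if parent[i] < 0 else depth[parent[i]] + 1
    groups = []
    for i in range(len(polys)):
        if depth[i] % 2 == 0:
            holes = [loops_2d[j] for j in range(len(polys)) if parent[j] == i]
            groups.append((loops_2d[i], holes))
    return groups


def triangulate_region(shell, holes=()):
    """Constrained-Delaunay triangles (CCW, no Steiner points) of a polygon."""
    poly = Polygon(shell, [np.asarray(h) for h in holes])
    if poly.area <= 0:
        return []
    tris = []
    for geom in shapely.constrained_delaunay_triangles(poly).geoms:
        c = np.asarray(geom.exterior.coords)[:3]
        e1, e2 = c[1] - c[0], c[2] - c[0]
        if e1[0] * e2[1] - e1[1] * e2[0] < 0:
            c = c[::-1]
        tris.append(c)
    return tris


def triangulate_loops(loops_2d):
    tris = []
    for shell, holes in _nest_loops(loops_2d):
        tris.extend(triangulate_region(shell, holes))
    return tris


def trace_loops(edges):
    """Order directed edges (pairs of hashable vertex keys) into closed loops."""
    succ: dict = {}
    for a, b in edges:
        succ.setdefault(a, []).append(b)
    for v in succ:
        succ[v].sort()
    loops = []
    while succ:
        start = min(succ)
        loop = [start]
        cur = start
        while True:
            nxts = succ.get(cur)
            if not nxts:
                raise GeometryError("open section boundary: cannot close cap loop")
            nxt = nxts.pop(0)
            if not nxts:
                del succ[cur]
            if nxt == start:
                break
            loop.append(nxt)
            cur = nxt
        if len(loop) >= 3:
            loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# half-space clip of a watertight mesh


def clip_halfspace(mesh, plane_origin, plane_normal, keep="negative", cap=True, eps=EPS):
    """Keep the part of a watertight mesh on one side of a plane, capped.

    ``keep='negative'`` keeps points p with n . (p - origin) <= 0.
    Returns a trimesh.Trimesh (possibly empty, possibly the input copied).
    """
    import trimesh

    n = unit(plane_normal)
    if keep == "positive":
        n = -n
    elif keep != "negative":
        raise ValueError("keep must be 'positive' or 'negative'")
    origin = np.asarray(plane_origin, dtype=np.float64)

    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    if len(F) == 0:
        return mesh.copy()
    d = _snap(V @ n - n @ origin, eps)
    dF = d[F]
    keep_all = (dF <= 0).all(axis=1)
    drop_all = (dF >= 0).all(axis=1)
    coplanar = (dF == 0).all(axis=1)
    crossing_any = ~(keep_all | drop_all)
    if not drop_all.any():
        return mesh.copy()
    if not (keep_all & ~coplanar).any() and not crossing_any.any():
        return trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), process=False)

    tri = V[F]
    raw_normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cop_keep = coplanar & (raw_normals @ n > 0)
    simple_keep = (keep_all & ~coplanar) | cop_keep
    crossing_faces = ~(keep_all | drop_all)

    new_pts: list[np.ndarray] = []
    cache: dict[tuple[int, int], int] = {}
    nV = len(V)

    def crossing(ia, ib):
        key = (ia, ib) if ia < ib else (ib, ia)
        idx = cache.get(key)
        if idx is None:
            x = _interp(V[key[0]], d[key[0]], V[key[1]], d[key[1]])
            new_pts.append(x)
            idx = nV + len(new_pts) - 1
            cache[key] = idx
        return idx

    out_faces: list[np.ndarray] = [f for f in F[simple_keep]]
    for f in F[crossing_faces]:
        poly: list[int] = []
        for k in range(3):
            ia, ib = int(f[k]), int(f[(k + 1) % 3])
            da, db = d[ia], d[ib]
            if da <= 0:
                poly.append(ia)
            if (da < 0 < db) or (db < 0 < da):
                poly.append(crossing(ia, ib))
        if len(poly) >= 3:
            for a, b, c in _fan(poly):
                out_faces.append(np.array([a, b, c]))

    allV = np.vstack([V] + [np.asarray(new_pts)]) if new_pts else V.copy()
    faces = np.asarray(out_faces, dtype=np.int64)
    on_plane = np.zeros(len(allV), dtype=bool)
    on_plane[:nV] = d == 0
    on_plane[nV:] = True

    if cap:
        # boundary edges of the kept surface lying on the plane, as directed
        # in the kept faces; the cap traverses them reversed.
        e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        key = np.sort(e, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        boundary = counts[inv] == 1
        bnd = e[boundary & on_plane[e].all(axis=1)]
        if len(bnd):
            loops_idx = trace_loops([(int(b), int(a)) for a, b in bnd])
            e1, e2 = plane_basis(n)
            rel = allV - origin
            p2 = np.column_stack([rel @ e1, rel @ e2])
            coord2idx = {(p2[i, 0], p2[i, 1]): i for loop in loops_idx for i in loop}
            tris2 = triangulate_loops([p2[loop] for loop in loops_idx])
            for t2 in tris2:
                idxs = [coord2idx[(c[0], c[1])] for c in t2]
                faces = np.vstack([faces, idxs])

    used = np.unique(faces)
    remap = np.full(len(allV), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = trimesh.Trimesh(allV[used], remap[faces], process=False)
    return out


# ---------------------------------------------------------------------------
# convex-solid representation


def convex_planes(mesh, eps=1e-6):
    """Deduplicated outward (normal, offset) face planes of a convex solid,
    or None when the mesh is not convex within tolerance."""
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    tri = V[F]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(n, axis=1)
    ok = norms > 1e-12
    n = n[ok] / norms[ok, None]
    off = np.einsum("ij,ij->i", n, tri[ok, 0])
    key = np.round(np.column_stack([n, off]) / 1e-6).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    planes = np.column_stack([n, off])[np.sort(first)]
    scale = max(1.0, float(np.abs(V).max()))
    d = V @ planes[:, :3].T - planes[:, 3]
    if d.max() > 1e-6 * scale:
        return None
    return planes


def clip_face_by_convex(P, planes, eps=EPS):
    """Partition one face polygon against a convex solid's planes.

    Returns (outside_polys, inside_poly_or_None, on_bucket) where on_bucket
    is None or ('same'|'anti', pieces) for a face coplanar with a tool plane.
    """
    P = [np.asarray(p, dtype=np.float64) for p in P]
    N = planes[:, :3]
    # coplanarity with any tool plane?
    fn = _tri_normal(np.asarray(P[:3]))
    for i, pl in enumerate(planes):
        di = _snap(np.asarray(P) @ pl[:3] - pl[3], eps)
        if np.all(di == 0):
            rest = P
            outside: list[list[np.ndarray]] = []
            for j, plj in enumerate(planes):
                if j == i or rest is None or len(rest) < 3:
                    continue
                dj = _snap(np.asarray(rest) @ plj[:3] - plj[3], eps)
                if (dj <= 0).all():
                    continue
                if (dj >= 0).all():
                    outside.append(rest)
                    rest = None
                    break
                negp, posp = split_poly(rest, dj)
                if len(posp) >= 3:
                    outside.append(posp)
                rest = negp if len(negp) >= 3 else None
            sign = "same" if fn @ pl[:3] > 0 else "anti"
            pieces = [rest] if rest is not None and len(rest) >= 3 else []
            return outside, None, (sign, pieces)
    outside = []
    rest = P
    for pl in planes:
        if rest is None or len(rest) < 3:
            rest = None
            break
        dr = _snap(np.asarray(rest) @ pl[:3] - pl[3], eps)
        if (dr <= 0).all():
            continue
        if (dr >= 0).all():
            outside.append(rest)
            rest = None
            break
        negp, posp = split_poly(rest, dr)
        if len(posp) >= 3:
            outside.append(posp)
        rest = negp if len(negp) >= 3 else None
    inside = rest if rest is not None and len(rest) >= 3 else None
    return outside, inside, None


def partition_mesh_by_convex(mesh, planes, eps=EPS):
    """Split every face of ``mesh`` into outside/inside/on-boundary pieces
    relative to a convex solid. Returns dict of triangle-coordinate lists."""
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    D = _snap(V @ planes[:, :3].T - planes[:, 3], eps)
    DF = D[F]  # (nf, 3, np)
    fully_out = (DF > 0).all(axis=1).any(axis=1)
    fully_in = (DF < 0).all(axis=(1, 2))
    res = {"outside": [], "inside": [], "on_same": [], "on_anti": []}
    tri = V[F]
    for t in tri[fully_out]:
        res["outside"].append(t)
    for t in tri[fully_in]:
        res["inside"].append(t)
    rest_idx = np.nonzero(~(fully_out | fully_in))[0]
    for fi in rest_idx:
        P = list(tri[fi])
        outside, inside, on = clip_face_by_convex(P, planes, eps)
        for poly in outside:
            res["outside"].extend(np.asarray(t) for t in _fan(poly))
        if inside is not None:
            res["inside"].extend(np.asarray(t) for t in _fan(inside))
        if on is not None:
            sign, pieces = on
            for poly in pieces:
                res[f"on_{sign}"].extend(np.asarray(t) for t in _fan(poly))
    return res


def weld_triangles(tris, tol=WELD_TOL):
    """Assemble a coordinate-triangle soup into an indexed mesh, merging
    vertices within ``tol`` (union-find over KD-tree pairs)."""
    import trimesh

    if not len(tris):
        return trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), process=False)
    pts = np.asarray([p for t in tris for p in t], dtype=np.float64)
    # exact dedupe first
    _, first, inv = np.unique(pts.round(decimals=9), axis=0, return_index=True, return_inverse=True)
    uniq = pts[first]
    parent = np.arange(len(uniq))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(uniq)
    for i, j in sorted(tree.query_pairs(tol)):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    rep = np.array([find(i) for i in range(len(uniq))])
    reps, newidx = np.unique(rep, return_inverse=True)
    verts = uniq[reps]
    faces = newidx[rep[inv]].reshape(-1, 3)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    mesh = trimesh.Trimesh(verts, faces[ok], process=False)
    if not mesh.is_watertight:
        mesh = repair_tjunctions(mesh, tol)
    return mesh


def repair_tjunctions(mesh, tol=WELD_TOL, max_rounds=12):
    """Split edges at vertices that lie on them (within ``tol``).

    Face clipping against a convex tool cuts along whole planes, so a face
    may gain a vertex on an edge whose neighbouring face was kept intact;
    the resulting T-junction is topological only — geometry is exact — and
    is resolved here by subdividing the intact neighbour.
    """
    import trimesh

    V = mesh.vertices.view(np.ndarray)
    F = [list(f) for f in mesh.faces.view(np.ndarray)]
    if not F:
        return mesh
    tree = cKDTree(V)
    for _ in range(max_rounds):
        faces = np.asarray(F, dtype=np.int64)
        e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        key = np.sort(e, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        bad = uniq[counts != 2]
        if len(bad) == 0:
            break
        # vertices to insert per (sorted) edge key
        inserts: dict[tuple[int, int], list[tuple[float, int]]] = {}
        for a, b in bad:
            pa, pb = V[a], V[b]
            ab = pb - pa
            L2 = ab @ ab
            if L2 < tol * tol:
                continue
            mid = (pa + pb) / 2
            for vi in tree.query_ball_point(mid, np.sqrt(L2) / 2 + tol):
                if vi == a or vi == b:
                    continue
                t = (V[vi] - pa) @ ab / L2
                if t <= 1e-9 or t >= 1 - 1e-9:
                    continue
                if np.linalg.norm(V[vi] - (pa + t * ab)) < tol:
                    inserts.setdefault((int(a), int(b)), []).append((t, vi))
        if not inserts:
            break
        newF: list[list[int]] = []
        for f in F:
            queue = [f]
            for k in range(3):
                a, b = f[k], f[(k + 1) % 3]
                ek = (a, b) if a < b else (b, a)
                ins = inserts.get(ek)
                if not ins:
                    continue
                chain = sorted(set(ins))
                vs = [vi for _, vi in chain] if a < b else [vi for _, vi in reversed(chain)]
                next_queue = []
                for tri_f in queue:
                    # find the (a,b) edge in this sub-face, if still present
                    split = False
                    for kk in range(3):
                        if tri_f[kk] == a and tri_f[(kk + 1) % 3] == b:
                            c = tri_f[(kk + 2) % 3]
                            seq = [a] + vs + [b]
                            for s in range(len(seq) - 1):
                                next_queue.append([seq[s], seq[s + 1], c])
                            split = True
                            break
                    if not split:
                        next_queue.append(tri_f)
                queue = next_queue
            newF.extend(queue)
        F = newF
    faces = np.asarray(F, dtype=np.int64)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return trimesh.Trimesh(V.copy(), faces[ok], process=False)


def _flip(tris):
    return [t[::-1] for t in tris]


def convex_boolean(a, b, op, eps=EPS):
    """Boolean of two convex watertight solids with coplanar-contact rules."""
    pa = convex_planes(a)
    pb = convex_planes(b)
    if pa is None or pb is None:
        raise GeometryError("convex_boolean requires two convex operands")
    A = partition_mesh_by_convex(a, pb, eps)
    B = partition_mesh_by_convex(b, pa, eps)
    if op == "union":
        tris = A["outside"] + A["on_same"] + B["outside"]
    elif op == "intersection":
        tris = A["inside"] + A["on_same"] + B["inside"]
    elif op == "difference":
        tris = A["outside"] + A["on_anti"] + _flip(B["inside"])
    else:
        raise ValueError(f"unknown op {op!r}")
    return weld_triangles(tris)


# ---------------------------------------------------------------------------
# general target, convex piercing tool


def _seam_loops_by_plane(mesh, planes, eps=EPS):
    """Closed loops of the mesh surface's intersection with each tool plane,
    oriented CCW about the plane normal with the solid's section on the left.

    Raises GeometryError when a loop strays onto another tool plane's outside
    (i.e. the tool's edges cut the target — unsupported)."""
    V = mesh.vertices.view(np.ndarray)
    F = mesh.faces.view(np.ndarray)
    tri = V[F]
    raw_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    out = []
    for i, pl in enumerate(planes):
        n_i = pl[:3]
        d = _snap(V @ n_i - pl[3], eps)
        dF = d[F]
        mixed = ~((dF <= 0).all(axis=1) | (dF >= 0).all(axis=1))
        if (dF == 0).all(axis=1).any():
            raise GeometryError("tool face coplanar with target surface (unsupported tangency)")
        segs = []
        cache: dict[tuple[int, int], np.ndarray] = {}

        def crossing(ia, ib):
            key = (ia, ib) if ia < ib else (ib, ia)
            x = cache.get(key)
            if x is None:
                x = _interp(V[key[0]], d[key[0]], V[key[1]], d[key[1]])
                cache[key] = x
            return x

        for fi in np.nonzero(mixed)[0]:
            f = F[fi]
            pts = []
            for k in range(3):
                ia, ib = int(f[k]), int(f[(k + 1) % 3])
                if d[ia] == 0:
                    pts.append(V[ia])
                if (d[ia] < 0 < d[ib]) or (d[ib] < 0 < d[ia]):
                    pts.append(crossing(ia, ib))
            if len(pts) != 2:
                raise GeometryError("degenerate plane/surface crossing (vertex tangency)")
            t = np.cross(n_i, raw_n[fi])
            if (pts[1] - pts[0]) @ t >= 0:
                segs.append((pts[0], pts[1]))
            else:
                segs.append((pts[1], pts[0]))
        if not segs:
            out.append((i, []))
            continue
        # piercing check: the seam must stay inside every *other* tool plane
        allpts = np.asarray([p for s in segs for p in s])
        others = [j for j in range(len(planes)) if j != i]
        if others:
            dj = allpts @ planes[others, :3].T - planes[others, 3]
            if dj.max() > 1e-6:
                raise GeometryError(
                    "tool edges intersect the target surface; the convex tool must "
                    "pierce fully through (enlarge the tool laterally)"
                )
        key = lambda p: (round(p[0], 9), round(p[1], 9), round(p[2], 9))
        k2p = {}
        edges = []
        for p0, p1 in segs:
            k0, k1 = key(p0), key(p1)
            k2p[k0], k2p[k1] = p0, p1
            if k0 != k1:
                edges.append((k0, k1))
        loops = trace_loops(edges)
        out.append((i, [np.asarray([k2p[k] for k in loop]) for loop in loops]))
    return out


def piercing_boolean(a, b, op, eps=EPS):
    """Boolean of a general watertight solid ``a`` with a convex tool ``b``
    that pierces fully through it (tool edges outside ``a``)."""
    planes = convex_planes(b)
    if planes is None:
        raise GeometryError("piercing tool must be convex")
    A = partition_mesh_by_convex(a, planes, eps)
    seams = _seam_loops_by_plane(a, planes, eps)
    patches = []
    for i, loops in seams:
        pl = planes[i]
        e1, e2 = plane_basis(pl[:3])
        origin = pl[:3] * pl[3]
        to2d = lambda p: np.column_stack([(p - origin) @ e1, (p - origin) @ e2])
        loops2 = [to2d(lp) for lp in loops]
        back = {}
        for lp3, lp2 in zip(loops, loops2):
            for p3, p2 in zip(lp3, lp2):
                back[(p2[0], p2[1])] = p3

        def lift(tri2):
            out3 = []
            for c in tri2:
                p3 = back.get((c[0], c[1]))
                if p3 is None:
                    p3 = origin + c[0] * e1 + c[1] * e2
                out3.append(p3)
            return np.asarray(out3)

        if op in ("difference", "intersection"):
            tris2 = triangulate_loops(loops2) if loops2 else []
            tris3 = [lift(t) for t in tris2]
            patches.extend(_flip(tris3) if op == "difference" else tris3)
        elif op == "union":
            # tool face region outside the target: face outline minus seam regions
            face_tris = [t for t in b.vertices.view(np.ndarray)[b.faces.view(np.ndarray)]
                         if abs(_tri_normal(t) @ pl[:3] / (np.linalg.norm(_tri_normal(t)) + 1e-300) - 1) < 1e-6]
            outline = shapely.union_all([Polygon(to2d(t)) for t in face_tris])
            region = outline.difference(shapely.union_all([Polygon(lp) for lp in loops2]))
            for geom in getattr(region, "geoms", [region]):
                if geom.is_empty or geom.area <= 0:
                    continue
                shell = np.asarray(geom.exterior.coords)[:-1]
                holes = [np.asarray(r.coords)[:-1] for r in geom.interiors]
                for t2 in triangulate_region(shell, holes):
                    patches.append(lift(t2))
        else:
            raise ValueError(f"unknown op {op!r}")
    if op == "difference":
        tris = A["outside"] + A["on_anti"] + patches
    elif op == "intersection":
        tris = A["inside"] + patches
    else:
        tris = A["outside"] + A["on_same"] + patches
    return weld_triangles(tris)
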