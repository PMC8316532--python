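"""Brute-force vectorised ray casting against triangle soups.

A chunked Moller-Trumbore implementation used for point containment,
radial surface probing and feature measurement.  Complexity is
O(n_rays * n_faces) per query, which is fine at the mesh sizes this
pipeline produces; no spatial index is required.
"""
from __future__ import annotations

import numpy as np

_EPS = 1e-12
# faces per broadcast chunk; keeps peak memory around tens of MB
_CHUNK = 1 << 21


def _triangles(mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tri = mesh.vertices.view(np.ndarray)[mesh.faces]
    return tri[:, 0], tri[:, 1], tri[:, 2]


def ray_hits(mesh, origins, directions, *, max_hits: int | None = None):
    """Return all ray/triangle hits as (ray_index, t) arrays, t > 1e-9.

    ``origins`` and ``directions`` are (n, 3); directions need not be unit
    (t is in units of the direction vector's length).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    v0, v1, v2 = _triangles(mesh)
    e1 = v1 - v0
    e2 = v2 - v0
    n_rays = len(origins)
    n_tri = len(v0)
    out_ray: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    if n_tri == 0 or n_rays == 0:
        return np.empty(0, dtype=np.intp), np.empty(0)
    rows = max(1, _CHUNK // n_tri)
    for start in range(0, n_rays, rows):
        o = origins[start : start + rows][:, None, :]
        d = directions[start : start + rows][:, None, :]
        p = np.cross(d, e2[None, :, :])
        det = np.einsum("rtk,tk->rt", p, e1)
        ok = np.abs(det) > _EPS
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", s, p) * inv
        ok &= (u >= -1e-9) & (u <= 1 + 1e-9)
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("rtk,rtk->rt", q, d) * inv
        ok &= (v >= -1e-9) & (u + v <= 1 + 1e-9)
        t = np.einsum("rtk,tk->rt", q, e2) * inv
        ok &= t > 1e-9
        r_idx, _ = np.nonzero(ok)
        out_ray.append(r_idx + start)
        out_t.append(t[ok])
    ray_index = np.concatenate(out_ray)
    t_all = np.concatenate(out_t)
    return ray_index, t_all


def first_hit_distance(mesh, origins, directions) -> np.ndarray:
    """Distance to the first surface hit per ray (inf when the ray misses)."""
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    ray_index, t = ray_hits(mesh, origins, directions)
    dist = np.full(len(origins), np.inf)
    np.minimum.at(dist, ray_index, t)
    return dist


_CONTAIN_DIRS = (
    (0.37287619, 0.82396187, 0.42673257),
    (-0.66371412, 0.29012071, 0.68937224),
    (0.22190962, -0.54231452, 0.81029370),
)


def contains_points(mesh, points) -> np.ndarray:
    """Even-odd point-in-solid test, majority-voted over three fixed ray
    directions so that rays grazing shared edges cannot flip the parity.
    Deterministic."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    votes = np.zeros(len(points), dtype=np.int64)
    for direction in _CONTAIN_DIRS:
        d = np.tile(np.asarray(direction, dtype=np.float64), (len(points), 1))
        ray_index, _ = ray_hits(mesh, points, d)
        counts = np.bincount(ray_index, minlength=len(points))
        votes += counts % 2
    return votes >= 2
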