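"""Deterministic synthetic bone phantoms.

Smooth parametric stand-ins for segmented bones so every pipeline stage is
testable without patient data: a tapered, mildly bowed tube for the fibula
and a swept U-arch for the mandible. They are *not* anatomical — no
condyles, teeth or medullary canal — but they exercise every geometric
operation downstream (normalisation, planning, cutting, guide seating).
Both are built directly in their convention poses and are watertight by
construction; an optional seeded sub-print-resolution surface jitter
(``jitter_mm``) can knock meshes out of exact symmetry when general
position is wanted.
"""
from __future__ import annotations

import numpy as np
import trimesh

from .errors import ParameterError
from .planning import CuttingPlane


def _tube(ring_centers, ring_dirs_u, ring_dirs_v, radii, jitter=None):
    """Closed swept tube: rings of points c + r*(cos t * u + sin t * v),
    quad strips between rings, fan caps. radii is (n_rings, n_theta)."""
    n_rings, n_theta = radii.shape
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = []
    for i in range(n_rings):
        ring = (
            ring_centers[i]
            + radii[i][:, None] * (ct[:, None] * ring_dirs_u[i] + st[:, None] * ring_dirs_v[i])
        )
        verts.append(ring)
    verts = np.concatenate(verts)
    if jitter is not None:
        verts = verts + jitter
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    c0 = len(verts)
    verts = np.vstack([verts, verts[:n_theta].mean(axis=0, keepdims=True)])
    c1 = len(verts)
    verts = np.vstack([verts, verts[(n_rings - 1) * n_theta : n_rings * n_theta].mean(axis=0, keepdims=True)])
    for j in range(n_theta):
        faces.append([c0, (j + 1) % n_theta, j])
        base = (n_rings - 1) * n_theta
        faces.append([c1, base + j, base + (j + 1) % n_theta])
    mesh = trimesh.Trimesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def synthetic_fibula(
    length: float = 350.0,
    proximal_radius: float = 9.0,
    distal_radius: float = 6.0,
    bow: float = 3.0,
    perforator_station: float | None = None,
    seed: int = 0,
    jitter_mm: float = 0.0,
    n_theta: int = 48,
    ring_spacing: float = 4.0,
) -> trimesh.Trimesh:
    """Tapered tube along +y, distal (thinner) end at negative y, mild
    circular bow in the y-z plane; optional ~1 mm bump marking a perforator
    at ``perforator_station`` mm from the distal end.
    """
    if min(length, proximal_radius, distal_radius) <= 0 or bow < 0:
        raise ParameterError("fibula fixture dimensions must be positive")
    if distal_radius >= proximal_radius:
        raise ParameterError("distal_radius must be smaller than proximal_radius")
    rng = np.random.default_rng(seed)
    n_rings = max(8, int(round(length / ring_spacing)) + 1)
    y = np.linspace(-length / 2, length / 2, n_rings)
    frac = (y + length / 2) / length
    r = distal_radius + (proximal_radius - distal_radius) * frac
    zoff = bow * (1 - (2 * y / length) ** 2)
    centers = np.column_stack([np.zeros_like(y), y, zoff])
    u = np.tile([1.0, 0.0, 0.0], (n_rings, 1))
    v = np.tile([0.0, 0.0, 1.0], (n_rings, 1))
    radii = np.tile(r[:, None], (1, n_theta)).astype(np.float64)
    if perforator_station is not None:
        if not 0 < perforator_station < length:
            raise ParameterError("perforator_station must lie inside the bone")
        theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        yp = -length / 2 + perforator_station
        # compact cosine bump, 1 mm high, ~6 mm across, on the +x side
        for i in range(n_rings):
            arc = np.minimum(np.abs(theta - 0.0), 2 * np.pi - theta) * r[i]
            d2 = (y[i] - yp) ** 2 + arc**2
            radii[i] += 1.0 * np.clip(np.cos(np.sqrt(d2) / 3.0 * (np.pi / 2)), 0, None) * (d2 < 9.0)
    jitter = jitter_mm * rng.standard_normal((n_rings * n_theta, 3)) / np.sqrt(3)
    jitter[:n_theta] = 0.0
    jitter[-n_theta:] = 0.0
    mesh = _tube(centers, u, v, radii, jitter)
    mesh.vertices -= mesh.vertices.mean(axis=0)  # centroid at origin
    mesh.metadata["name"] = "synthetic_fibula"
    mesh.metadata["perforator_station"] = perforator_station
    return mesh


def synthetic_mandible(
    arch_width: float = 110.0,
    arch_depth: float = 95.0,
    body_height: float = 28.0,
    defect: tuple[float, float] | None = None,
    seed: int = 0,
    jitter_mm: float = 0.0,
    body_width: float = 13.0,
    n_alpha: int = 72,
    n_phi: int = 28,
):
    """Watertight U-arch solid in mandible convention pose.

    The body is an elliptic cross-section swept along a half-elliptic arch;
    ``arch_width``/``arch_depth`` are outer extents, the floor sits on z = 0
    and the anterior apex points to +y. With ``defect=(start_deg, end_deg)``
    (angles about the anterior midline, negative = patient-right span of the
    parametrisation) the two mandibular resection planes at the span
    boundaries are returned alongside the mesh, normals facing into the
    defect: returns (mesh, (plane_start, plane_end)).
    """
    if min(arch_width, arch_depth, body_height, body_width) <= 0:
        raise ParameterError("mandible fixture dimensions must be positive")
    if arch_width <= 2 * body_width or arch_depth <= body_width:
        raise ParameterError("arch extents too small for the body cross-section")
    rng = np.random.default_rng(seed)
    a = (arch_width - body_width) / 2.0  # centreline semi-axis, x
    b = arch_depth - body_width  # centreline depth extent, y
    alpha = np.linspace(-np.pi / 2, np.pi / 2, n_alpha)

    def centreline(al):
        return np.column_stack(
            [a * np.sin(al), b * np.cos(al), np.full(np.shape(al), body_height / 2.0)]
        )

    def tangent(al):
        t = np.column_stack([a * np.cos(al), -b * np.sin(al), np.zeros(np.shape(al))])
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    C = centreline(alpha)
    T = tangent(alpha)
    # horizontal outward normal and vertical axis frame the cross-section
    N = np.column_stack([-T[:, 1], T[:, 0], np.zeros(len(T))])
    Z = np.tile([0.0, 0.0, 1.0], (len(alpha), 1))
    radii_u = np.full((n_alpha, n_phi), body_width / 2.0)
    # elliptic section: scale the v (vertical) component via per-point dirs
    theta = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    verts_rows = []
    for i in range(n_alpha):
        # mildly wider towards the alveolar (top) side, as real bodies are;
        # this vertical asymmetry also anchors the normalisation's z sign
        width = (body_width / 2.0) * (1.0 + 0.08 * np.sin(theta))
        ring = (
            C[i]
            + width[:, None] * np.cos(theta)[:, None] * N[i]
            + (body_height / 2.0) * np.sin(theta)[:, None] * Z[i]
        )
        verts_rows.append(ring)
    verts = np.concatenate(verts_rows)
    jitter = jitter_mm * rng.standard_normal(verts.shape) / np.sqrt(3)
    jitter[:n_phi] = 0.0
    jitter[-n_phi:] = 0.0
    verts = verts + jitter
    faces = []
    for i in range(n_alpha - 1):
        for j in range(n_phi):
            p = i * n_phi + j
            q = i * n_phi + (j + 1) % n_phi
            r_ = (i + 1) * n_phi + j
            s = (i + 1) * n_phi + (j + 1) % n_phi
            faces.append([p, q, s])
            faces.append([p, s, r_])
    c0 = len(verts)
    verts = np.vstack([verts, verts[:n_phi].mean(axis=0, keepdims=True)])
    c1 = len(verts)
    verts = np.vstack([verts, verts[-n_phi - 1 : -1].mean(axis=0, keepdims=True)])
    for j in range(n_phi):
        faces.append([c0, (j + 1) % n_phi, j])
        base = (n_alpha - 1) * n_phi
        faces.append([c1, base + j, base + (j + 1) % n_phi])
    mesh = trimesh.Trimesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    if mesh.volume < 0:
        mesh.invert()
    # convention pose: centre x/y on the vertex centroid, floor to z = 0
    shift = mesh.vertices.mean(axis=0)
    shift[2] = mesh.vertices[:, 2].min()
    mesh.vertices -= shift
    mesh.metadata["name"] = "synthetic_mandible"
    if defect is None:
        return mesh
    start, end = (np.deg2rad(defect[0]), np.deg2rad(defect[1]))
    if not (-np.pi / 2 < start < end < np.pi / 2):
        raise ParameterError("defect span must satisfy -90 < start < end < 90 degrees")
    planes = []
    for al, into in ((start, +1.0), (end, -1.0)):
        origin = centreline(np.array([al]))[0] - shift
        # tangent points toward increasing alpha == decreasing anatomical
        # left-angle; 'into' flips it to face the defect interior
        normal = into * tangent(np.array([al]))[0]
        planes.append(
            CuttingPlane(origin=origin, normal=normal, blade_thickness=0.0,
                         role="mandible-resection", index=len(planes))
        )
    return mesh, tuple(planes)
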