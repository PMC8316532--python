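"""Triangle-mesh I/O and sanity checks.

Meshes move between the segmentation software, this pipeline and the 3D
printer as STL (binary or ASCII, auto-detected); PLY and OBJ are accepted
as an extension. None of these formats carries units: the pipeline defines
all coordinates as millimetres and *warns* (never errors) on implausible
scales, mirroring the manual check-your-units step of clinical workflows.

The in-memory mesh container is :class:`trimesh.Trimesh`; the free-text
label travels in ``mesh.metadata['name']``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import ContentError, FormatError, ParameterError

#: load-time vertex-merge tolerance (mm); far below print resolution,
#: far above floating-point noise, so distinct anatomy is never welded.
MERGE_TOL = 1e-6

_SUPPORTED = {".stl", ".ply", ".obj"}

#: plausible longest-extent windows (mm) per bone; configurable because
#: segmented meshes may or may not include the malleolus / condyles.
SCALE_WINDOWS_MM = {"fibula": (250.0, 500.0), "mandible": (80.0, 160.0)}


@dataclass
class WatertightReport:
    watertight: bool
    boundary_edge_count: int
    volume: float | None  # mm^3, only reported when watertight


def clean_mesh(mesh: trimesh.Trimesh, name: str | None = None) -> trimesh.Trimesh:
    """Merge duplicate vertices (within MERGE_TOL) and drop degenerate faces."""
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    key = np.round(v / MERGE_TOL).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    out = trimesh.Trimesh(v[first], inv[f], process=False)
    areas = out.area_faces
    faces = out.faces[
        (out.faces[:, 0] != out.faces[:, 1])
        & (out.faces[:, 1] != out.faces[:, 2])
        & (out.faces[:, 0] != out.faces[:, 2])
        & (areas > 1e-14)
    ]
    out = trimesh.Trimesh(out.vertices, faces, process=False)
    if name is not None:
        out.metadata["name"] = name
    return out


def load_mesh(path, expected_units: str = "mm") -> trimesh.Trimesh:
    """Load and clean a surface mesh (STL/PLY/OBJ, mm).

    Raises FormatError for unreadable/unsupported files and ContentError for
    files that parse to no geometry. Whether the mesh arrived watertight is
    recorded in ``metadata['loaded_watertight']``.
    """
    path = os.fspath(path)
    if expected_units != "mm":
        raise ParameterError("all pipeline I/O is defined in millimetres")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED:
        raise FormatError(f"unsupported mesh format {ext!r} (expected stl/ply/obj)")
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        raw = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise ContentError(f"{path} contains no triangle geometry")
    mesh = clean_mesh(raw, name=os.path.splitext(os.path.basename(path))[0])
    mesh.metadata["loaded_watertight"] = bool(mesh.is_watertight)
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path, file_format: str | None = None) -> None:
    """Write a mesh as stl-binary (default for .stl), stl-ascii, ply or obj."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    fmt = file_format or {".stl": "stl-binary", ".ply": "ply", ".obj": "obj"}.get(ext)
    if fmt not in ("stl-binary", "stl-ascii", "ply", "obj"):
        raise ParameterError(f"unknown mesh format {file_format!r}")
    try:
        if fmt == "stl-binary":
            data = trimesh.exchange.stl.export_stl(mesh)
            with open(path, "wb") as fh:
                fh.write(data)
        elif fmt == "stl-ascii":
            data = trimesh.exchange.stl.export_stl_ascii(mesh)
            with open(path, "w") as fh:
                fh.write(data)
        else:
            mesh.export(path, file_type=fmt)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


def check_watertight(mesh: trimesh.Trimesh) -> WatertightReport:
    """Diagnostic closedness report; volume via divergence theorem when closed."""
    if len(mesh.faces) == 0:
        return WatertightReport(False, 0, None)
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int((counts != 2).sum())
    watertight = bool(mesh.is_watertight)
    return WatertightReport(watertight, boundary, float(mesh.volume) if watertight else None)


def sanity_check_scale(mesh, bone_kind: str, windows=None) -> list[str]:
    """Warn when the longest bounding-box extent is implausible for the bone.

    Catches unit mishaps such as meshes exported in inches (a 350 mm fibula
    becomes ~13.8, far below the 250 mm floor).
    """
    windows = windows or SCALE_WINDOWS_MM
    if bone_kind not in windows:
        raise ParameterError(f"unknown bone kind {bone_kind!r}")
    lo, hi = windows[bone_kind]
    extent = float(mesh.extents.max()) if len(mesh.vertices) else 0.0
    warnings = []
    if extent < lo:
        warnings.append(
            f"{bone_kind} longest extent {extent:.1f} mm is below the plausible "
            f"minimum {lo:.0f} mm - check units (inches vs millimetres?)"
        )
    elif extent > hi:
        warnings.append(
            f"{bone_kind} longest extent {extent:.1f} mm exceeds the plausible "
            f"maximum {hi:.0f} mm - check units"
        )
    return warnings
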