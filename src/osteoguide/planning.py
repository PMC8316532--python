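"""The surgical plan: resection, graft segments, kerf-compensated planes.

Conventions (documented in detail in the methods note):

* A :class:`CuttingPlane`'s origin/normal locate the **blade centre**: the
  saw removes a band of ``blade_thickness`` (kerf) centred on the plane.
  Each fibular blade-centre plane is offset *outward* from the designed
  graft end face by kerf/2 along the outward face normal, so the surviving
  segment has exactly the designed length.
* Grafts are disjoint fibular intervals packed proximal -> distal in index
  order. The designed inter-graft gap is ``max(2*kerf, gap_floor)`` so that
  consecutive blade-centre planes stay at least one kerf apart and every
  graft keeps its own two osteotomies (n grafts -> 2n cuts).
* Graft-local frame: long axis +y, end 0 at local -y. End-face orientations
  are stored as outward unit normals in the graft-local frame, so they ride
  rigidly with the graft between the mandible and fibula frames.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    CapacityError,
    GeometryError,
    ParameterError,
    PlanConflictError,
)
from .frames import RigidTransform


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length normal")
    return v / n


@dataclass
class CuttingPlane:
    """An oriented blade-centre plane with kerf."""

    origin: np.ndarray
    normal: np.ndarray
    blade_thickness: float = 0.0
    role: str = "fibula-osteotomy"
    index: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.normal = _unit(self.normal)
        if self.blade_thickness < 0:
            raise ParameterError("blade_thickness must be >= 0")
        if self.role not in ("fibula-osteotomy", "mandible-resection"):
            raise ParameterError(f"unknown plane role {self.role!r}")

    def signed_distance(self, points):
        return np.atleast_2d(points) @ self.normal - self.origin @ self.normal

    def to_dict(self):
        return {
            "origin": [round(float(x), 9) for x in self.origin],
            "normal": [round(float(x), 9) for x in self.normal],
            "blade_thickness": self.blade_thickness,
            "role": self.role,
            "index": self.index,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**{**d, "origin": np.asarray(d["origin"]), "normal": np.asarray(d["normal"])})


@dataclass
class GuideSpec:
    """Dimensional parameters of a cutting guide (all mm).

    ``screw_clearance`` defaults to 0.2 mm — the upper bound of the
    customary 0.1-0.2 mm print-tolerance allowance — and is validated to
    that band unless ``allow_nonstandard_screw_clearance`` is set.
    Screw positions are (station mm along the guide sweep, angle deg around
    the bone cross-section, 0 deg = top).
    """

    slot_clearance: float = 0.2
    wall_thickness: float = 3.0
    flange_height: float = 12.0
    seat_clearance: float = 0.1
    screw_diameter: float = 2.0
    screw_clearance: float = 0.2
    screw_positions_fibula: tuple = ()
    screw_positions_mandible: tuple = ()
    allow_nonstandard_screw_clearance: bool = False
    end_margin: float = 8.0  # sweep extension beyond the outermost slot

    def __post_init__(self):
        for name in ("slot_clearance", "wall_thickness", "flange_height",
                     "seat_clearance", "screw_diameter", "screw_clearance", "end_margin"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"GuideSpec.{name} must be > 0")
        if not self.allow_nonstandard_screw_clearance and not (
            0.1 - 1e-12 <= self.screw_clearance <= 0.2 + 1e-12
        ):
            raise ParameterError(
                "screw_clearance outside the suggested 0.1-0.2 mm band; set "
                "allow_nonstandard_screw_clearance=True to override"
            )

    def slot_width(self, blade_thickness: float) -> float:
        return blade_thickness + self.slot_clearance

    @property
    def hole_diameter(self) -> float:
        return self.screw_diameter + self.screw_clearance

    def to_dict(self):
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for k in ("screw_positions_fibula", "screw_positions_mandible"):
            if k in d:
                d[k] = tuple(tuple(x) for x in d[k])
        return cls(**d)


@dataclass
class GraftSegment:
    """One fibular segment: designed length, poses in both frames, end faces."""

    index: int
    length: float
    pose_in_mandible: RigidTransform
    pose_in_fibula: RigidTransform = field(default_factory=RigidTransform.identity)
    # outward unit normals of the two end faces, graft-local frame
    end_normals_local: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]])
    )
    pinned_station: float | None = None  # explicit fibular start station (mm, designed start)

    def __post_init__(self):
        self.end_normals_local = np.asarray(self.end_normals_local, dtype=np.float64).reshape(2, 3)
        self.end_normals_local /= np.linalg.norm(self.end_normals_local, axis=1, keepdims=True)
        if self.length <= 0:
            raise ParameterError("graft length must be positive")
        outward = np.array([[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]])
        for e in range(2):
            if self.end_normals_local[e] @ outward[e] <= 0:
                raise GeometryError(
                    f"graft {self.index} end {e}: face normal makes >= 90 deg with the long axis"
                )

    def end_angles_deg(self):
        """Angle between each end plane and the graft long axis (90 = square cut)."""
        axis = np.array([0.0, 1.0, 0.0])
        c = np.abs(self.end_normals_local @ axis).clip(0, 1)
        return [round(float(np.degrees(np.arcsin(ci))), 9) for ci in c]


@dataclass
class PerforatorMarker:
    axial_position: float  # mm cranial of the distal fibula end
    world_point: np.ndarray  # on the fibular axis, fibula frame


@dataclass
class GraftPlan:
    """The whole case: bones, resection, grafts, kerf, guide parameters."""

    mandible: object  # trimesh.Trimesh, normalised mandible frame
    fibula: object  # trimesh.Trimesh, normalised fibula frame
    n_grafts: int
    kerf: float
    resection_planes: tuple
    grafts: list = field(default_factory=list)
    guide_spec: GuideSpec = field(default_factory=GuideSpec)
    gap_floor: float = 1.0
    perforator_offset: float = 90.0
    perforator: PerforatorMarker | None = None
    harvest_margin_distal: float = 60.0
    harvest_margin_proximal: float = 60.0
    fibula_planes: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------


def default_resection_planes(mandible, span_deg=(-20.0, 20.0), tilt_deg=20.0):
    """Placeholder resection planes when the case config gives none.

    Two planes at the angular bounds of the (configured or default) defect
    span about the anterior midline, tilted about the vertical axis, normals
    facing into the defect.
    """
    v = mandible.vertices.view(np.ndarray)
    cx, cy = 0.0, v[:, 1].mean()
    zmid = v[:, 2].mean()
    planes = []
    for k, (phi_deg, into) in enumerate(((span_deg[0], +1.0), (span_deg[1], -1.0))):
        phi = np.deg2rad(phi_deg)
        u = np.array([np.sin(phi), np.cos(phi), 0.0])  # radial, midline at phi=0
        proj = (v[:, :2] - [cx, cy]) @ u[:2]
        origin = np.array([cx, cy, zmid]) + u * (proj.max() * 0.75)
        tang = np.array([np.cos(phi), -np.sin(phi), 0.0]) * into
        tilt = np.deg2rad(tilt_deg) * (1 if k == 0 else -1)
        Rz = RigidTransform.from_axis_angle([0, 0, 1], tilt)
        planes.append(
            CuttingPlane(origin=origin, normal=Rz.apply_vector(tang),
                         blade_thickness=0.0, role="mandible-resection", index=k)
        )
    return tuple(planes)


def init_plan(
    mandible,
    fibula,
    n_grafts: int,
    kerf: float = 1.0,
    resection_planes=None,
    guide_spec: GuideSpec | None = None,
    gap_floor: float = 1.0,
    perforator_offset: float = 90.0,
    harvest_margin_distal: float = 60.0,
    harvest_margin_proximal: float = 60.0,
) -> GraftPlan:
    """Build a plan with default graft initialisation and derived fibular planes.

    Both bones must be watertight and already in their normalised frames.
    """
    if n_grafts < 1:
        raise ParameterError("n_grafts must be >= 1")
    if kerf < 0:
        raise ParameterError("kerf must be >= 0")
    for label, bone in (("mandible", mandible), ("fibula", fibula)):
        if not bone.is_watertight:
            raise GeometryError(f"{label} mesh is not watertight")
    if resection_planes is None:
        resection_planes = default_resection_planes(mandible)
    resection_planes = tuple(resection_planes)
    if len(resection_planes) != 2:
        raise ParameterError("exactly two mandibular resection planes required")
    for p in resection_planes:
        p.blade_thickness = kerf
        p.role = "mandible-resection"
    plan = GraftPlan(
        mandible=mandible,
        fibula=fibula,
        n_grafts=n_grafts,
        kerf=kerf,
        resection_planes=resection_planes,
        guide_spec=guide_spec or GuideSpec(),
        gap_floor=gap_floor,
        perforator_offset=perforator_offset,
        harvest_margin_distal=harvest_margin_distal,
        harvest_margin_proximal=harvest_margin_proximal,
    )
    place_perforator_marker(plan)  # before packing, so packing can centre on it
    init_graft_controls(plan)
    return plan


def init_graft_controls(plan: GraftPlan):
    """Initial graft poses: equal subdivision of the resection chord.

    The straight chord between the two resection-plane origins is split into
    ``n_grafts`` equal spans; each graft's long axis lies along the chord.
    Terminal end faces copy the adjacent resection-plane orientation so the
    initial neomandible mates flush; interior joins are square cuts.
    Returns the list of control transforms (graft-local -> mandible frame).
    """
    o0, o1 = plan.resection_planes[0].origin, plan.resection_planes[1].origin
    chord = o1 - o0
    clen = float(np.linalg.norm(chord))
    if clen < 1e-9:
        raise GeometryError("resection plane origins coincide; no defect chord")
    yhat = chord / clen
    zref = np.array([0.0, 0.0, 1.0])
    if abs(zref @ yhat) > 0.99:
        zref = np.array([1.0, 0.0, 0.0])
    xhat = _unit(np.cross(yhat, zref))
    zhat = np.cross(xhat, yhat)
    R = np.column_stack([xhat, yhat, zhat])
    seg_len = clen / plan.n_grafts
    plan.grafts = []
    for i in range(plan.n_grafts):
        centre = o0 + (i + 0.5) * seg_len * yhat
        pose = RigidTransform(R, centre)
        normals = np.array([[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]])
        if i == 0:
            n_res = plan.resection_planes[0].normal  # faces into the defect
            cand = R.T @ (-n_res)
            if cand[1] < 0:  # must stay an outward (-y side) face normal
                normals[0] = cand
        if i == plan.n_grafts - 1:
            n_res = plan.resection_planes[1].normal
            cand = R.T @ (-n_res)
            if cand[1] > 0:
                normals[1] = cand
        plan.grafts.append(
            GraftSegment(index=i, length=seg_len, pose_in_mandible=pose,
                         end_normals_local=normals)
        )
    derive_fibula_planes(plan)
    return [g.pose_in_mandible for g in plan.grafts]


def _footprint(graft: GraftSegment, bone_radius: float):
    """Axial extent (mm) the graft's designed interval claims on the fibula,
    accounting for tilted end faces sweeping across the bone cross-section."""
    ext = [0.0, 0.0]
    for e in range(2):
        n = graft.end_normals_local[e]
        axial = abs(n[1])
        lateral = float(np.hypot(n[0], n[2]))
        ext[e] = bone_radius * lateral / max(axial, 1e-6)
    return graft.length + ext[0] + ext[1], ext


def derive_fibula_planes(plan: GraftPlan):
    """Pack grafts proximal -> distal along the fibula and derive the
    2 x n_grafts kerf-compensated blade-centre planes (fibula frame).

    Each graft's end faces (defined graft-locally, hence identical in the
    mandible frame via pose_in_mandible and in the fibula frame via
    pose_in_fibula) are offset outward by kerf/2.
    """
    v = plan.fibula.vertices.view(np.ndarray)
    ymin, ymax = float(v[:, 1].min()), float(v[:, 1].max())
    w0 = ymin + plan.harvest_margin_distal
    w1 = ymax - plan.harvest_margin_proximal
    if w1 <= w0:
        raise CapacityError("harvest margins exceed the fibula length")
    r_bone = _local_max_radius(plan.fibula)
    gap = max(2 * plan.kerf, plan.gap_floor)
    feet = [_footprint(g, r_bone) for g in plan.grafts]
    total = sum(f[0] + plan.kerf for f in feet) + gap * (len(plan.grafts) - 1)

    pinned = [g for g in plan.grafts if g.pinned_station is not None]
    if pinned and len(pinned) != len(plan.grafts):
        raise ParameterError("either pin every graft station or none")
    if not pinned:
        if total > (w1 - w0) + 1e-9:
            raise CapacityError(
                f"grafts need {total:.1f} mm but only {w1 - w0:.1f} mm of fibula "
                "is harvestable"
            )
        if plan.perforator is not None:
            # keep the perforator inside the first (most distal) graft
            lead = feet[0][1][0] + plan.kerf / 2  # band ahead of graft 0's start
            cursor = plan.perforator.world_point[1] - plan.grafts[0].length / 2 - lead
        else:
            cursor = (w0 + w1) / 2 - total / 2
        cursor = float(np.clip(cursor, w0, w1 - total))
        starts = []
        for (fp, ext), g in zip(feet, plan.grafts):
            cursor += plan.kerf / 2 + ext[0]
            starts.append(cursor)  # designed start (end-0 face centre station)
            cursor += g.length + ext[1] + plan.kerf / 2 + gap
    else:
        starts = [g.pinned_station for g in plan.grafts]
        intervals = []
        for s, (fp, ext), g in zip(starts, feet, plan.grafts):
            intervals.append((s - ext[0] - plan.kerf / 2, s + g.length + ext[1] + plan.kerf / 2, g.index))
        intervals.sort()
        for (a0, a1, i0), (b0, b1, i1) in zip(intervals, intervals[1:]):
            if b0 < a1 + (gap - plan.kerf) - 1e-9:
                raise PlanConflictError(
                    f"grafts {i0} and {i1} claim overlapping fibular intervals"
                )
        if intervals[0][0] < w0 - 1e-9 or intervals[-1][1] > w1 + 1e-9:
            raise CapacityError("pinned grafts fall outside the harvestable window")

    plan.fibula_planes = []
    for g, s in zip(plan.grafts, starts):
        centre_y = s + g.length / 2
        g.pose_in_fibula = RigidTransform(np.eye(3), np.array([0.0, centre_y, 0.0]))
        for e, local_face in enumerate(((0.0, -g.length / 2, 0.0), (0.0, g.length / 2, 0.0))):
            n = g.pose_in_fibula.apply_vector(g.end_normals_local[e])
            face_centre = g.pose_in_fibula.apply(np.asarray(local_face))
            origin = face_centre + (plan.kerf / 2) * n
            plan.fibula_planes.append(
                CuttingPlane(origin=origin, normal=n, blade_thickness=plan.kerf,
                             role="fibula-osteotomy", index=2 * g.index + e)
            )
    _validate_plan(plan)
    return list(plan.fibula_planes)


def _local_max_radius(fibula) -> float:
    v = fibula.vertices.view(np.ndarray)
    return float(np.hypot(v[:, 0] - v[:, 0].mean(), v[:, 2] - v[:, 2].mean()).max())


def _validate_plan(plan: GraftPlan):
    plan.warnings = [w for w in plan.warnings if not w.startswith("perforator")]
    if plan.perforator is not None and plan.grafts and plan.fibula_planes:
        y = plan.perforator.world_point[1]
        inside = any(
            g.pose_in_fibula.translation[1] - g.length / 2 <= y <= g.pose_in_fibula.translation[1] + g.length / 2
            for g in plan.grafts
        )
        if not inside:
            plan.warnings.append(
                "perforator marker lies outside every planned graft interval; "
                "the perforating vessels would not remain in the harvested segment"
            )
    for g in plan.grafts:
        if g.length <= plan.kerf:
            raise PlanConflictError(f"graft {g.index} shorter than the kerf")


def set_graft_pose(plan: GraftPlan, index: int, pose_in_mandible: RigidTransform) -> GraftPlan:
    """Update one graft's control transform and re-derive the fibular planes."""
    if not 0 <= index < len(plan.grafts):
        raise ParameterError(f"graft index {index} out of range")
    if not isinstance(pose_in_mandible, RigidTransform):
        raise ParameterError("pose must be a RigidTransform")
    plan.grafts[index].pose_in_mandible = pose_in_mandible
    derive_fibula_planes(plan)
    return plan


def set_graft_end_face(plan: GraftPlan, index: int, end: int, normal_local) -> GraftPlan:
    """Tilt one end face (outward normal, graft-local frame) and re-derive."""
    if not 0 <= index < len(plan.grafts):
        raise ParameterError(f"graft index {index} out of range")
    if end not in (0, 1):
        raise ParameterError("end must be 0 or 1")
    g = plan.grafts[index]
    normals = g.end_normals_local.copy()
    normals[end] = _unit(normal_local)
    plan.grafts[index] = replace(g, end_normals_local=normals)
    derive_fibula_planes(plan)
    return plan


def set_graft_station(plan: GraftPlan, index: int, station: float | None) -> GraftPlan:
    """Pin a graft's designed start station on the fibula (None = auto-pack)."""
    if not 0 <= index < len(plan.grafts):
        raise ParameterError(f"graft index {index} out of range")
    plan.grafts[index].pinned_station = station
    derive_fibula_planes(plan)
    return plan


def place_perforator_marker(plan: GraftPlan, axial_offset: float | None = None) -> PerforatorMarker:
    """Mark the expected perforating-vessel position on the fibular axis.

    Default offset: 90 mm cranial of the distal end (the common clinical
    heuristic of ~9 cm above the lateral malleolus), configurable per plan.
    """
    offset = plan.perforator_offset if axial_offset is None else axial_offset
    v = plan.fibula.vertices.view(np.ndarray)
    ymin, ymax = float(v[:, 1].min()), float(v[:, 1].max())
    if not 0 < offset < (ymax - ymin):
        raise ParameterError(
            f"perforator offset {offset} mm outside the bone (length {ymax - ymin:.1f} mm)"
        )
    y = ymin + offset
    near = v[np.abs(v[:, 1] - y) < 5.0]
    point = np.array([near[:, 0].mean(), y, near[:, 2].mean()])
    plan.perforator = PerforatorMarker(axial_position=offset, world_point=point)
    if plan.fibula_planes:
        _validate_plan(plan)
    return plan.perforator


def plan_summary(plan: GraftPlan) -> dict:
    """Deterministic JSON-serialisable report of the plan."""
    stations = sorted(
        round(float(p.origin[1]), 6) for p in plan.fibula_planes
    )
    # span between the outermost blade-centre planes (designed length plus
    # one kerf/2 allowance per terminal cut, plus inter-graft gaps)
    harvest = round(stations[-1] - stations[0], 6) if stations else 0.0
    return {
        "n_grafts": plan.n_grafts,
        "kerf_mm": plan.kerf,
        "grafts": [
            {
                "index": g.index,
                "designed_length_mm": round(float(g.length), 6),
                "end_face_angles_deg": g.end_angles_deg(),
                "fibula_interval_mm": [
                    round(float(g.pose_in_fibula.translation[1] - g.length / 2), 6),
                    round(float(g.pose_in_fibula.translation[1] + g.length / 2), 6),
                ],
            }
            for g in plan.grafts
        ],
        "fibula_plane_stations_mm": stations,
        "total_harvest_length_mm": harvest,
        "perforator_axial_position_mm": (
            None if plan.perforator is None else round(float(plan.perforator.axial_position), 6)
        ),
        "warnings": list(plan.warnings),
    }


# ---------------------------------------------------------------------------
# plan (de)serialisation — the single source of truth between CLI stages


def plan_to_dict(plan: GraftPlan, mandible_path=None, fibula_path=None) -> dict:
    return {
        "mandible": mandible_path,
        "fibula": fibula_path,
        "n_grafts": plan.n_grafts,
        "kerf": plan.kerf,
        "gap_floor": plan.gap_floor,
        "perforator_offset": plan.perforator_offset,
        "harvest_margin_distal": plan.harvest_margin_distal,
        "harvest_margin_proximal": plan.harvest_margin_proximal,
        "resection_planes": [p.to_dict() for p in plan.resection_planes],
        "guide_spec": plan.guide_spec.to_dict(),
        "grafts": [
            {
                "index": g.index,
                "length": round(float(g.length), 9),
                "pose_in_mandible": [round(float(x), 9) for x in g.pose_in_mandible.matrix.ravel()],
                "end_normals_local": [[round(float(x), 9) for x in n] for n in g.end_normals_local],
                "pinned_station": g.pinned_station,
            }
            for g in plan.grafts
        ],
    }


def plan_from_dict(d: dict, mandible, fibula) -> GraftPlan:
    plan = GraftPlan(
        mandible=mandible,
        fibula=fibula,
        n_grafts=int(d["n_grafts"]),
        kerf=float(d["kerf"]),
        resection_planes=tuple(CuttingPlane.from_dict(p) for p in d["resection_planes"]),
        guide_spec=GuideSpec.from_dict(d["guide_spec"]),
        gap_floor=float(d.get("gap_floor", 1.0)),
        perforator_offset=float(d.get("perforator_offset", 90.0)),
        harvest_margin_distal=float(d.get("harvest_margin_distal", 60.0)),
        harvest_margin_proximal=float(d.get("harvest_margin_proximal", 60.0)),
    )
    place_perforator_marker(plan)  # before packing, as in init_plan
    for gd in d["grafts"]:
        plan.grafts.append(
            GraftSegment(
                index=int(gd["index"]),
                length=float(gd["length"]),
                pose_in_mandible=RigidTransform.from_matrix(np.asarray(gd["pose_in_mandible"]).reshape(4, 4)),
                end_normals_local=np.asarray(gd["end_normals_local"]),
                pinned_station=gd.get("pinned_station"),
            )
        )
    if len(plan.grafts) != plan.n_grafts:
        raise ParameterError("plan lists a different number of grafts than n_grafts")
    derive_fibula_planes(plan)
    return plan


def save_plan(plan: GraftPlan, path, mandible_path=None, fibula_path=None):
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan, mandible_path, fibula_path), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_plan(path, mandible=None, fibula=None) -> GraftPlan:
    with open(path) as fh:
        d = json.load(fh)
    if mandible is None or fibula is None:
        from .meshio import load_mesh

        mandible = mandible or load_mesh(d["mandible"])
        fibula = fibula or load_mesh(d["fibula"])
    return plan_from_dict(d, mandible, fibula)
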