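# osteoguide

Patient-specific cutting-guide generation for fibula free-flap mandibular
reconstruction, as a headless, scriptable geometry pipeline.

When a segment of the mandible is resected (tumour, osteomyelitis,
osteonecrosis), the standard reconstruction harvests bone segments from the
fibula and fits them into the defect — the osteocutaneous free flap. Doing
this accurately requires *cutting guides*: 3D-printed jigs that seat on the
exposed bone and carry slots that steer the saw along pre-planned osteotomy
planes. Commercial virtual-surgical-planning services produce such guides at
significant cost and turnaround; `osteoguide` implements the same geometry
workflow as an open, scriptable library: two segmented bone surface meshes
(STL/PLY/OBJ, millimetres) plus a plan configuration in, watertight
print-ready fibular and mandibular guide solids out.

## The model

All planning is done with rigid geometry in two normalised anatomical
frames (fibula: long axis along **y**, distal end at −y; mandible: inferior
border on the x–y plane, anterior arch at +y; both recovered automatically
by an equivariant PCA-plus-shape-moment normalisation).

* Each osteotomy is a **blade-centre plane** with a kerf `t` (saw-blade
  thickness): the cut removes the slab of width `t` centred on the plane.
* A plan with `n` grafts has 2 mandibular resection planes and `2n` fibular
  osteotomy planes. Graft end faces are stored as outward normals in the
  graft-local frame and mapped rigidly between the mandible pose and the
  fibula pose, so end-face angles are identical in both frames.
* **Kerf compensation**: each fibular blade-centre plane is offset outward
  from the designed graft end face by `t/2`, so the surviving segment has
  exactly its designed length. Grafts pack proximal→distal with an
  inter-graft gap of `max(2t, 1 mm)`, keeping adjacent blade-centre planes
  at least one kerf apart.
* **Guides** are partial-ring shells swept along the bone: inner surface
  `seat_clearance` (0.1 mm) off the bone surface, `wall_thickness` (3 mm)
  thick, wrapping `flange_height` (12 mm) of arc past the bone's equator.
  Each cutting plane gets a through-slot of width `t + slot_clearance`
  (default +0.2 mm); screw holes are drilled `screw_clearance` (default
  0.2 mm, within the customary 0.1–0.2 mm print-tolerance band) wider than
  the screw. A perforator marker defaults to 9 cm cranial of the distal
  fibular end, and planning warns if no graft interval contains it.

Guide solids are built as conforming parametric sweeps (watertight by
construction, slot widths and hole diameters exact); general solid
modelling — capped plane cuts, Booleans between convex primitives, and
convex piercing tools against arbitrary watertight meshes — is provided by
the in-package clipping kernel in `osteoguide.solids`.

## Worked example

```bash
osteoguide fixtures --outdir case --defect-start 0 --defect-end 40
osteoguide plan case/case.json --out case/plan.json --summary case/plan_summary.json
osteoguide guides case/plan.json --outdir case
osteoguide validate case/plan.json --outdir case --report case/validation.json
```

The `fixtures` stage writes synthetic bones (a 350 mm tapered fibula tube
and a U-arch mandible with a 0–40° defect) plus a case config. `plan`
prints a summary like:

```json
{
  "fibula_plane_stations_mm": [-103.728376, -66.237935],
  "grafts": [
    {
      "designed_length_mm": 36.605089,
      "end_face_angles_deg": [58.393007279, 66.786184641],
      "fibula_interval_mm": [-103.302544, -66.697456],
      "index": 0
    }
  ],
  "kerf_mm": 1.0,
  "n_grafts": 1,
  "perforator_axial_position_mm": 90.0,
  "total_harvest_length_mm": 37.490441,
  "warnings": []
}
```

One graft means two fibular osteotomies. The 36.6 mm graft spans the chord
of the 40° defect; its end faces are tilted (58.4° and 66.8° to the graft
axis) to mate flush with the resection planes, and the blade-centre
stations sit outside the designed interval by half a kerf at each end, so
the harvested segment survives at exactly 36.6 mm. The interval is placed
so the 90 mm perforator marker falls inside it (no warning). `guides` then writes
`fibula_guide.stl` and `mandible_guide.stl` (watertight, validated against
the contracts above) plus a virtual *neomandible* preview assembly, and
`validate` exits non-zero if any printable-solid contract fails.

The same pipeline is available as a library (`osteoguide.init_plan`,
`osteoguide.build_fibula_guide`, ...); see `docs/methods.md` for the
geometric conventions, defaults and limitations.

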