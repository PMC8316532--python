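# Methods

This note records the geometric model behind `osteoguide`, the defaults
and their rationale, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Coordinate conventions and normalisation

Two anatomical frames carry the whole pipeline:

* **Fibula frame** — long axis along +y, vertex centroid at the origin,
  distal (thinner) end at negative y.
* **Mandible frame** — inferior border resting on z = 0, anterior arch
  apex at +y, left–right axis along x.

`normalize_fibula` / `normalize_mandible` recover these frames
automatically from the vertex covariance (PCA) plus intrinsic shape
moments. Eigenvector *signs* are deliberately not taken from coordinate
conventions (which would break under rotation of the input) but from
shape properties that travel with the bone:

* fibula: distal end = smaller mean squared cross-section radius over the
  terminal 10 % of length (overridable via `distal_end=` for segmentations
  that include the malleolus); roll about the long axis = the bone's bow
  (mid-shaft centroid deviation from the end-to-end chord defines +z).
* mandible: the flattest covariance axis is vertical, signed so the body
  widens towards the alveolar side; of the two horizontal axes, the one
  with the larger third moment is anterior–posterior, signed so the apex
  (the thin single end; the skew tail is posterior) points to +y.

This makes normalisation *equivariant*: normalising a rigidly moved mesh
recovers the motion to ~1e-12, which the test suite checks over 100 seeded
rotations. Degeneracies are documented rather than hidden: a perfectly
straight tube has no defined roll, a sphere no principal axis (the latter
raises nothing — any deterministic unit vector is acceptable). A
`--no-normalize` CLI flag preserves a user-checked orientation, and the
posterior-facing roll convention of interactive workflows is *not*
enforced — long-axis alignment is the load-bearing convention; roll is
left to the user's graft control transforms.

## Cutting planes and kerf compensation

A `CuttingPlane`'s origin/normal denote the **blade centre**: the saw
removes a slab of `blade_thickness` (kerf) centred there. The offset
applied to fibular planes is kerf/2 outward along the outward end-face
normal: with the blade-centre convention this makes every surviving
segment exactly its designed length, which the suite verifies by actually
cutting the synthetic bone and measuring the survivor (max error below
1e-3 mm for square cuts; for tilted end faces "length" means the distance
between the end-face planes, so the axial-extent oracle applies to the
square-cut configuration).

Graft initialisation subdivides the straight chord between the two
resection-plane origins into equal spans. Terminal end faces copy the
adjacent resection-plane orientation (so the initial neomandible mates
flush — the preview test asserts parallel mating faces); interior joins
are square. End-face orientations live in the graft-local frame and ride
rigidly with the graft, so the angle between a graft's end planes is the
same in the mandible and fibula frames by construction.

Packing is proximal→distal in graft index order with designed inter-graft
gap `max(2*kerf, gap_floor)` (`gap_floor` default 1 mm). The `2*kerf`
floor keeps consecutive blade-centre planes at least one kerf apart, i.e.
every graft keeps its own two distinct osteotomies (n grafts → 2n cuts)
and adjacent kerf bands never merge into one ambiguous cut. Harvest
margins of 60 mm are reserved at both fibular ends (common clinical
practice to protect ankle and knee stability); exceeding the remaining
span raises a capacity error, explicitly pinned stations that collide
raise a plan conflict naming the grafts. When a perforator marker exists,
auto-packing centres the first (most distal) graft on it, and validation
warns whenever no graft interval contains the marker. The marker default
of 90 mm cranial of the distal end encodes the usual ~9 cm clinical
heuristic for peroneal perforators and is a per-plan parameter, not a
constant.

## Solid modelling kernel

No Boolean engine is assumed; `osteoguide.solids` carries its own
plane-clipping kernel scoped to the pipeline's structured needs:

* **Capped half-space clips** (the osteotomies): faces are classified by
  snapped signed distance (`|d| < 1e-8 mm` → on-plane), crossing faces are
  split with edge-crossing points computed once per mesh edge in a
  canonical operand order (bit-identical across adjacent faces, so welds
  are exact), and section loops are capped with shapely's constrained
  Delaunay triangulation (GEOS adds no Steiner points, so cap boundaries
  weld exactly too).
* **Convex–convex Booleans** with explicit coplanar-contact rules
  (same-normal contact keeps one copy, anti-normal contact drops the
  interior interface), which makes nested-corner differences and
  self-intersection exact.
* **Piercing-tool Booleans**: a convex tool whose edges stay outside the
  target (a slab or box extended through it) against any watertight mesh;
  the tool-face patches are bounded purely by seam loops collected from
  the target-side clipping, so they close exactly. Tools whose edges cut
  the target are detected and rejected with a clear error.

Face clipping against whole planes introduces T-junctions where a split
face borders an unsplit one; geometry is exact, so a repair pass that
subdivides edges at vertices lying on them (tolerance 1e-6 mm, the weld
tolerance) restores edge-paired watertightness. The kernel's contract —
watertight in/watertight out, vol(A−B)+vol(A∩B)=vol(A) and
inclusion–exclusion to 1e-6 relative — is exercised on 50 seeded random
box/cylinder pairs per run. Empty results (disjoint intersections) are an
explicit empty mesh, never an error; non-watertight Boolean operands are a
hard error naming the operand. Subtraction tools elsewhere in the package
are extended ~0.01 mm beyond every surface they must pierce so coplanar
configurations cannot arise by accident.

Point containment (used by validation checks) is even–odd ray parity
majority-voted over three fixed directions, so a ray grazing a shared edge
cannot flip the answer.

## Guide construction

Both guides are the same solid: a partial ring swept along the bone, with
cutting slots and screw holes. Rather than subtracting slot slabs and hole
cylinders from a generic shell with the Boolean kernel, the builder
realises the identical solid as a *conforming parametric sweep*:

1. A centreline with frames is sampled every 2 mm (fibula: per-station
   cross-section centroids, axis ŷ; mandible: polar arch sampling about
   the vertical axis, smoothed, between the resection stations).
2. The bone surface radius r(u, θ) is probed by brute-force ray casting
   from the centreline; misses inherit neighbours.
3. The guide lives on the 2D domain (station u, wrap angle θ). Slot strips
   and hole discs are subtracted from the domain with shapely; the trimmed
   domain is meshed cell-by-cell (full cells fast-pathed, boundary cells
   clipped and constrained-Delaunay triangulated). The angular cell size
   adapts to the probed surface's curvature so that chord sag stays below
   0.04 mm — essential on ridge-like cross-sections such as the mandibular
   crest, whose local curvature radius (~3 mm) is far smaller than the
   body size.
4. Every 2D vertex is lifted twice (inner sheet at bone+`seat_clearance`,
   outer at +`wall_thickness` more); boundary edges grow wall quads. The
   mesh is therefore watertight by connectivity. Tagged boundary vertices
   are lifted onto the *exact* feature geometry: slot-boundary vertices
   onto the kerf±clearance offset planes (slot width is exact to the
   bisection tolerance), hole-rim vertices onto the true screw cylinder
   (hole walls are exactly cylindrical). The slot strip removed from the
   domain is the full parametric *shadow* of the kerf slab across both
   sheet radii, so tilted-slot boundary vertices only ever stretch into
   already-removed cells and the sheets cannot fold over themselves.

Slots span a finite wrap (`slot_wrap_deg`, default 200°) rather than the
full ring, leaving connecting bridges in the flanges so one guide body
stays in one piece; an oscillating saw reaches the whole cross-section
through such a slot. A slot whose strip misses the domain raises a
construction error naming the plane; screw holes whose disc approaches a
slot strip raise a placement error naming both.

`add_screw_holes` drills by re-running the recorded build (the sweep
context travels in the mesh metadata): subtracting a cylinder from an
arbitrary mesh is outside the piercing-tool domain (a cylinder's
tessellation edges cross the shell), while the rebuild is deterministic —
requesting zero holes returns a bit-identical mesh, which is tested.

Defaults (all overridable in `GuideSpec`): wall 3.0 mm, flange 12.0 mm of
wrap arc past the equator (wrap capped at 135° per side so the guide can
seat), seat clearance 0.1 mm, slot clearance 0.2 mm, screw clearance
0.2 mm — the top of the customary 0.1–0.2 mm print-tolerance band, safer
against print shrinkage; values outside the band require an explicit
override flag. Auto screw placement puts one hole on the crest of each end
flange. These body dimensions are this package's concrete definition of a
guide (interactive workflows shape them by eye); they reproduce the usual
printed-guide form with testable dimensions.

Validation is geometric, not bookkeeping: slots are counted by probing the
blade plane for void and its flanks for material; slot width by casting
rays between the slot walls; hole diameter as the ray-cast maximal
inscribed circle at mid-wall (for a 32-segment hole wall this reads the
polygon apothem, ~0.5 % under the nominal diameter — the measured
clearance stays inside the 0.1–0.2 mm band); seating by sampled
guide∩bone volume (expected exactly 0 — the sampled estimate reports 0
when no jittered grid point penetrates both solids); wall thickness by
radial ray sampling with slots and holes legitimately thin.

## Synthetic fixtures

`synthetic_fibula` (350 mm tapered tube, 9→6 mm radius, 3 mm bow, optional
1 mm perforator bump) and `synthetic_mandible` (110×95×28 mm U-arch,
elliptic body cross-section slightly wider towards the alveolar side,
optional angular defect returning the two resection planes) are smooth
parametric solids built directly in convention pose, watertight by
construction and bit-deterministic per seed. An optional seeded surface
jitter (`jitter_mm`, default 0) knocks them out of exact symmetry when
general position is wanted.

They emulate the *geometry class* of segmented bones — tapered curved
tube, U-arch with a defect — not real anatomy: no condyles, teeth, ramus,
medullary canal, segmentation noise, or non-convex cross-sections with
overhangs. Passing tests therefore demonstrate that the planning
arithmetic, kerf compensation, frame conventions and guide contracts are
correct on well-behaved closed meshes; they do not demonstrate seating
quality on real segmentations, where slice stair-stepping and local
concavities would stress the radial-probe seat model (a limitation of the
centreline ray probing: cross-sections must be star-shaped about the
centreline).

## Numerical choices

* Load-time vertex merge 1e-6 mm: far below print resolution, far above
  float noise; STL round-trips hold vertices to ~1e-5 mm (32-bit floats).
* Plane-distance snap 1e-8 mm; weld and T-junction tolerance 1e-6 mm.
* Plane-crossing solves: 33-point bracketing scan + 40 bisection steps
  (≈1e-10 mm); slot-width and length oracles assert at 1e-3 mm.
* Scale sanity windows: fibula 250–500 mm, mandible 80–160 mm longest
  extent — wide enough for anatomical variation, narrow enough to catch
  inch-scaled exports (÷25.4 lands far outside); warnings only, since
  unit checking is ultimately the operator's call.
* Eigenvector sign ties use a 1e-3 threshold: smaller cross-components on
  near-axis-aligned meshes are surface noise, not anatomy.
* Problem sizes in tests and the acceptance script (fixture tessellation
  48×~90 rings, 32-section Boolean primitives, ~1 mm validation sampling
  pitch capped at ~12k points) were chosen so the full suite and the
  script each run in a few minutes on one CPU while keeping every
  tolerance above meaningful at print scale.

## Known limitations

* Booleans between two arbitrary non-convex meshes are out of scope
  (disjoint pairs, convex pairs and piercing tools cover the pipeline);
  the kernel raises rather than approximating.
* Guide seating assumes locally star-shaped cross-sections; severe
  undercuts would require a mould-parting analysis the package does not
  attempt.
* One guide body per bone; the splitting of very long plane clusters into
  multiple bodies is not implemented (all clinical-scale plans tested span
  well under the distance where that would matter).
* Resection planes extended to infinity can, in principle, re-intersect a
  strongly curved arch far from the defect; the preview's sequential
  cutting keeps pieces disjoint but the geometry should be reviewed when
  planning near-posterior defects.
* No plate modelling, dental occlusion, vascular pedicle geometry, DICOM
  handling or print support generation.
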