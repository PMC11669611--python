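# Methods

## Scope and model

`seegplan` evaluates straight SEEG electrode trajectories against three
anatomical constraints — vessel clearance, insertion angle, and target
reach/passage — and aggregates them into a composite quality score. The
library is purely geometric: it starts from triangle meshes (brain surface,
vasculature, target regions) and never touches image data. Segmentation of
those meshes from T1w MRI and TOF MRA, VR rendering, and group-level
inferential statistics are out of scope.

All computation happens in patient-space millimetres with right-handed
coordinates and 0-based face indexing. Plans expressed in enlarged-model
("world") coordinates are divided by their `scale_factor` (default 6, the
usual enlargement for precision hand work in VR) before scoring, because the
clinical thresholds — 2 mm, 5 mm, 30° — are only meaningful at patient
scale. The one handedness flip a mirrored display pipeline may need is
exposed as `FrameTransform.mirror_x`, which also reverses face winding so
outward normals survive the reflection.

## Vessel clearance d

The trajectory is sampled at `n_key_points` uniformly spaced points from the
entry point to the electrode tip, both ends included (default 125 — on a
~10 cm trajectory that is sub-millimetre spacing, comfortably finer than the
vessel-mesh resolution; raising it is a config field). For each key point
the nearest vessel-model *vertex* is found, and d is the minimum over key
points. Measuring to vertices rather than triangle interiors reproduces how
interactive planners compute this figure and is the default; an exact
point-to-triangle mode (`distance_mode="exact"`) is available and never
returns a larger value. Vertex-mode overestimates d by at most about one
mesh edge length, which the tests bound as 2 × max edge length against the
analytic capsule ground truth.

Nearest-vertex queries run on a spatial hash grid: each vertex is bucketed
by `floor(coord / cell_size)` (default cell: 2 × the median mesh edge, which
keeps cells neither empty nor crowded). A query walks occupied cells in
order of Chebyshev shell distance from the query's cell and stops only when
the best distance found is no larger than the nearest point any unexplored
cell could contain, so the result provably equals the brute-force minimum —
a fixed 3×3×3 neighbourhood ("immediately adjacent cells"), which can miss
the true nearest vertex, is kept behind `mode="fixed"` for fidelity
experiments only. Two implementation details matter for speed, not
correctness: whole shells are gathered with one vectorised lookup over the
sorted occupied-cell codes, and a caller minimising over many queries can
pass an `upper_bound` to abandon provably hopeless queries early.
`min_vessel_distance` additionally prunes with a bounding box: a coarse
stride of exact queries gives an upper bound, and the final minimum is taken
over all vertices in cells within that bound of the key-point box.

## Insertion angle α

The entry point is the *outermost* crossing (largest ray parameter) of the
brain surface along the ray from the electrode tip through the entry marker
— an electrode arrives from outside the head, so with a folded surface the
last crossing is the physical entry. The angle is measured against the flat
normal of the crossed face, sign-oriented away from the tip; flat normals
keep the result deterministic, at the cost of a discretisation error that
equals the face-normal deviation from the smooth surface (≈ 3.6° worst-case
at icosphere subdivision 4, ≈ 1.2° at subdivision 5; the tests assert 2°
agreement with closed-form sphere normals at the resolutions where that
bound holds). α is clamped to [0°, 90°] for scoring.

## Scoring and validity

Clearance below 2 mm (hemorrhage risk) or angle above 30° (keyhole drilling
limit) rejects a trajectory outright; both boundaries are strict as printed,
so d = 2 mm and α = 30° are accepted with component score 0. Otherwise
f_d ramps linearly from 0 at 2 mm to 1 at 5 mm (beyond which risk reduction
plateaus), f_α from 1 at 0° to 0 at 30°, and f = 0.8 f_d + 0.2 f_α, the
heavier weight on clearance because intra-operative hemorrhage is the more
serious complication. Rejected trajectories carry no composite score — a
plan's score is the mean of f over accepted trajectories only, and is
flagged undefined when none are accepted. Scores are displayed at 3 decimals
with the raw value preserved. All thresholds and weights live in
`ScoringConfig` (there is no universal consensus on the criteria, so they
are data, not code); every report echoes the effective config.

Target validity uses ray-parity point-in-mesh tests on closed meshes: the
deep target must contain the electrode tip, and the shaft must pass through
the superficial target, decided from the sorted segment–mesh crossing
parameters (a graze with no interior interval does not count). When a
trajectory's superficial and deep targets are the same region — a real
configuration, e.g. an electrode implanted along the axis of one gyrus —
passage follows from reach. The parity ray re-selects its direction from a
fixed list when a hit lands within 1e-9 of a triangle edge, where parity
counting is unreliable. All violated constraints are reported, not just the
first, so a rejected trajectory's report is diagnostic.

Two auxiliary operations support plan review: `pairwise_clearance` computes
exact segment-to-segment distances between electrodes (warning below a
configurable 2 mm, mirroring the vessel margin, since electrodes must not
cross); `suggest_entries` scores the trajectory from a fixed endpoint to
brain-surface vertices (all of them, or an evenly strided subsample, default
500, chosen to keep an interactive-scale runtime) and returns the top
candidates by f, ties broken toward larger d and then lower vertex index so
the ranking is deterministic and — absent exact score ties — invariant to
vertex reordering.

## Synthetic phantoms

The phantom generator exists so that every geometric operation can be tested
against closed-form answers. A scene contains:

- **Brain**: an icosphere (default radius 70 mm, subdivision 4 ≈ 2562
  vertices) radially perturbed by a smooth sum of six seeded plane waves,
  normalised so the excursion never exceeds `surface_bumpiness` × radius
  (default 0.05; 0 gives an exact sphere with analytic normals). Radial
  perturbation preserves the icosphere topology, so the surface stays
  watertight.
- **Vessels**: smooth random-walk centerlines (fixed 4 mm step, turning
  clamped to 0.25 rad, an inward pull near the containment boundary) swept
  into capped tubes. Ring vertices sit exactly one radius from the
  centerline and the end caps are cone fans whose apices are pushed one
  radius out along the axis, so *every* tube vertex lies on the analytic
  capsule surface (within ~0.8% at gentle bends) — the capsule distance
  `capsule_min_distance` is therefore the exact ground truth for d.
- **Targets**: axis-aligned ellipsoid meshes (deep ≈ 7×5.5×5 mm, superficial
  ≈ 9×7×6 mm, roughly amygdala- and gyrus-sized), placed strictly inside the
  brain with a 2 mm margin.
- **Demo plan**: seven trajectories whose superficial/deep pairings mirror a
  typical left-hemisphere temporal implantation (amygdala, anterior and
  posterior hippocampus, parahippocampal, fusiform and posterior-cingulate
  targets; trajectory 2 targets the same region superficially and deeply).
  Deep-target centres sit at fixed fractions (0.35–0.52) of the brain radius
  along spread-out left-hemisphere directions; each trajectory leaves its
  tip along a direction tilted 8–20° from radial, and its superficial target
  is centred on the shaft so passage holds by construction. Trajectory 1 is
  *engineered*: a dedicated straight vessel runs parallel to it at exactly
  `engineered_clearance` (default 4 mm) capsule distance, and random vessels
  are resampled until they keep ≥ 3 mm from every demo trajectory (≥ 6 mm
  from trajectory 1), so the engineered vessel is unambiguously the nearest
  structure. With `surface_bumpiness = 0` each trajectory's insertion angle
  also has a closed-form ray–sphere value, recorded in the scene's truth
  table.

Randomness derives from one integer seed through fixed sub-streams (brain /
vessels / targets), so scenes are bit-reproducible and adding vessels never
perturbs the brain. What the phantoms deliberately do **not** emulate:
cortical folding (no multi-valued radial profile), vascular branching
topology, mesh noise or holes from real segmentation, and anatomically
realistic target shapes. Passing tests therefore demonstrate correctness of
the geometry and scoring, not robustness to segmentation artefacts — open
or self-intersecting clinical meshes should be repaired upstream (the
point-in-mesh test flags non-watertight inputs rather than guessing).

## Usability-study metrics

`score_sus` implements the standard System Usability Scale: 1-indexed odd
items contribute x−1, even items 5−x, summed and ×2.5 → 0–100 (68 is the
conventional usability benchmark). `score_tlx` implements raw ("RTLX")
NASA-TLX on 1–21 ratings: each dimension normalises as (x−1)·5 to 0–100 and
the overall score is the unweighted mean of the six; the pairwise-weighted
variant is deliberately not implemented. `endpoint_error` reports placed-vs-
intended endpoint centroid distance in world mm and, divided by the scale
factor, patient mm — at 6× enlargement, ~6 mm world-scale placement error
corresponds to ~1 mm, i.e. about one MRI voxel, at patient scale.

## Numerical choices and limitations

- Segment–mesh intersection is vectorised Möller–Trumbore with a 1e-10
  barycentric tolerance; duplicate hits on shared edges collapse at 1e-9 in
  the ray parameter.
- The expanding-shell termination bound uses the distance from the query to
  the faces of the explored cell box — conservative, hence exact for any
  cell size.
- Degenerate inputs fail loudly: zero-length trajectories, empty meshes,
  non-positive scales, out-of-range questionnaire items all raise typed
  errors; geometric failures during trajectory evaluation (tip outside the
  brain, ray missing the surface) are instead recorded as reject reasons so
  a plan report is always complete.
- Vertex-mode d is biased upward by up to ~one vessel-mesh edge; use
  `--exact-distance` when the vessel mesh is coarse.
- Test and demo problem sizes (icosphere subdivisions 3–5, 3–6 vessels,
  125–249 key points, 100–500 suggestion candidates) were chosen as the
  smallest sizes at which the discretisation-error bounds above are
  demonstrable; all scale linearly if raised.
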