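# Methods

This note documents the models, the numerical choices and the limits of
the `craniotome` toolkit. All lengths are millimetres; the shared frame is
right-handed, patient supine (+x left, +y superior, +z anterior).

## Synthetic phantom

The phantom stands in for segmented patient anatomy so every algorithm is
testable without data. It is deliberately geometry-generic: the craniotomy,
exposure and retraction algorithms operate on arbitrary triangle meshes,
so anatomical fidelity is not required for their correctness, and all
quantitative checks in the test suite are oracle-based rather than
anatomy-based.

- **Skull**: a thick spherical shell — an outer icosphere (default radius
  85 mm, subdivision 4, 5120 faces) plus an inverted inner icosphere
  (radius 85 − 6 mm, one subdivision coarser). The shell is watertight by
  construction; the two tables are distinct closed components, each of
  Euler characteristic 2. Radii approximate an adult head; the 6 mm
  calvarial thickness is mid-range for adult bone.
- **Brain**: an icosphere of radius 75 mm (inside the inner table) sliced
  by a plane — the Sylvian-fissure stand-in — into a frontal and a
  temporal lobe separated by a 2 mm gap. Each open slice is closed by a
  centroid-fan cap over its rim, giving the fissure-facing surface that
  the retraction spatula engages. The default plane passes through the
  brain centre with normal (0, √½, √½), i.e. tilted 45° between superior
  and anterior. The real fissure is a curved, interdigitated surface; a
  plane is a documented fidelity limit.
- **Vessel**: an open polyline standing in for the Circle of Willis /
  middle-cerebral-artery course, running through the temporal half of the
  brain. The segment between two designated waypoints is the M1 segment;
  its length is a configuration parameter (default 25 mm, mid-range for
  adults) because M1 length matters clinically when planning MCA-aneurysm
  approaches. The waypoint chain beyond the M1 origin is translated so the
  designated segment has exactly the requested length.
- **Target**: a point landmark placed on the vessel at a normalized arc
  length in [0, 1], around which the exposure module samples a small
  sphere (default radius 2 mm) — the "target sphere" a trainee would place.
- **Landmarks**: optic nerve and pterion as points. They support distance
  and visibility queries; they carry no geometry.
- **Templates**: four closed contours on the outer skull — two locations
  (a pterional site and a more frontal site) × two line widths (1 and
  2 mm) — mirroring the four-template tracing protocol used to assess
  drawing precision. Each is a circle of 15 mm geodesic radius (a typical
  pterional bone-flap size), sampled at 64 points and snapped to the
  skull mesh, so every template point lies on the discrete surface. The
  line width is carried in the template name; the metrics operate on the
  centreline. Hand-drawn clinician templates are not reproducible
  synthetically; circles keep the protocol while making oracle values
  computable.

Determinism: a fixed seed reproduces the scene bit-for-bit. Optional
Gaussian vertex jitter (default σ = 0, radial on the skull so the tables
cannot interpenetrate) exercises robustness; with jitter enabled only
vertex positions change across seeds, never topology.

## Head pose

Longitudinal inclination (about the left–right x axis) is clamped to ±90°
and transversal inclination (about the anterior–posterior z axis) to
±30°. The limits are stated as magnitudes in the requirements the module
models; the symmetric per-direction reading is adopted as the
anatomically neutral one. Clamping is idempotent and applied at
construction, so an out-of-range `HeadPose` cannot exist.

Composition order is a genuine free choice (a slider UI never states
one): the longitudinal rotation is applied first and the transversal
rotation acts about the head-fixed (intrinsic) anterior axis, i.e.
`R = Rx(longitudinal) · Rz(transversal)` about the pivot. The pivot
stands in for the head clamp and defaults to the skull centroid. Applying
a pose rotates every mesh, contour and landmark and the fissure plane, so
downstream stages stay consistent; rigidity is exact up to floating point.

## Craniotomy

1. **Projection.** Each drawn point is replaced by its nearest point on
   the outer table (brute-force exact point-to-triangle minimisation; the
   meshes are small enough that a spatial index is unnecessary). Points
   farther than 10× the snap tolerance (default 0.5 mm) are rejected.
   Consecutive projected points are joined by chords subdivided until
   every chord midpoint is within the snap tolerance of the surface and
   no chord exceeds half the median mesh edge length — the latter bound
   guarantees consecutive samples land on the same or adjacent faces, so
   no face transition is skipped.
2. **Barrier.** The mesh edges crossed between consecutive sample faces
   are collected as barrier edges; when two consecutive samples skip
   across a vertex, a breadth-first search in the face-adjacency (dual)
   graph bridges the gap so the barrier is gap-free. The contour is
   closed when its projected endpoints coincide within the snap
   tolerance. Self-crossing paths are rejected: any two path segments
   farther apart along the path than a window scaled to the sampling but
   closer in space than half the snap tolerance constitute a crossing.
3. **Region growing.** Breadth-first growth over face adjacency from the
   face containing the seed, never crossing a barrier edge. Growth
   exceeding a configurable fraction (default 50%) of the outer-table
   area aborts as a leak — the signature of a gap in the barrier. The
   result is independent of which interior face seeds it.
4. **Excision.** Region faces are removed; vertices are kept so indices
   remain valid. The new boundary of the cut mesh is exactly the set of
   edges between kept and removed faces, a subset of the barrier.

The barrier lives on mesh edges rather than on a re-meshed exact curve:
region selection is face-granular (≈ 17 mm² per face at the default
resolution), well below the millimetre precision scale of freehand
drawing. Exact re-meshing is a possible extension. Only the outer table
participates in growing and excision — the bone flap is taken from the
outside; on the shell phantom outer faces are identified by centroid
radius above the mean, and arbitrary meshes take a user-supplied face
mask. `through_cut` additionally removes the inner-table faces radially
beneath the region, producing the through-thickness opening that the
exposure stage needs (an outer-table-only cut would leave the inner table
occluding every sight line).

## Exposure

The simulator's human self-assessment in the microscopic view is replaced
by a quantitative proxy. Rays start at stratified-random points on the
target sphere (a golden-spiral lattice with seeded jitter, deterministic
per seed) and run to the microscope eye; a ray intersecting the cut skull
(Möller–Trumbore, vectorised over rays × triangles) counts as occluded.
Reported are the visible fraction, the minimum distance from the
eye–target segment to the hole rim (clearance), and the hole area (from
the region if available, else a centroid-fan over the largest boundary
loop). Enlarging a hole can only remove occluders, so for a fixed seed
the visible fraction is monotone in the hole. Because the sampling
lattice is seeded in world coordinates, a joint rigid transform of all
inputs reproduces the fraction only up to marginal rays at the hole rim
(a few per mille at the default ray count), not bitwise. Brain meshes are
excluded as occluders by default (evaluation happens after retraction);
they can be passed as extra occluders to model the unretracted state.
There is no endorsed threshold for "adequate" exposure; that judgement
stays with the user.

## Retraction

Each lobe mesh becomes one particle per vertex and one Hookean spring per
unique edge (rest length = initial edge length). Particles farther than a
fixation depth (default 15 mm) from the fissure plane are fixed,
anchoring the lobes — the stand-in for the brain's attachment. The
integrator is position Verlet with velocity damping:

    x' = x + (1 − damping)(x − x_prev) + a·dt²,   a = (F_spring + F_ext)/m.

Defaults — dt 5 ms, damping 0.02, stiffness 1 N/mm, particle mass 1 g —
are module choices tuned for stability (dt²·k/m = 0.025 ≪ 1), not
measured tissue parameters, and are documented as such. Divergent
positions raise a dedicated error naming dt and stiffness.

The spatula retracts a lobe under displacement control: lobe particles
within its influence radius (default 25 mm) are ramped linearly to the
requested displacement over the step budget, weighted by linear falloff
(1 − d/r) from the contact point, while the rest of the system relaxes
through the springs each sub-step. Displacement control matches the UI
semantics of pulling a retractor to a position and is unconditionally
stable at the boundary; zero amount is exactly a no-op. The lobes share
no springs, so retracting one leaves the other bitwise untouched. No
self-collision or brain–skull contact is modelled; a warning threshold
for excessive retraction is configuration only, with no endorsed default.

## Contour metrics

Both metrics resample the contours at uniform arc length (default step
0.5 mm; open contours keep both endpoints, closed contours wrap) and
measure distances by exact point-to-segment minimisation against the
*other* polyline — never sample-to-sample — so a value does not depend on
the other contour's sampling density. The surface DSC needs a TP/FP/FN
definition on curves, which the published formula leaves open; the
tolerance construction is adopted: a drawn sample within τ (default 1 mm)
of the template polyline is TP, otherwise FP, and template samples
farther than τ from the drawn polyline are FN. τ and the step are always
reported alongside the values. The Hausdorff distance is the symmetric
max-min over resampled points against the exact opposite polyline;
discretisation error is bounded by the step. Consequences verified by the
suite: DSC ∈ [0, 1], equals 1 on identical contours, 0 beyond τ
everywhere, monotone in τ; H is symmetric, zero on coincident contours,
rigid-invariant, and stable under step halving. Published cohort averages
from human tracings depend on an unstated tolerance and on hand-drawn
templates, so they are procedurally, not numerically, comparable.

## Pipeline and problem sizes

The `run` pipeline executes pose → craniotomy → exposure → retraction →
metrics on a saved scene, materialises every default into the persisted
config, and writes a manifest with SHA-256 hashes of all artifacts;
identical configs reproduce identical manifests. The acceptance script
uses the full-resolution phantom (subdivision 4: 6400 skull faces, ~3200
brain particles), 500 exposure rays and 200 retraction sub-steps; the
test suite mostly uses subdivision-3 scenes, which preserve every
topological and metric property while keeping the whole suite under a
minute. What passing tests show is correctness of the geometry and
dynamics on these phantoms; they do not certify anatomical realism of
segmented patient meshes, fissure curvature, tissue constants, or
drawing ergonomics.
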