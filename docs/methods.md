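# Methods

## Coordinate frame and units

All geometry lives in the head-first-supine patient DICOM frame: +x
patient-left, +y patient-posterior, +z patient-superior, origin at the plan
isocenter.  Every length is a centimetre; converters belong at I/O
boundaries, none exist inside the package.  The patient body is the rigid
frame of reference — couch and body meshes never move, and every machine
rotation is applied to the gantry model.

Pose composition for a beam is collimator spin about the beam axis, then
gantry rotation, then the couch rotation of the whole machine assembly,
then the isocenter shift as a pure machine translation.  The pinned sign
conventions are: gantry 0 places the source anterior, the gantry angle
increases toward patient-left (gantry 90 = source on the patient's left),
and a couch angle rotates the machine by the negative couch angle about
room-vertical.  None of these signs can be read off a published constant,
so they are guarded by a behavioural invariant instead: for a laterally
symmetric phantom with a midsagittal isocenter, the clearance map must
satisfy `clearance(g, c) = clearance(360−g, (360−c) mod 360)`.  Any flipped
sign in the chain breaks this mirror identity; the test suite checks it
over the full validation sweep at 1e-6 cm (observed deviation ~5e-14 cm).

## Clearance definition

The clearance between two structures is the minimum Euclidean distance
over *vertex pairs*, not over triangle surfaces.  This matches how body
contours exported from a planning system are consumed in clearance checks,
and makes exactness statements crisp (the objective is a minimum over a
finite set).  The consequence is a known overestimate of true surface
clearance of up to a local edge length — one of the reasons a safety margin
is mandatory on top of the calculation.  An exact point-to-triangle
refinement was deliberately not made the default, to keep the reported
numbers interpretable against the vertex-based definition.

Ties between equidistant vertex pairs are broken by the lexicographically
smallest index pair in the brute-force scan; the tree traversal returns the
identical distance but may report a different equidistant witness pair,
since provably suboptimal subtrees are pruned before their ties are seen.

## OBB trees and the branch-and-bound traversal

Boxes are fitted by PCA of the owned vertex cloud: covariance eigenvectors
ordered by descending eigenvalue (stable sort, ties by axis index), each
axis' sign fixed so its largest-magnitude component is positive, extents
tight along the chosen axes.  Convex-hull-weighted covariance was not used;
for distance pruning the boxes only need to be valid bounds, not minimal
ones.  Splitting is top-down through the box center, perpendicular to the
longest box axis, with a median fallback when the plane fails to separate;
leaves hold at most 8 vertices by default.

Box-pair separation uses the separating axis theorem's 15 candidate axes
(3 + 3 face normals, 9 edge cross products; degenerate cross products
skipped below an axis norm of 1e-12).  The distance lower bound between two
boxes is the largest projection gap over those axes *plus the
center-to-center direction as a 16th candidate*.  The gap along any unit
direction underestimates the box-pair distance, so the bound is sound; the
extra direction tightens it substantially for offset (corner-to-corner)
configurations, which is what drives pruning below 1% of the quadratic
pair count at 20 cm separations.  A sound lower bound — rather than an
iteratively-converged "exact" box distance, which yields upper bounds until
convergence — is what makes the branch-and-bound provably lossless: a pair
is pruned only when its bound already meets the best vertex-pair distance
found, so the returned minimum equals the quadratic scan bit-for-bit.  Both
code paths share one squared-distance kernel to keep that equality exact in
floating point.

Traversal is deterministic: best-first over a heap keyed by lower bound,
the bulkier internal node expanded first, children inserted
nearer-bound-first with insertion order breaking ties.  Boolean
margin queries can optionally stop at the first pair inside the margin, in
which case the reported distance is only an upper bound; early exit is off
by default so that reported minima support closest-pose reporting.

The margin comparison is strict (`distance < margin` is a collision): a
pose at exactly the margin is safe.  The near-collision band is half-open,
`margin <= d < margin + 10`.

## Machine model

The gantry head is rebuilt parametrically: a casing profile of
(height, circumference) pairs linearly interpolated over the 14 cm of
casing nearest the face, plus cylindrical face projections (two locking
pins and a horseshoe tray insert by default).  Tessellation density is
derived from a target vertex count of 1639, the size of the reference CAD
model this reconstruction emulates; the default build lands at 1637
vertices.  The face-to-isocenter distance defaults to 40 cm — a documented,
machine-specific placeholder that users are expected to adjust, and that no
test treats as ground truth.  Everything behind the modeled casing band is
absent, so clearances larger than the modeled extent are not meaningful.
Couch structures are cuboid composites (flat couch top, or a board with a
narrower head extension continuing superiorly).

## Registration

Auxiliary structures are aligned translation-only to extremal coordinates:
add-on posterior datum to the body's posterior extreme, lateral midline to
the midpoint of the body's lateral extremes, and superiorly either mating
the add-on's top face to the body's inferior extreme (body additions,
extending a chin-to-crown scan) or placing the add-on's superior extreme at
the body's superior extreme minus a head offset (couch structures).  The
add-on-side datums are declared in a JSON sidecar rather than inferred,
because the correspondence between add-on features and body extremes is a
design choice, not something the extremes themselves determine.  Rotational
registration is excluded: couch-mounted hardware shares the patient frame
axes, and translation-only placement is reproducible.  Overlap between a
registered add-on and the body is reported as a warning (an extent-based
proxy; vertex clouds cannot detect surface interpenetration) and fixed with
a numeric manual offset.

## Trajectory sampling

Arcs are sampled on a start-anchored lattice (default 5°) with both control
points always included, wrapping through 0/360 along the travel direction.
Between-sample collisions are not detected — the discrete step is part of
the method, and the safety margin absorbs the residual risk.  Body and
couch are scored as separate targets with separate witnesses; one
collimator angle is used per beam.  The maximum-bounds search scans the
full 72-angle lattice at one couch angle and returns maximal circular runs
of safe angles.

## Validation model

The measurement generator draws `measured = max(0, true + e)` with
`e ~ N(−0.2, 0.7²)` clipped to ±2.9 cm.  Bias, spread and worst case are
the agreement statistics observed when this class of clearance software was
compared against physical caliper measurements over a full couch/gantry
sweep; the clip encodes that no larger discrepancy was observed.  Actual
collision in a margin sweep means `measured <= threshold` with threshold
0 (contact).  The equality matters: the measurement floor at zero makes a
strictly-negative reading impossible, so contact itself is the observable.
Under this model a 3 cm margin can never miss a collision (an actual
collision requires an error at least as large as the calculated clearance,
and errors are bounded by 2.9 cm); the suite verifies zero false negatives
across 100 seeded campaigns.  At margins below the worst-case error —
including the 1.5 cm value that sufficed physically — the synthetic model
does not guarantee 100% sensitivity, because it spreads the worst-case
error over all poses instead of concentrating small errors near contact the
way the physical system did.  That is a fidelity limit of the synthetic
campaign, not of the margin logic.

Derived rates follow the standard definitions, with NPV reported as unity
whenever there are no false negatives.  Table percentages round half-up to
one decimal.  Strict metric computation raises on undefined denominators;
margin sweeps use the vacuous-truth convention so saturated margins still
produce curve points.

## Synthetic data

Phantoms are schematic by design: a tessellated cuboid on an
immobilization board for calibration-style sweeps, and an ellipsoid head +
cylinder neck + box chest for the upper-body cases, all laterally
symmetric with defaults of realistic clinical scale (30×20×20 cm cuboid,
~40 cm shoulder width, 2 cm mesh edge length — the order of a planning
system's contour resolution).  Scenes are deterministic per seed and
byte-stable on disk.  The collision demonstration scene is constructed so a
body lattice vertex coincides exactly with the gantry face center at gantry
zero, then verified by brute force at build time.  Passing tests on these
phantoms demonstrates correctness of the geometry, kinematics and
classification pipeline — not anatomical fidelity, caliper physics, or any
specific machine's true clearance map.

## Problem sizes and numerical choices

Test and acceptance runs use meshes of order 10²–10³ vertices per
structure (phantom ~800, board ~4000, head ~1600), full 72-angle arcs, and
the 13-angle couch sweep; these sizes exercise every code path while
keeping a complete run in tens of seconds.  Key tolerances: rotation
orthonormality 1e-8, box containment inflation 1e-7 cm, degenerate SAT axis
cutoff 1e-12, mirror-symmetry assertion 1e-6 cm, scene export round-trip
1e-4 cm (STL stores float32; at ~50 cm coordinates quantization alone is
~2e-5 cm).  STL welding is exact-coordinate, so the logical vertex set is
tolerance-free; OBJ I/O is handled as plain v/f records so that vertices
unreferenced by faces — meaningful here, where meshes are point clouds —
survive a round trip.

## Known limitations

Vertex-pair clearance overestimates surface clearance on coarse meshes;
discrete arc sampling misses between-sample poses; the head model covers
only the casing band nearest the face; imaging arms, electron applicators
and couch translations are not modeled; the synthetic phantoms carry no
anatomy.  All are absorbed by, and argue for, the clinical safety margin.
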