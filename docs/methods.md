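# Methods

This note documents the model behind `spindlegraph`: what each measure
assumes, how the open design points were resolved, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Input model and standardization

A spatial graph is a set of 3D polylines (one per traced microtubule) with
per-edge integer labels.  An edge with a nonzero `KMT` field is a
kinetochore microtubule; a positive `KFiberID` assigns it to a k-fiber.
Only the ASCII AmiraMesh dialect is supported — binary files are rejected
with an explicit message.  Pole coordinates may be carried in the
`Parameters` block (`SpindlePole1`/`SpindlePole2`, written by the
generator); absent that, poles are estimated as the two hemisphere
centroids of the poleward KMT endpoints.  Coordinates are assumed to be in
nanometres unless the configuration says micrometres; everything internal
is nm.

Standardization before measurement:

1. **Resampling** to uniform 20 nm arc-length spacing.  Resampled points
   lie exactly on the original polyline; endpoints are preserved exactly.
   Tracks shorter than one spacing collapse to their endpoints and are
   flagged degenerate.
2. **Reorientation** by a single proper rotation + translation taking
   pole 1 to the origin and the pole-to-pole axis onto +z (configurable).
   This realizes the convention that both poles share their off-axis
   coordinates.  Reflections are never applied: twist and helicity are
   chiral and a reflecting "alignment" would silently flip their signs.
3. **End assignment.**  Each KMT belongs to the pole nearest either of its
   ends; its plus end is the end farther from that pole along the spindle
   axis.  This encodes the biology (KMT plus-ends terminate at
   kinetochores, minus-ends point poleward) rather than any ordering of the
   file.  Exact ties go to the first point and are flagged.
4. **K-fiber construction.**  Members are sampled every 500 nm of arc from
   their plus ends; the fiber center at step k is the member mean, and the
   curve is truncated once fewer than two members remain.  A single-member
   fiber keeps its own resampled track as the center curve.  A fiber whose
   members disagree on pole association is an error, not a warning — it
   indicates broken labels.
5. **Sister pairing.**  Opposite-pole fibers are paired when mutually
   nearest by plus-end centroid and antiparallel (pole→centroid directions
   within a 60° cone of opposition).  "Facing each other" is not further
   operationalized by the source material; mutual-nearest-plus-cone is this
   package's choice, and ambiguous fibers stay unpaired rather than being
   force-matched.

## Measures: conventions and numerics

**Twist.**  The printed formula for the per-step angle (an arctangent of
two 2D vectors) is not well defined as a scalar expression; it is
implemented as the signed planar angle
`atan2(n·(r_i × r_{i+1}), r_i · r_{i+1})`, which is numerically stable at
small angles and carries the correct sign.  The plane normal `n` is the
local center-curve tangent, oriented along the pole1→pole2 axis so that
positive twist is a right-handed rotation about that axis everywhere in the
spindle.  For each step pair the participating members are those present at
*both* steps, and the center used for the radial vectors is recomputed over
exactly those members — centering on all available members would let a
member ending between two steps shift the mean and manufacture twist in a
perfectly straight bundle.  The fiber's local twist is the member mean; the
total twist is the sum of local twists (so a randomly zig-zagging fiber
cancels toward 0°).

**Helicity** is measured in a different frame than twist, deliberately:
the azimuth of the fiber *center curve* about the *pole-to-pole axis*,
accumulated along the curve and divided by the center-curve arc length
(deg/µm).  Twist uses the fiber-center frame, helicity the pole-axis frame;
both are reported.  Because the azimuth accumulation is signed along the
traversal (plus end → pole) while the reference axis is global, the same
physical handedness yields opposite helicity signs in the two half-spindles.
Center-curve points closer than 1 nm to the axis contribute no azimuth (a
straight on-axis fiber has helicity exactly 0).  For an ideal helix the
estimate approaches 360/pitch as radius/pitch → 0; at finite radius the
center-curve arc exceeds the axial extent by √(1 + (2πρ/p)²), which is the
dominant bias term (≈1.8 % at ρ/p = 0.03).

**Cross-section area** uses a 2D alpha complex built on
`scipy.spatial.Delaunay`: triangles with circumradius ≤ α are kept and
their areas summed.  α = ∞ keeps every triangle and therefore reproduces
the convex-hull area exactly; the area is monotonically non-decreasing
in α.  Plane–polyline intersections are linearly interpolated on the
segment that crosses the plane (the crossing nearest the fiber center if
there are several); a member merely tangent to the plane contributes its
nearest point when within half the resample spacing.  Fewer than three
in-plane points yield NaN, not zero — a two-KMT "area" of 0 would make the
derived density infinite and is better reported as undefined.  Density is
the in-plane member count divided by the area, reported per µm².

**Branching and interactions** use segment-exact distances (point to the
polyline's segments, never to its sampled vertices); with a 25 nm detection
threshold, vertex-sampled distances at 20 nm spacing could err by up to
half a spacing and are not acceptable.  A cKDTree over all track points
prefilters candidates with a radius enlarged by the longest segment in the
graph, which provably cannot miss a polyline within the threshold; every
candidate is confirmed exactly, so the accelerated result is identical to
brute force (and is tested to be, against independently coded oracles).
Ties in "closest microtubule" break toward the lower id for deterministic
output.  Interaction runs are accounted on the source side: the reported
position and length are arc lengths on the source track; each direction of
a pair is reported, so the pair relation stays symmetric.  Local tortuosity
uses contiguous windows of the same 500 nm step as twist (the window and
stride are configurable).

## Parameters

| name | default | unit | rationale |
| --- | --- | --- | --- |
| `resample_spacing` | 20 | nm | finest spacing the tracing supports; tracks are uniform after resampling |
| `twist_step` | 500 | nm | step of the twist/area/density profiles |
| `tortuosity_window` | 500 | nm | local-tortuosity window, aligned with the twist step |
| `alpha_radius` | ∞ | nm | convex hull unless a concave cross-section is requested |
| `sister_cone_deg` | 60 | deg | opposition cone for sister acceptance |
| `branch_threshold` | 25 | nm | minus-end-to-lattice distance counted as branching |
| `interaction_threshold` | 100 | nm | proximity distance counted as interaction |
| `units` | nm | — | input coordinate unit (`um` supported) |

## The synthetic generator

The generator emulates the geometry the measures assume: two poles 10 µm
apart on the z axis, kinetochore pairs on a metaphase plate (1.5 µm radius
by default, optional bounded axial jitter), sister plus-end centroids
separated by 1 µm, KMT bundles on a 100 nm circle around each kinetochore,
KMT lengths from a truncated normal (3.5 ± 0.8 µm), ~30 background
microtubules, and 5 nm isotropic Gaussian tracing noise per node.  When a
helix pitch is set, the whole fiber cross-section pattern rotates rigidly
about the pole-to-pole axis by 360° per pitch of axial distance — a single
construction under which the fiber center curve is an ideal helix about the
spindle axis *and* every member's radial vector about the fiber center
rotates at the same rate, so both twist (360·step/pitch per step) and
helicity (±360/pitch) have closed forms to recover.

Noise is applied at the generated 100 nm node scale, before the 20 nm
resampling.  This matters: independent per-point noise at the final 20 nm
spacing would inflate arc lengths by ~17 % (white-noise bias of polyline
length), which no tracing pipeline exhibits; at the node scale the bias is
under 1 %.

Planted branch events move a chosen KMT minus-end to a drawn distance
(5–20 nm) perpendicular to an *interior* segment of a nearby track —
terminal segments are excluded because a track's end node may legitimately
move later (its own planting, or the clearance pass).  After planting,
every other KMT minus-end is checked against a 30 nm clearance and nudged
away if necessary, so the planted set is exactly the set of true branch
events in the emitted file, and the recorded ground-truth distances are
re-measured on the final geometry.

What the generator does **not** emulate: curved (non-helical) fiber
shapes, KMT detachment and mid-spindle plus-ends, section-boundary
stitching artifacts, variable point density, false-positive/negative
tracing errors, or pole-proximal fiber splaying.  Tests passing on
synthetic spindles therefore validate the geometry pipeline and its
estimators, not robustness to segmentation pathology.

## Known limitations

* Fiber membership must come from labels; there is no de-novo clustering of
  KMTs into fibers.
* The center curve is undefined (truncated) where fewer than two members
  remain, so profile measures do not cover the last partial step of a
  fiber.
* Helicity's sign convention (global pole1→pole2 axis) makes the two
  half-spindles report opposite signs for the same physical chirality;
  consumers comparing halves should fold the sign by pole, as the per-fiber
  `pole_id` column allows.
* Interaction lengths are quantized at the resample spacing (run extent of
  in-threshold sample points).
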