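# Methods

## Scope and model

`crosshairsim` models the geometry of scanner-frame reproduction by a laser
crosshair simulator, as a chain of proper rigid transforms between six frames
(world, headset, tracked target, reference image, simulator, scanner). All
transforms are stored as homogeneous 4×4 matrices with the last row
(0, 0, 0, 1); the convention is column vectors, `p' = R p + t`, with `T[A→B]`
mapping coordinates expressed in A into B and the product `T2 · T1` applying
`T1` first. Units are millimetres throughout; frames are right-handed; patient
axes follow LPS (x left, y posterior, z superior). Only rigid motion is
modelled — no scaling, no projective camera, no soft-tissue deformation.

Rotations are parameterized for construction and optimization as rotation
vectors (axis-angle, radians): minimal and singularity-free near the identity,
which is where every optimization in the package operates. Constructors
re-project near-orthonormal rotation blocks onto SO(3) by polar decomposition
when within 1e-6 of orthonormal and reject anything farther, as well as any
reflection; matrices already orthonormal to 1e-12 are kept bit-identical so
that serialized transforms round-trip exactly.

## Simulator and reference-plane geometry

The rig holds two emitters at a configurable 400 mm stand-off (top emitter
above, side emitter to the +x side). Each projects two fan planes containing
its boresight; the two crosses share a coplanar centreline, so the four fans
span exactly three planes, stored per reference-plane role: *sagittal* (normal
x), *coronal* (normal y, the shared plane), *axial* (normal z). A rig is
*intrinsically ok* when the distinct planes are mutually orthogonal and the two
coronal fans coincide within 1e-9. Emitter miscalibration is modelled as a
rotation of the whole emitter about its mount (position fixed), which keeps
each fan containing its boresight; perturbations are capped at 0.2 rad, the
small-angle regime in which the screw-adjustment procedure is meaningful. The
stand-off distance does not affect the plane geometry of a calibrated rig.

Laser curves on a surface are plane–mesh intersections computed by
`trimesh.intersections.mesh_plane`, chained into polylines by endpoint matching
(endpoints rounded to 1e-6 mm), clipped to the *laser-visible side* — segments
whose generating face's outward normal has positive dot product with the
direction toward at least one illuminating emitter — and resampled at a fixed
arc-length step (default 0.5 mm; arcs shorter than twice the step are dropped).
Full ray-cast occlusion is deliberately not performed: the half-space test
matches lines drawable on the upper/front scalp, is deterministic, and costs a
dot product. Scanner-marked skin lines use the same machinery with the same
visibility convention (sagittal lines lit from above, axial from the side,
coronal from both), so marked and projected curves are directly comparable.

## Curve misfit

The alignment score between two labelled curve sets is the symmetric mean
closest-point distance: every vertex of one side is measured against the
polyline segments of the other, in both directions, pooled over labels. The
mean (rather than Hausdorff) form gives a smooth optimization landscape;
a symmetric Hausdorff variant is available as a diagnostic. Distances use an
expanded closed-form point-to-segment formulation evaluated with matrix
products; its cancellation floor is ~1e-7 mm at head-sized coordinates, far
below every tolerance in the package but the reason "identical curves" tests
assert < 1e-6 rather than exact zero.

## Calibration

**Sphere.** The calibration sphere (default radius 60 mm) stores three
orthogonal great-circle planes (colour roles red/blue/black mapped to
sagittal/coronal/axial) and three small-circle planes, each sharing its
colour's normal at the tangency offset `d = R/√2` — the offset at which two
small circles on orthogonal planes meet in exactly one point on the sphere
(`z² = R² − 2d²`), verified independently by root counting. Enumerating all
per-colour {great, small} choices and testing mutual orthogonality yields the
8 calibration positions (1 primary, 7 secondary). Arcs are represented as full
circles for residual computation: the physical arcs are partial, but the full
circle is a strictly stronger constraint and has closed-form point-to-circle
distances.

**Intrinsic.** Securing the sphere at a position means the selected marked
planes coincide with the rig's nominal laser planes; with sphere axes aligned
to the SCS this puts the centre at minus the selected offsets. The residual at
a position is the mean distance from sampled points of each fan's projection
circle (180 samples/circle) to the same-colour marked circle. Calibration
minimizes the residual at the primary position only, with a derivative-free
Nelder–Mead simplex over the per-emitter correction rotation vectors
(6 parameters; tolerances xatol 1e-9 / fatol 1e-13, up to 3 restarts), then
evaluates all 8 positions, the seven secondary ones acting purely as held-out
verification — mirroring the physical procedure. Convergence is declared at a
worst-position residual below 1e-3 mm; failure raises with the final residual.
The residual depends on the images of two orthonormal vectors per emitter, so
the 6 parameters are fully observable and the zero-residual rig is unique.

**Extrinsic.** The target-to-image transform is recovered by 6-DOF least
squares (Levenberg–Marquardt on rotation vector + translation) on the distances
from the transformed virtual great-circle sample points (default 500/circle) to
the physical circles of the sphere at the primary position. The initial guess
must lie in the convergence basin (about 20 mm / 15° in simulation); the
discrete 180°-flip ambiguities of the three-circle figure are outside it.
Observation noise is modelled as isotropic per-point Gaussian on the virtual
samples.

## Deployment

Pose recovery minimizes the labelled curve misfit between the rig's projection
and the marked lines over the 6-DOF rig pose, with a seeded multi-start
Nelder–Mead (default 4 starts: the initial guess plus perturbations inside half
the 10 mm / 10° basin; adaptive simplex, xatol 1e-5, plus one polishing run at
1e-6). The manual physical alignment has no algorithmic counterpart, so this
operation is package-defined plumbing grounded in the same alignment criterion.
Inside the optimizer a fast path is used: marked curves are recoarsened to a
~1.5 mm step (chord-sag bias ≲ 0.01 mm, well under the recovery tolerance) and
scored against raw intersection segments without polyline chaining; the
reported misfit is always the public curve-misfit on fully chained, 0.5
mm-resampled projections. A candidate pose whose plane misses the mesh receives
a constant penalty of 10× the mesh extent. On success the simulator-to-scanner
transform is the identity by convention; the residual misfit is reported,
never absorbed.

Constraint analysis uses a central-finite-difference 6×6 Hessian of the
*squared* misfit (the smooth form) at a pose; steps 2e-3 rad / 0.2 mm. On a
generically curved surface all six eigenvalues are positive; a single crosshair
on a flat plate leaves translation along the surface normal (the boresight)
unconstrained, which surfaces as a null eigenvalue with eigenvector along that
axis. Because rotations are in radians with ~100 mm lever arms, the spectrum
spans ~4 orders of magnitude even at full rank; rank tests therefore compare
the smallest eigenvalue against 1e-6 of the largest, orders of magnitude above
the flat-plate null level.

## Curvature sensitivity

The experiment projects the top-emitter crosshair onto paraboloid patches
`z = (x² + y²)/(2ρ)` (apex curvature radius ρ, circular aperture default
80 mm), once at the nominal pose with the SCS origin at the apex and once
tilted about the oblique in-plane axis `(1,1,0)/√2` so both fans are affected,
and reports the misfit between the two projections per radius. To first order
the lateral shift of a fan's curve is `α·z`, i.e. `α·r²/(2ρ)`: misfit grows
linearly in tilt and inversely with curvature radius, which is the
degrees-of-freedom argument for why tightly curved regions anchor the pose.

## Synthetic phantom

The head is a superellipsoid (exponent 2.5, half-axes 75 × 95 × 85 mm, jittered
±2% per seed) over an icosphere topology (subdivision 4, 2562 vertices), with a
Gaussian-profile paraboloid nose (height 22 mm, angular width 0.22 rad)
protruding anteriorly below the equator — a deliberately small-curvature-radius
feature — plus a mild seeded left–right asymmetry. It is watertight and genus
zero by construction. Six fiducials are mesh vertices on the upper head chosen
by seeded rejection sampling with a 55 mm minimum pairwise separation; they are
evaluation-only landmarks. The scanner pose places the reference-image origin
at the head centroid plus a uniform ±10 mm offset and a random-axis tilt up to
5°, emulating arbitrary gantry positioning. The default scan geometry is a
251 × 251 mm field of view on a 128 × 128 matrix with 0.625 mm slices
(in-plane spacing 1.9609 mm, quoted as 1.96). Every generator is a pure
function of (parameters, seed).

What the phantom does *not* emulate: real scalp anatomy and texture, skin
shift, imaging distortion, segmentation error, tracking jitter, or rendering
latency. Passing tests therefore demonstrate the *geometric consistency* of
the method — that with exact inputs the pipeline closes to machine precision,
and that each stage degrades gracefully and recoverably under controlled,
parameterized error — not the accuracy attainable with physical hardware.

## Evaluation protocol

Per-point TRE is the 3D Euclidean distance between reference and probed
fiducial, with signed per-axis components retained; the per-axis RMSE
aggregate is also reported, since both forms circulate as "TRE". The simulated
protocol nests registrations × sessions × markers (default 3 × 3 × 6 = 54):
each registration draws one rigid bias (per-axis Gaussian rotation-vector and
translation components) standing in for deployment error, each probe adds
isotropic Gaussian perception noise. Under pure isotropic noise σ the TRE is
chi-distributed with 3 degrees of freedom (mean `2σ√(2/π)`), which is the
package's noise-calibration check and the bridge between simulated output and
the millimetre accuracy band reported for physical systems. Summaries use the
sample standard deviation (n−1). The whole-head error extrapolation fits a
proper rigid `T_PQ` by Kabsch/SVD (det +1 enforced, collinear configurations
rejected at a 1e-9 relative singular-value threshold) and maps per-vertex
displacements on the mesh by the corresponding-vertex convention. The one-way
ANOVA is the classical fixed-effects F on (k−1, N−k) degrees of freedom
(scipy), with the all-identical degenerate case defined as F = 0, p = 1.

The freeze/unfreeze state machine snapshots the live image-to-world transform
into an anchor; an optional isotropic Gaussian random walk on the anchor
translation (off by default — no measured drift rate exists, the magnitude is
a placeholder) models holographic drift, and unfreezing discards it, as loop
closure would.

## Problem sizes and seeds

Default sizes were chosen so each stage is comfortably over-determined while
the full suite and the acceptance script each complete in about a minute on one
CPU: 2562-vertex head meshes (tests that exercise many deployments use the
642-vertex subdivision-3 variant), 0.5 mm curve sampling, 180 samples per
calibration circle, 500 per extrinsic circle, 1000 random chains for the
algebra check, and ~10,000 probes for the noise-calibration statistic. All
stochastic components take explicit integer seeds (`numpy.random.default_rng`);
the calibration module's default seed is 20231107.

## Known limitations

* Visibility is a half-space test, not occlusion-accurate ray casting; deeply
  concave surfaces could mark lines a physical laser could not reach.
* The deployment optimizer is local multi-start, not global: initial errors far
  outside the configured basin can fail (and report failure) rather than
  recover.
* Extrinsic calibration assumes the discrete symmetry flips of the circle
  figure are excluded by the initial guess.
* The drift model is translation-only and rate-unspecified.
* Reported accuracies of physical mixed-reality systems include headset
  tracking, display and perception errors that this geometric framework
  deliberately does not model.
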