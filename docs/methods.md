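# Methods

`endogeo` reconstructs the geometry of a stereo-endoscopic scene offline:
it tracks the camera with a feature-based stereo SLAM front end, densifies
each keyframe with ZNCC stereo matching, fuses the per-keyframe clouds into
a world-frame surface mesh, and exposes geometry-aware AR operations
(picking, labels, on-surface measurement, area highlighting) on that mesh.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic study does and does not demonstrate.

## Camera model and conventions

The rig is rectified: both pinhole cameras share intrinsics
(f in pixels, principal point), and the right camera sits a baseline
B (mm) along the left camera's +x axis. Corresponding points share an
image row, and depth follows from the disparity d = x_l − x_r by similar
triangles:

    Z = f · B / d.

Coordinates are right-handed, camera looking down +z, image origin
top-left, pixel centers at integers. Quaternions are scalar-first and
camera-to-world; increments compose on the right (camera side). The world
frame is the first camera frame of a run; initialisation is simply "the
first trackable frame defines the map" with zero initial velocity.

A minimum-disparity cutoff (0.5 px) rejects near-infinity points: the
depth sensitivity dZ/dd = Z²/(fB) diverges as d → 0.

## Tracking

Per frame the pose is predicted by the constant-velocity model

    r_{t+1} = r_t + v_t Δt,   q_{t+1} = q_t ⊗ q(ω_t Δt),

with accelerations defaulting to zero (they are carried in the state and
can be finite-differenced behind a config flag, which preserves the full
four-row update). Landmarks of the local map (the last 3 keyframes) are
re-projected through the predicted pose; each landmark gets a square
search window (radius 15 px; 3× on the first tracked frame, when no
velocity estimate exists) and is matched to the frame's ORB features by
best Hamming distance inside its window (threshold 80 of 256 bits,
conflicts resolved best-first).

The matched pairs (landmark world point, stereo-triangulated camera
point) feed a 3-point RANSAC whose minimal solver is the closed-form
SVD/Kabsch alignment; hypotheses are scored by the per-pair residual
norm against a 1.5 mm threshold, the iteration budget adapts by the
standard 0.99-confidence formula (cap 500), and the best hypothesis's
inliers are refined with the full closed-form solver. Because the
alignment maps current-camera points onto world points, the estimated
transform *is* the camera-to-world pose. RANSAC is also the mechanism
that rejects moving specular points, mismatches and locally deforming
tissue: they land in the outlier set and never touch the pose.

The 3D-3D estimate inherits stereo depth noise (≈4 mm per pixel of
disparity error at the default rig and 100 mm depth). A motion-only
refinement therefore follows: damped Gauss-Newton on the 6-dof pose
minimising the Huber-robust reprojection error of the inlier landmarks.
Pixels are measured an order of magnitude more precisely than
triangulated depths, and this step reduces per-frame pose error from
~1 mm to ~0.1 mm in the synthetic study.

## Features and specular filtering

ORB detection/description is delegated to scikit-image; stereo matching
is mutual-best Hamming over packed 256-bit descriptors, filtered by the
rectified-row tolerance (±2 px) and the positive-disparity requirement.
Matched disparities are refined to sub-pixel by a 1D ZNCC parabola fit
along the epipolar row — depth resolution scales directly with disparity
resolution, so this cheap step matters for everything downstream.
Keypoints brighter than 240/255 are discarded as specular: saturated
highlights are view-dependent and violate the static-scene assumption.
Frames with fewer than 20 surviving matches are flagged untrackable.

## Keyframes and bundle adjustment

A tracked frame becomes a keyframe when the fraction of keypoints shared
with the last keyframe drops below 0.80 while more than 50 keypoints are
tracked. One calibration sits between the rule and the measurement: a
binary-descriptor matcher re-finds only a fraction of keypoints even with
*no* view change (~0.78 for this stack), so the raw shared fraction
underestimates true view overlap. The pipeline estimates that same-view
recall on the first frame after each keyframe (smoothed across keyframes)
and divides the measured fraction by it before applying the unchanged
0.80/50 rule. Without the correction every frame qualifies as a keyframe
regardless of motion.

Keyframe insertion triggers a windowed bundle adjustment (last 5
keyframes by default; global optionally) minimising the Huber-robust
reprojection cost

    Σ_{i,j} ρ_h( ‖ p_{i,j} − CamProj(KF_i, P_j) ‖ ),

with ρ_h quadratic below δ = 2 px and linear above. Observations are
stereo triples (u_l, v, u_r): projecting into both rectified cameras
pins the scale that left-only reprojection leaves free (a monocular BA
with a free pose can slide all depths and the baseline coherently; the
right-camera column removes that gauge). The optimiser is an
iteratively-reweighted Gauss-Newton with Levenberg damping on sparse
normal equations; rotations are updated by local 3-parameter increments
composed onto the quaternion and renormalised. A step is accepted only
when the robust cost decreases, so the cost trace is monotone by
construction, and the first keyframe of the window is the gauge anchor,
left bit-identical. Landmarks observed once stay out of the problem.
New-landmark policy: stereo features a keyframe cannot match to the map
are triangulated and added.

## Dense reconstruction

Dense matching runs at keyframes only. The matching score is the
patch ZNCC (7×7 patches by default)

    C(p, d) = Σ (I_L − Ī_L)(I_R − Ī_R) / sqrt( Σ(I_L − Ī_L)² · Σ(I_R − Ī_R)² ),

invariant to affine intensity changes of either patch — the property
that matters under endoscope lighting. The volume stores cost = −ZNCC
(lower = better; asserted in tests) and is computed with box filters on
full-width shifted images, so the cost per disparity slice is independent
of patch size. The default disparity range is [1, 64] px; the pipeline
narrows it per keyframe to the sparse features' disparity bracket ±5 px,
which both speeds the volume and removes most gross mismatches.

Winner-takes-all takes the per-pixel argmin (ties break toward smaller
disparity) with parabolic sub-pixel refinement. Unreliable pixels are
masked by three standard checks, all free given the volume: minimum ZNCC
confidence (0.3), left-right consistency (the right image's WTA disparity
is read from the same volume via C_R(x, d) = C_L(x+d, d); disagreement
beyond 1.5 px marks occlusion), and a 3×3 median speckle check. The map
is then smoothed by minimising the Huber-L1 energy

    E(u) = Σ_p H_ε(∇u(p)) + λ C(p, u(p)),

via quadratic relaxation: Huber-weighted (lagged-diffusivity) smoothing
of u coupled to an auxiliary map a, alternated with an exact point-wise
search of the cost volume for a, with the coupling θ annealed downward.
The candidate with the lowest true energy across iterations is returned,
so the energy never exceeds the WTA initialisation's (asserted). The
point-wise search includes the off-grid candidate a = u, which makes a
flat data term exert no pull (the pure-regulariser limit flattens the
map, the λ→∞ limit returns WTA exactly). Defaults: λ = 2, ε = 0.5 px,
θ annealed 2 → 0.05 over 12 outer iterations.

Valid pixels back-project through Z = fB/d to a camera-frame cloud
(stride 2 by default — the fusion voxel grid needs no denser input), and
a statistical outlier filter (mean 16-NN distance beyond 2σ) removes the
sparse floating points that survive the 2D checks; these few points
otherwise dominate the squared-error surface metric.

## Fusion and meshing

Each keyframe cloud is moved to world space by the keyframe's pose
(T_f2w) and merged into the global cloud on a 1 mm voxel grid (one
centroid per voxel), so re-observed tissue collapses to a single
representative and the fused size is bounded by scene area, not run
length. The fused cloud is triangulated by projection onto its dominant
PCA plane followed by 2D Delaunay, lifting the triangles back to 3D.
Triangles with an edge much longer than the local sampling distance are
dropped (holes stay holes); the allowance is slope-aware — where vertex
normals tilt away from the projection axis the threshold grows by
1/cos(tilt), clamped at 10× — since projection legitimately compresses
steep regions. Vertex normals come from local PCA plane fits (k = 20),
oriented toward the observing camera. Re-meshing happens at finalisation
by default (per-keyframe optionally); the construction is well posed for
camera-facing sheets, which is what an endoscope sees, and is not a
general-purpose closed-surface reconstructor.

## Geometry-aware AR

Picking casts the pixel's viewing ray against all triangles
(vectorised Möller–Trumbore, nearest positive hit) and returns a surface
anchor: face id, barycentric coordinates, position and interpolated
normal. The mesh re-projection layer is a software z-buffer rasteriser
with perspective-correct (1/z) depth interpolation. Labels orient their
plane by the anchor normal, with in-plane spin fixed by projecting the
camera up-vector at placement time.

On-surface measurement is a shortest path in a graph over mesh vertices
plus edge midpoints (Steiner points), with every node pair inside a face
linked, plus links between all nodes of edge-adjacent face pairs; the
across-pair chords cut the graph-metric overestimate of geodesic length
to ~1%. Duplicate graph entries are deduplicated by minimum weight
(sparse COO construction would otherwise sum them). The Dijkstra path is
then shortened by iterative midpoint pulls re-projected onto the mesh
(closest-point queries via per-triangle region classification), accepted
only while the length decreases — the result is a surface polyline, so
its length can never undercut the straight-line chord. Area highlighting
runs a single-source Dijkstra from the seed anchor and sums the areas of
faces whose mean node distance is within the radius.

## Synthetic ground-truth study

The generator emulates the conditions that make endoscopic stereo hard
while keeping every quantity exact:

* **Geometry** — an analytic height field: a broad dome (25 mm high,
  organ-scale: the principal structure spans ~140 mm, matching an average
  liver diameter of 14.0 cm) plus 10 seeded Gaussian bumps (≈4 mm), at a
  nominal 100 mm working depth.
* **Appearance** — multi-octave value-noise albedo (contrast 0.55, enough
  corner structure for ≥500 ORB keypoints per 840×640 frame), Lambertian
  shading, and a strong Phong specular term (exponent 60) that saturates
  into moving highlights.
* **Illumination** — a spot light co-located with the camera with cosine
  cone falloff and inverse-square distance attenuation, as on an
  endoscope.
* **Trajectory** — a smooth hovering sweep (sinusoidal, ±18 mm lateral,
  ±7 mm in depth, ±4° rotation), the regime in which a constant-velocity
  model is a good short-horizon predictor. 300 frames at 840×640 are the
  default study length.
* **Rig** — f = 500 px, B = 5 mm, principal point at the image center:
  disparities fall in the 12–50 px range over the 50–200 mm working depths.

Rendering is exact per-pixel ray casting against the height field
(Newton iteration on the ray parameter, warm-started along the
trajectory; the fixed point is independent of the start), so the
ground-truth depth is consistent with the surface to machine precision
and the rendered disparity obeys Z = fB/d identically.

Evaluation: the reconstructed world-frame surface is grid-sampled at
2 mm spacing over the central half of the scene extent against the
analytic truth, and compared by

    RMSD = sqrt( (1/mn) Σ_x Σ_y (Z_xy − z_xy)² )

over covered samples (coverage is reported; below 50% a warning is
raised). No alignment step is needed beyond the identity: stereo SLAM is
metric and the world frame is anchored at the first camera. Trajectory
quality is an absolute-trajectory RMS after rigid (no-scale) alignment.

What the study does not emulate: tissue deformation (respiration,
heartbeat), instruments and smoke, blood, rolling shutter, calibration
error, and photoreal tissue appearance. Passing it therefore shows the
pipeline's geometric machinery is correct and accurate under realistic
scale, texture, speculars and lighting — not that it is robust to
non-rigid in-vivo scenes, where the only defence implemented is RANSAC's
rejection of non-rigidly moving points.

## Problem sizes and determinism

The bundled benchmark (scripts/acceptance.py, also exercised by the
acceptance tests) uses the 300-frame default study at 840×640; it runs in
roughly 11 minutes on one CPU with keyframe-only dense matching (~23
keyframes). Unit tests run the same machinery at 420×320 with short
trajectory excerpts. All stochastic components (scene, RANSAC) draw from
seeded generators; a fixed config and seed reproduce trajectories and
clouds bit-for-bit.

## Known limitations

* Tracking has no relocalisation: after a tracking-loss the next frames
  re-match against the stale local map with widened windows, which
  recovers from brief losses only.
* The mesher assumes a locally single-valued sheet; undercuts and
  closed cavities are out of scope.
* The Huber-L1 smoother is a convergent relaxation scheme, not a
  primal-dual solver; it honours the energy-descent contract but may
  stop short of the global optimum on strongly non-convex cost columns.
* Keyframe-rate normalisation relies on the same-view recall estimate;
  a matcher with drifting recall (e.g. under heavy motion blur) would
  shift the effective keyframe cadence.
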