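# Methods

This note records the models, parameter choices and numerical decisions
behind `bovimetry`, and what the synthetic experiments do and do not
demonstrate about real scans.

## Coordinate conventions

All clouds live in the sensor frame: x right, y **down**, z along the range
axis, metres. The camera never states which axis is vertical, so the
pipeline takes the fitted ground plane — not an axis — as the height datum;
the default synthetic rig has −y up. ToF sensors emit invalid pixels; loaders
drop non-finite rows and log the count rather than erroring, and an organized
(176×132) grid survives loading only when every pixel was valid.

## Filter fusion

The three filters run in a fixed order: pass band → statistical outlier
removal (SORF) → voxel grid (VGF).

* Pass band: strict inequalities on x ∈ (−1.25, 1.00) and z ∈ (1.50, 3.00) m;
  y unconstrained. The bounds are the working envelope of the reference rig.
* SORF: d̄ᵢ = mean distance to the `mean_k` = 60 nearest neighbours,
  excluding the point itself; points with d̄ᵢ > μ + 1.0·σ are removed.
  One-sided (only sparse points are outliers); σ is the population standard
  deviation; a relative 1e-12 epsilon keeps perfectly uniform clouds intact
  when σ underflows.
* VGF: 3 cm cubic voxels anchored at floor(coordinate/leaf), one centroid
  per occupied voxel — deterministic and order-independent. Centroids, not
  voxel centres, preserve the surface position.

## Segmentation

Euclidean cluster extraction is connected components of the graph linking
points within 5 cm (the paper-era name "K-means" for this step is a
misnomer — there is no cluster-count parameter anywhere; region growing by
distance is what the tolerance/min-size parameters describe). Clusters under
50 points are discarded. RANSAC plane fitting draws 3-point hypotheses
(default 1000 iterations, early exit at 90% inliers, 2 cm inlier distance),
then refits the winning consensus set by total least squares (smallest
eigenvector of the inlier covariance) for stability. Only the single best
plane is removed: the rig views one floor.

## Descriptors and matching

Normals come from k = 30 nearest-neighbour covariance (smallest-eigenvalue
eigenvector), oriented toward the viewpoint; neighbourhoods whose second
eigenvalue vanishes (relative 1e-9) yield NaN normals that later stages skip.

FPFH uses the standard Darboux frame (u = source normal, v = d̂ × u,
w = u × v; α = v·n_t, φ = u·d̂, θ = atan2(w·n_t, u·n_t)) with 11 bins per
angle; FPFH(p) = SPFH(p) + (1/k) Σ SPFH(p_k)/‖p − p_k‖, each block
renormalised to percent.

The global VFH is stored as `[viewpoint 128 | α 45 | φ 45 | θ 45 | dist 45]`
= 308 components. The shape component pairs the cluster centroid (with the
mean normal) against every point; the distance block is ‖p − c‖ normalised by
its maximum, making the descriptor scale-invariant; the viewpoint component
histograms cos(normal, centroid→viewpoint) into 128 bins. Each sub-histogram
sums to 100. Putting the viewpoint block first is an internal convention and
is recorded in the serialized library header.

Matching is nearest-descriptor Euclidean distance; small distance = similar;
a cluster matches iff its minimum distance ≤ threshold. The threshold is
data-driven: each library cluster is jittered (σ = 5 mm, 5 repeats), and the
threshold is the mean + 2σ of the resulting intra-class distances. Measured
on the synthetic rig, same-condition rescans sit at descriptor distance
~25–30, jitter-calibrated thresholds at ~50, and unrelated shapes (noise
spheres) far above — but descriptors are *not* invariant across photographic
distance or sensor distortion, so a library must be built from scans of the
same rig and working range it will classify.

## Registration

ICP with point-to-point error and mutual (bidirectional) kd-tree
correspondence filtering: a pair survives only if each point is the other's
nearest neighbour and within 0.10 m (tests of large initial offsets widen
this). The least-squares step is the cross-covariance SVD with a det(R) = +1
reflection guard. Convergence is an RMS change below 1e-6 m or 50 iterations.
No initial-alignment stage is provided; scans are assumed roughly pre-aligned
by the sensor pose, which the synthetic experiments respect.

Known limitation: on coarsely voxelised inputs, where both clouds share a
near-regular 3 cm lattice, any ICP variant can lock a fraction of the leaf
size away from the optimum (observed ~12 mm). Registration accuracy claims
are therefore verified on dense scans (doubled sensor resolution, ~5 mm
sampling): there the implementation recovers a 10°/5 cm motion to ~0.01° /
0.2 mm at σ = 2 mm noise, and 60%-overlap scans register to a median
closest-point distance below 5 mm.

## Surface reconstruction

MLS fits a Gaussian-weighted (h = search radius, default 5 cm) reference
plane per point, then a bivariate polynomial (default order 2) of heights
over that plane, and projects the point onto the fitted surface; neighbour-
starved points fall back to order 1, then to plane projection, and are
logged. The procedure reproduces planes exactly and roughly halves Gaussian
surface noise at the default densities.

Greedy projection triangulation projects each point's neighbourhood
(radius min(0.10 m, 2.5·d_nn)) onto its tangent plane, Delaunay-triangulates
locally, and keeps triangles incident to the point that pass the angle
bounds (10°–120°) and the 45° surface-angle bound. A triangle enters the
mesh when at least two of its three vertices propose it, and a final greedy
pass refuses any triangle that would give an edge a third face — so the
output never contains non-manifold edges, by construction. A deterministic
1e-7-relative jitter (triangulation only; vertices are untouched input
points) breaks cocircular ties so regular grids triangulate consistently in
every local frame. GPT parameter defaults were chosen once to triangulate
the 3 cm-voxel clouds the pipeline produces and frozen.

## Measurement and distance correction

Heights are unsigned point-to-ground-plane distances of the picked
landmarks; chest depth is the height difference between the chest top and
the brisket bottom (vertical convention); body length is the distance
between the ground-plane projections of the shoulder point and pin bone.
Landmark picking is by coordinates (config/CLI or phantom landmarks) rather
than interactive clicking.

The correction model is multiplicative: corrected = raw × s(d). This form is
forced by the published worked examples: within each of the three reference
scenes the five corrected/initial ratios agree to a relative spread of
~1e-5, so whatever correction produced them acted as a single per-scene
scale. s(d) is a polynomial in the photographic distance d of degree
min(2, #distinct distances − 1) — three distances determine a quadratic
exactly. d is the mean z of the segmented target cloud, matching the
published per-scene scalar distances. Positivity of s over the calibrated
range is validated at construction.

## Synthetic scenes

The generator emulates the reference rig: 60°×45° aperture, 176×132 pixels,
per-pixel ray casting against analytic primitives, Gaussian range noise
(default σ = 2 mm) along the ray, uniform outlier pixels (default 80), and a
tripod camera pitched 20° down at about withers height. The quadruped
phantom realises the five body dimensions *exactly* in its landmark table
(defaults 1.57, 0.65, 1.56, 1.59, 1.60 m — an adult-steer scale); its torso
is three overlapping ellipsoids that pinch the topline at shoulder, back and
loin. Two shape concessions keep the *scan* (not just the geometry)
connected, because Euclidean clustering at 5 cm must see a path from topline
to floor: below the brisket line the torso is slab-sided and the legs are
full-width slabs flush with it (a convex belly pinches to a point and leaves
a depth jump bigger than the tolerance), and the leg slabs are yawed 12° so
their side faces are not sampled at grazing incidence (SORF removes
too-sparse grazing points and would sever the ground contact).

The injected range distortion defaults to the quadratic through the three
published (photographic distance, corrected/initial ratio) pairs — the
empirically observed sensor behaviour. Distortion is applied as a per-scene
range factor k solving k·s(k·m) = 1 with m the subject's pipeline-measured
mean range, which makes s exactly the measured-distance → correction law the
calibration procedure estimates; the root is unique (k·s increasing) and
found by bisection. Scene placement targets the requested photographic
distance but keeps ≥95% of the subject inside the pass band: with the 45°
vertical aperture, a 1.6 m subject plus its ground contact cannot sit wholly
inside the band closer than ≈1.67 m, so the default scene settles there —
within the 1.55–1.79 m range of the reference scenes.

Calibration scenes scan cuboids and spheres at eight distances with small
random lateral offsets. Cuboid widths are measured as the front-face x
extent plus one pixel footprint; the pixel phase makes individual cuboid
observations uncertain by ~±2.5%, which the sphere observations (algebraic
least-squares fit, ~±0.1%) and distance averaging pull down to a fitted-law
error under 1% across the calibrated interior.

## What the synthetic results do and do not show

End-to-end on the default distorted scene, corrected dimensions land within
~0.1–0.7% of ground truth across seeds (the acceptance script prints the
realized values). That validates the *chain*: segmentation isolates the
subject, the plane datum is right, the photographic-distance convention is
self-consistent, and calibration undoes the injected distortion. It does not
bound errors on live animals: the phantom has exact landmark coordinates
(no manual-picking variance), does not move, has no hair or specular
artifacts, and its distortion follows the injected law by construction.
Published live-animal deviations of up to ~2% should be read as the
practical regime; the synthetic numbers are a lower bound from an idealised
subject.
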