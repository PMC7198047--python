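# Methods

This note records the models, numerical choices, and open design decisions
behind `woundmetrics`, and what the synthetic validation does and does not
demonstrate.

## Geometry model

Cameras are ideal pinholes after undistortion (even-order radial k1,k2,k3 +
tangential p1,p2 coefficients; an empty list means no distortion).  Pixel
coordinates are 0-based with the origin at the centre of the top-left
pixel, x right / y down.  Camera frames are right-handed with +z into the
scene; the reference frame is the left camera.  The stereo rig is assumed
parallel after rectification (Fusiello-style: both image planes rotated to
a common orientation whose x-axis is the baseline), so matching is a 1-D
row search and triangulation reduces to `Z = f·b/d`.  Reconstruction
resolution follows `ΔX = 2D·tan(FOV_H/2)/C_H`, `ΔY = 2D·tan(FOV_V/2)/C_V`,
`ΔZ = D²/(f·b)`; lateral resolution is linear and depth resolution
quadratic in the working distance D.

Dense matching is zero-normalized cross-correlation over square windows
(default 11 px) along the epipolar row, with a 3-point parabola fit over
the correlation peak for sub-pixel disparity.  Pixels with peak correlation
below 0.7 or without local texture are masked invalid.  Projector
calibration treats the projector as an inverse camera: 3D positions of
projected checkerboard corners are obtained by intersecting projector
pixel rays with a known plane over several plane poses; a DLT estimate of
the 3×4 projection matrix (RQ-decomposed into intrinsics and pose) seeds a
Levenberg–Marquardt re-projection refinement.  Correspondences coplanar in
aggregate are rejected as rank-deficient.

## Segmentation

The clinician's coarse contour initializes a two-phase Chan–Vese level set
on grayscale intensity (the refinement is intensity-based; color-aware
refinement would be an extension).  Defaults: λ1 = λ2 = 1, tol 1e-3, at
most 500 iterations, and length penalty μ = 0.05.  μ deserves a note: the
usual μ ≈ 0.25 is appropriate when objects span hundreds of pixels; at
this package's validation scale a wound is only 60–120 px across and
μ = 0.25 measurably erodes lobed boundaries (≈1–2% of perimeter and
projected area on the irregular phantom), so the default favours boundary
fidelity.  The largest connected component overlapping the initialization
is kept; a uniform image (no two-phase partition) raises a refinement
error and callers fall back to the coarse polygon.

The surrounding-skin band — the reference region for the skin plane — is
the wound region grown isotropically until the enclosed area reaches 1.5×
the wound area, implemented exactly via the Euclidean distance transform
(the nearest `0.5 × area` outside pixels), not by iterated 3×3 dilation
whose per-step granularity is too coarse for small regions.  Everything
beyond the band is background and ignored.

## SOM surface fit

The wound mesh is a rectangular self-organizing map whose node weights are
3D coordinates: the fixed grid topology guarantees a hole-free quad-mesh,
and node averaging suppresses reconstruction noise.  Training is online
Kohonen learning in two phases:

* **ordering** — 10 shuffled passes; learning rate 0.5 → 0.01 and Gaussian
  neighbourhood radius max(r,c)/2 → 1, both decaying exponentially;
* **convergence** — 3 passes at fixed radius 0.5 and rate 0.05.

The convergence phase matters quantitatively: after the ordering phase
each node's position is an average over a several-cell neighbourhood, which
biases curved surfaces toward their tangent planes (a 6 mm spherical cap
read ≈2.4% low in volume without it).  The map is initialized as a planar
grid spanning the cloud's two leading principal directions; if the trained
map is folded in its parameter plane (mixed quad orientations), training
restarts once from a jittered initialization.  Fits are bit-reproducible
for a fixed seed.

Two border treatments compensate the known SOM boundary contraction
(border nodes settle roughly half a map cell inside the data support).  By
default the border ring is mirror-extrapolated outward by half the local
grid step.  When the sub-pixel wound contour is available — in the
pipeline it always is, from the 0.5 iso-contour of the refined mask,
bilinearly lifted through the point grid — the border ring is instead
pinned to that 3D contour at the end of every epoch.  Pinning uses a
monotone arc-length assignment: each border node takes the arc parameter of
its nearest contour point and the parameter sequence is made cyclically
monotone by pool-adjacent-violators.  Plain nearest-point snapping can fold
the border where the wound has tall interior walls (on the trapezoid
phantom it inflated the 3D area by ~19%); monotone pinning removes the
artifact while letting interior columns migrate onto the walls.

The pipeline clamps the requested grid (default 64×64) to
`floor(sqrt(N))` per side so the map never has more nodes than samples.

## Clinical parameters

The skin plane is the total-least-squares plane of the skin-band points
(smallest principal component of the centred points), oriented so the
wound interior has positive signed distance (toward −z if no wound points
are given).  Depth is the maximum signed plane distance over mesh
vertices, clamped at zero (hypergranulation above the skin plane is out of
scope).

**Perimeter.**  The wound boundary is traced on the mask with
Moore-neighbour tracing under Jacob's stopping criterion (stop when the
start pixel is re-entered from its original entry direction; the largest
component is traced if several exist), lifted to 3D through the pixel map
(invalid pixels bridged), and summed as a closed polyline.  Two bias
corrections are applied, with defaults fixed by a bias analysis on known
shapes (axis-aligned and rotated squares, circles, the irregular phantom
outline): (i) anisotropic circular smoothing — σ = 1.0 samples in the skin
plane removes the digital staircase (up to +7% on diagonal boundaries)
while preserving corners, and σ = 3.0 along the plane normal suppresses
the length inflation that uncorrelated per-point depth noise causes
(E[√(a²+Δz²)] > a); the true out-of-plane profile of a wound rim is
smooth, so the stronger normal smoothing is benign; (ii) a `+2π·(s/2)`
offset, s the lateral sample spacing, because the traced chain runs
through pixel centres half a sample inside the region boundary, and
offsetting a smooth simple closed curve outward by d lengthens it by
exactly 2πd regardless of shape.

**Areas.**  The 3D area is the mesh quad sum — per quad, half the sum of
|e_row × e_col| at the (r,c) corner and at the opposite corner — which
agrees with a two-triangle decomposition to well under 1% on smooth
meshes.  The projected area rotates the wound points so the skin plane is
the x-y plane, drops z, and takes the area of the 2D alpha shape
(Delaunay triangles with circumradius ≤ α).  Default
α = 2 × the 99.5th percentile of nearest-neighbour spacings — the upper
quantile, not the median, so Poisson-like sampling gaps do not punch
spurious holes — and α auto-grows by 1.5× (with a warning) until every
point is enclosed.  The polygon is Minkowski-buffered by half the sample
spacing to restore the half-pixel rim that point sampling of a filled
region removes (the pixel-counting measure).  Main axes are the extents
(max − min of projections) of the projected points along their two
principal directions; variance-based definitions were rejected because
the axes should span the wound.

**Volume.**  The cavity is closed into a watertight surface: the
triangulated mesh, a wall joining the mesh boundary ring to its orthogonal
projection onto the skin plane, and a planar cap fanned from the projected
ring centroid — the plane acting as the constraint that keeps the closure
from collapsing into the cavity.  Closure is topological (surface, wall
and cap share vertices by index), so coincident snapped vertices cannot
break watertightness; the volume is the magnitude of the signed-tetrahedron
sum.  A strongly non-star-shaped boundary ring could make the cap fan
self-intersect; wound footprints in practice (and all phantoms) are far
from that regime.

## Tissue classification

Classification runs on CIELAB chroma only: dropping L makes the features
exactly invariant to lightness manipulation, which is the defence against
shadows.  (Note that dimming in *RGB* also shrinks chroma magnitude — only
the hue direction is preserved — so the features are robust to shading
through the superpixel averaging, not magnitudes alone.)  SLIC superpixels
(k-means in (L,a,b,x,y) with a compactness prior, default one superpixel
per 200 wound pixels) partition the wound; k-means on superpixel mean
(a,b), with centroids initialized at the seed pixels' chroma, labels each
superpixel with the seed class its centroid descends from.  k equals the
number of tissue classes the clinician seeds (1–3).  Composition weights
every wound pixel by its local 3D surface-area element (cross product of
the lifted point grid's central differences), so steep, foreshortened
regions contribute their true share of the wound bed.

## Registration and AR overlay

The registration marker is modelled as a 12 × 8 mm checkerboard whose 3×2
inner corners are the fiducials (corner detection in real images is
pluggable; synthetic tests supply pixel coordinates).  Fiducials are
triangulated per visit from the rectified pair; the previous→current rigid
transform is the SVD (Arun) least-squares solution with reflection
correction, and the stored perimeter (or classification splats) is
re-posed and rasterized into the projector image plane, clipping points
outside the frustum.  Overlay accuracy is scored physically: each lit
projector pixel casts a ray that is intersected with the skin surface, and
the mean 3D distance from the hits to the true current perimeter is
reported.  The synthetic device uses the published-class hardware numbers:
2208×1242 cameras with 80°/54° fields of view, 45 mm baseline, an 854×480
projector offset 50 mm and toed in toward the working distance.

## Evaluation statistics

Accuracy is the signed relative deviation (percent); aggregated accuracy
over a study is the mean of absolute values.  Precision is the coefficient
of variation σ/|x̄| (sample SD).  Inter-rater reliability is ICC(2,1) —
two-way random effects, absolute agreement, single measure — computed from
the mean squares `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)` and
cross-checked in the tests against an independent variance-components
implementation and against `pingouin`.  Repeatability is 2.77 × the
within-subject SD from one-way ANOVA (2.77 = 1.96·√2, the bound expected
to cover 95% of test–retest differences).

## Synthetic phantoms and what the validation shows

Each phantom is an analytic depth field z(x, y) ≥ 0 over a footprint curve
on an exactly flat skin plane (printed phantoms are plate-mounted; curved
skin is not part of the accuracy suite).  Ground truths are closed-form
where possible (spherical cap; ellipse perimeter via the complete elliptic
integral; paraboloid volume πabd/2), exact per-triangle sums for the
piecewise-linear trapezoid, and converged 0.01–0.02 mm midpoint-grid
integration otherwise; the integrator is validated against the closed
forms it overlaps.

Two deliberate design choices concern the depth maxima.  The trapezoid's
ramp ends in a 2 mm flat landing at maximum depth, and the irregular
phantom's field is compressed near its maximum so the peak has zero slope:
a knife-edge crease or point maximum cannot be recovered to 2% by *any*
averaging surface fit at 0.1–0.2 mm sampling, so the phantoms make the
stated maxima resolvable features.  Likewise the default circular phantom
is a 6 mm-radius, 3 mm-deep spherical cap rather than a full hemisphere: a
vertical rim tangent concentrates ~15% of the true surface area in the
last 0.1 mm of lateral sampling, which no laterally sampled height field
can represent.  The full hemisphere remains available
(`make_phantom("circular", radius=6, depth=6)`) and exercises the
closed-form machinery.

The sampler emulates the per-pixel 3D reconstruction as a lateral grid
(default 0.2 mm) with i.i.d. Gaussian depth noise (default σ = 0.1 mm) —
finer than a real rig's raw ΔZ at working distance because the SOM in the
real device averages many raw points per node; the fixtures validate the
pipeline, not the sensor.  What the synthetic suite does *not* emulate:
spatially correlated disparity noise, specular highlights and exudate
gloss, occlusions and self-shadowing, curved limbs, and real marker/corner
detection.  Passing the phantom suite therefore demonstrates the
correctness and internal biases of the algorithms, not end-to-end clinical
accuracy.

The multi-rater simulation models rater variability as an independent
acquisition per (rater, phantom) cell — a small random device tilt and a
fresh noise draw whose magnitude grows with the jitter parameter — so
ICC(2,1) is exactly 1 at zero jitter and decreases monotonically with it.
Working distances and perspective resampling are not simulated (the
lateral grid is phantom-fixed), which is why rigid pose enters only
through the geometry, not the sampling pattern.

## Problem sizes

The validation protocol uses 4 phantoms × 10 seeded acquisitions at 0.2 mm
spacing (≈3–7 k wound points each, SOM grids 53–64 per side), noiseless
0.1 mm sampling (≈20–26 k points) for the depth-recovery checks, and 100
Monte-Carlo trials for the AR overlay; the whole protocol runs in a few
minutes on one CPU.  Unit tests use coarser spacings and smaller grids.

## Known limitations

* Multi-component wounds: only the largest connected component is
  measured; undermining/tunneling is out of scope.
* Depth is clamped at zero above the skin plane (no hypergranulation).
* The cap fan of the volume closure assumes a roughly star-shaped
  boundary ring.
* Chan–Vese runs on intensity; tissue classes with skin-like luminance
  could weaken refinement on real images.
* The SOM allocates nodes by point density, so extremely steep walls are
  represented more coarsely than face-on regions.
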