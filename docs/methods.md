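# Methods

This note records the model, the numerical choices and the synthetic study
conditions behind `earaam`, at the level of detail a maintainer needs to
judge what the package's tests do and do not demonstrate.

## Landmark scheme and atlas

The 91-point scheme is frozen in `src/earaam/data/scheme.json`: outer helix
rim clockwise from the front lower attachment (0–35), inner helix edge
(36–55), antihelix ridge (56–67), conchal rim (68–75), tragus (76–79),
antitragus (80–81), and the nine-point earlobe contour last (82–90).  The
sources describing the 91-point convention do not tabulate which index
belongs to which structure, so this ordering is the package's own canonical
choice; every consumer reads indices from the scheme file and nothing
downstream hard-codes them.  The region atlas expresses each of the nine
auricular regions as a polygon over landmark indices (the earlobe over the
reconstructed points P₁…P₉), and records the standard's sub-area counts
(helix 12, antihelix 13, conchae 18 combined — bookkept as 6 cymba + 12
cavum, fossae helicis 6, triangular fossa 5, tragus 4, antitragus 4,
earlobe 9).  The acupoint registry is an approximation: the national
standard's coordinates are not reproduced anywhere accessible to this
package, so acupoints are anchored as relative positions (bounding-box
fractions, or earlobe sub-area ids) inside their host region and are fully
user-replaceable via JSON.  The 91 points are treated as geometric
landmarks; acupoints are a layer on top.

## Shape model

- Landmark weights: wₖ = (Σᵢ Var‖aₖ − aᵢ‖)⁻¹ summed over **all** other
  landmarks.  A literal reading in which only the distance to landmark 1
  enters is kept behind `weight_mode="to_point1"`; `"uniform"` disables
  weighting.  If every variance is zero (identical training shapes) the
  weights fall back to uniform with a warning rather than diverging.
- Procrustes: each shape is aligned to the evolving mean by the W-weighted
  similarity transform (closed-form linear least squares); the mean is
  recentred, scaled to unit centroid size and — to pin the rotational
  gauge — rotated so its centroid-to-first-landmark direction is at angle
  zero.  Convergence: RMS mean change < 1e-7, at most 300 iterations.  The
  gauge makes `procrustes_align` invariant to a common similarity transform
  of all inputs; `EarShapeModel.fit` then rotates the converged frame to
  the training data's circular-mean orientation so that placing the mean
  shape in a detection box yields an upright initialization.
- PCA retains the smallest mode count reaching 98% cumulative eigenvalue
  fraction by default (`variance_retained`); an absolute eigenvalue floor
  discards numerically null modes so that degenerate training sets yield
  empty bases.  Tangent-space projection is available behind a flag and off
  by default.
- `project_shape` solves pose and weights as one linear least-squares
  problem in the inverse direction (T⁻¹(lm) = mean + B w, in which the
  inverse-pose parameters enter linearly); when the basis is overcomplete
  enough to overlap the similarity gauge, the residual-minimizing solution
  of minimal weight norm is taken.

## Appearance model

- Reference frame: mean shape scaled so its bounding box's longest side is
  150 px (≈10⁴ texture pixels), with a 3 px margin.
- Triangulation: Delaunay over the 91 reference landmarks.  The canonical
  template's outline is convex, so the hull contains no redundant exterior
  triangles and the shipped exclusion list is empty; pruning remains fully
  config-driven (sorted vertex triples), and exact slivers are dropped
  automatically.  Point-location ties on shared edges go to the first
  triangle in lexicographic order.
- Warping: per target pixel, triangle membership and barycentric
  coordinates are precomputed once; a warp from any source shape is a
  barycentric combination of source vertices followed by bilinear sampling
  (`scipy.ndimage.map_coordinates`, nearest padding).  Color images are
  reduced to luminance 0.299R + 0.587G + 0.114B.  More than 5% of target
  pixels mapping through degenerate source triangles aborts the warp.
- Texture normalization uses the population standard deviation, the only
  reading consistent with an output variance of exactly 1; a constant
  texture raises instead of dividing by zero.

## Detector

HOG (8×8 cells, 2×2 blocks, 9 unsigned bins, L2-hys) + `LinearSVC` over a
96×96 window, pyramid factor 1.25, stride 16, NMS at IoU 0.3.  Positives
are square crops around the calibration box (side 1.05·max(w,h)) so the
training geometry matches the square sliding window; detections are
converted back to the mean training aspect ratio before reporting.  The
mean shape is fitted into the reported box isotropically (larger-fit rule,
centred) — no anisotropic stretch, which would invalidate the shape
statistics.

## Fitting

The global 4-DOF similarity is folded into the linear parameterization
s(p) = s_ref + Q p, where Q's first four orthonormal columns are the scaled
mean, its 90° rotation and the two translations (scale and translation
exact, rotation first-order), followed by the shape modes orthogonalized
against them.  The project-out inverse-compositional loop precomputes the
mean-texture gradients chained with the warp Jacobian, projects out the
appearance modes and Cholesky-factorizes H (with a trace-scaled ridge if
near-singular).  Per iteration: warp + normalize, Δp = H⁻¹Jᵀr,
inverse-compose (first-order: apply −QΔp to the reference landmarks, map
them through the current piecewise-affine warp with barycentric extension
outside the hull, re-project onto Q), then refresh λ′ in closed form.

Numerical choices: max 50 iterations; `tol_shape` = 1e-4 in units of the
reference shape's centroid size (≈0.05 px of landmark motion);
`tol_residual` = 1e-6 relative; up to 4 step halvings when a step increases
the projected-out residual.  A proposal rejected at every halving means the
accepted update is zero, which is below any shape tolerance — the fit then
terminates on the tolerance criterion at its local minimum.  The best-
residual iterate is returned, so the accepted-iterate residual trace is
non-increasing.  Reported pose and shape weights come from re-projecting
the final landmarks through the shape model; because rotation is
linearized in Q, `shape_instance(weights, pose)` reproduces the landmarks
to well under a pixel rather than to machine precision.

Fitting itself is deterministic.  `EarAAM` fits coarse-to-fine with 2
levels by default: the first pass runs on a Gaussian-smoothed image
(σ = 4 px) against an appearance model trained on equally smoothed images,
which widens the convergence basin of the box initialization; the last
level is the raw image.  A single-level fit is `n_levels=1`, and
`fit_aam`/`AAMFitter` remain single-resolution primitives.

## Earlobe geometry

Endpoint extension keeps the adjacent segment's length and repeats the
neighbouring vertex's turning angle, so a straight contour extends
collinearly and a circular one stays on its circle; this keeps the
endpoint bisectors consistent with the interior ones (a collinear
extension would degrade the two end segments of a circular lobe).
Interior-angle bisectors define each segment's polar origin; the branch of
θ is chosen with |Δθ| ≤ π; near-parallel bisectors (or an origin at an
endpoint) fall back to linear interpolation for that segment, logged.
kₙ = 10 interpolation points per segment by default.  P₅ is the first
maximal-depth point along the contour; chords at depths h/3 and 2h/3 are
intersected with the densified polyline exactly, taking the two crossings
flanking the apex; P₄/P₆ bisect the arcs by arclength.  The nine-area
division splits each chord at its third-points and continues the outer
connections below P₃P₇ along their last direction until they meet the
contour; cells share edges, so the tiling conserves area up to numerical
error.  Self-intersecting region polygons fall back to their convex hull
with a warning flag.

## Synthetic study conditions

The generator emulates the data regime the method targets: 500×500 images,
an ear occupying most of the frame, 91 exact ground-truth landmarks.
Shapes are the canonical template deformed by four fixed smooth fields
(width stretch, lobe growth, vertical shear, bulge/twist; RMS amplitudes
3.0/2.5/2.0/1.5 px) plus similarity jitter (scale ±8%, rotation ±0.1 rad,
translation ±12 px) — moderate anatomical variation, chosen once as
plausible for adult ears photographed head-on.  Rendering fills the region
polygons with distinct flat intensities, darkens the ridge lines, blurs
with σ = 3 px and adds noise.  The standard profile has uniform
illumination and σ ≤ 2 noise; the degraded profile adds a linear
illumination gradient up to ±30% across the frame, gain ±20%, offset ±15
gray levels and noise σ ∈ [3, 8] — an idealization of hand-held phone
capture without lens or perspective effects.

What passing tests show, and what they do not: the synthetic appearance is
an almost deterministic function of shape plus illumination, so the
benchmark demonstrates that the *pipeline* (detection, initialization,
coarse-to-fine IC search, geometry) is correctly implemented and robust to
the modelled photometric degradations.  Real ears carry texture the
generator does not model (hair, specularities, depth shading, occlusion,
perspective), so sub-pixel synthetic errors do not predict real-image
accuracy; they bound implementation error, not modelling error.

## Benchmark problem sizes

The reproduction script and the accuracy tests train on 40 standard
images, evaluate 10 held-out standard and 20 degraded images, run the
parameter-recovery experiment with deterministic ±2σ mode weights and a
1.05×-scale, (5, −4) px-shifted initialization, and the earlobe division on
an analytic semicircular contour (radius 60 px, kₙ = 20).  These sizes keep
a full run at a few minutes on one CPU while leaving the success criteria
(6-pixel acceptability threshold, 100%/95% rates) well clear of sampling
noise at the achieved sub-pixel errors.

## Known limitations

- Rotation is linearized in the fitting parameterization; fits beyond
  roughly ±15° of in-plane rotation rely on the modes' extrapolation.
- Left ears are handled only by mirroring inputs externally; the scheme
  carries no flip flag logic beyond that.
- The acupoint registry is an approximate, replaceable stand-in, not a
  reproduction of the national standard's coordinates.
- The detector is single-object: one ear per image.
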