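# Methods

## Scene model and conventions

The growth vessel is a thick-walled acrylic cylinder, by default 6 in
diameter by 6 in tall (outer radius 76.2 mm, height 152.4 mm) with a 3.175 mm
(1/8-in stock) wall; the wall thickness is configurable because it is a
property of the acrylic stock, not of the method. World coordinates are
right-handed millimetres with the origin on the canister axis at the net-pot
plane and +z pointing down into the liquid; pixels are (u, v) =
(column, row), 0-based, origin top-left. Volumes are reported in mL
(1 mL = 1000 mm³).

## Camera localization

Each view's pose is solved from ≥ 4 (3D marker center, 2D detection) pairs.
A normalized direct linear transform over the 12 entries of [R | t] seeds the
estimate when six or more pairs are available (a small deterministic set of
standoff initializations covers the minimal 4–5 point case), followed by
Levenberg–Marquardt minimization of total squared pixel reprojection error
over a rotation-vector + translation parameterization. The residual RMS is
attached to the returned pose. Collinear marker configurations are rejected:
they leave a one-parameter family of solutions. Marker *detection* is out of
scope — detections arrive as (id, u, v) rows, matching how a standard
fiducial detector would be used; radial distortion coefficients, when
supplied, are applied to normalized coordinates before the residual.

The circle of best fit through the camera centers (used to audit the
turntable ring) fits the plane by SVD, seeds center/radius with the
algebraic Kåsa fit — exact for noise-free circles — and refines with
geometric (orthogonal-distance) least squares.

## Silhouette extraction

Backlit root images are segmented by a hybrid of two channels and their
union restricted to a region of interest:

* **solid channel** — global Otsu threshold, dark-foreground polarity by
  default. For 8-bit integer images the threshold is computed exactly by
  exhaustive maximization of between-class variance over the 256-bin
  histogram (returned as the midpoint between the two classes so the cut is
  unambiguous); float images use `skimage.filters.threshold_otsu`.
* **edge channel** — 3×3 Sobel magnitude (reflection borders), normalized,
  then hysteresis thresholding with 8-connectivity. The hysteresis
  thresholds are anchored to the data: high = Otsu threshold of the
  normalized gradient magnitude, low = 0.5 × high, both exposed in
  `SilhouetteConfig`. A Sobel response straddles a boundary, so edge pixels
  that touch the solid mask from outside *and* lie on the background side of
  the global threshold are discarded; this removes the one-pixel halo that
  would otherwise thicken every large structure, while leaving genuinely
  thin, faint roots (which are nowhere adjacent to the solid mask) intact.

The union is masked by the projected canister-interior ROI when provided
(`optics.interior_roi`: pixels whose traced ray reaches the liquid) and
finished with a 3×3 morphological opening (radius configurable) to drop
speckle. Every threshold actually used is recorded in the silhouette's
provenance dictionary, and the pipeline is bit-for-bit deterministic.

## Refraction raytracing

For each view a grid of primary rays (default 800 × 600 = 480,000, decoupled
from the sensor resolution; silhouettes are nearest-neighbor resampled onto
the ray grid when they differ) is cast from the camera center through the
pixel centers. Each ray is intersected with the outer cylinder wall
(quadratic in the plane normal to the axis, hits clipped to the wall height —
the annular end caps are not modeled, rays through them are flagged
invalid), refracted by the vector form of Snell's law

    t = η d + (η cos θᵢ − cos θₜ) n,   η = n₁/n₂,

carried through the wall, intersected with the inner wall, and refracted
again. The ray field stores, per pixel, the entry point on the inner surface
and the in-water direction. Rays that miss either wall, exit through an end
cap, or undergo total internal reflection are invalid and *never carve*:
carving requires positive evidence. Defaults n_air = 1.00,
n_acrylic = 1.49, n_water = 1.33; with all three equal the tracer reduces to
straight pinhole rays (verified to < 1e-12 rad). The in-water path is
straight — refractive-index gradients in the nutrient solution are not
modeled. Ray fields are cacheable to `.npz` (arrays `origins`,
`directions`, `valid`, plus JSON metadata) so per-view tracing is done once.

## Octree space carving

The reconstruction volume is the axis-aligned cube circumscribing the
liquid column; voxels outside the inner cylinder are pre-marked empty, and
boundary-straddling voxels refine until the leaf size, where they are kept
only if their center is in the liquid. Carving is level-synchronous
mark-and-refine: every node of the current level is classified against every
view by the fraction f of its covering rays that land in the silhouette,

* f ≥ τ_full (default 1.0) — consistent with this view,
* f ≤ τ_empty (default 0.0) — inconsistent: carved once
  `min_views_to_carve` views agree (default 1 = classic intersection
  semantics; larger values soften the aggressive culling of thin structures
  at the price of a looser hull),
* otherwise ambiguous — the node splits into its 8 children (fixed octant
  order −−−, −−+, −+−, … for determinism) while children would remain at or
  above the target leaf `s_min`.

A node covered by no ray of a view is *unseen* by it and keeps its state;
voxels seen by no view at all stay occupied and are reported separately as
unobserved volume. Terminal ambiguous leaves are kept, which is what makes
the occupied set a discrete visual hull: it always contains the object and
its volume converges to the hull volume from above with an O(surface × s)
discretization layer (empirically ≈ 0.6 s across the surface).

Two interchangeable visibility backends implement the coverage counts:

* **ray-field backend** — the voxel's axis-aligned slab test against the
  cached in-water ray segments; exactly the per-voxel
  `pixel_visibility_mask` / `visible_fraction` contract, vectorized over
  rays and chunked over nodes.
* **projective backend** (uniform-index limit) — pixel counts inside the
  bounding box of the eight projected corners, answered in O(1) per node by
  a per-view integral image. The box is a superset of the exact footprint
  (the projection of a convex solid is the convex hull of its projected
  vertices), so all/none classifications stay safe; the hulls it produces
  contain the ray-backend hulls and agree up to a boundary layer.

`total_volume` sums s³ over occupied leaves (mixed leaf sizes allowed).
`to_flat_grid` samples the octree onto a dense grid (guarded by a cell cap)
and is the bridge to the brute-force carve oracle used in tests.
`export_mesh` flattens at the finest leaf size and emits only faces between
occupied and empty cells, outward-wound, giving a watertight cube-union
surface whose signed volume equals the voxel volume exactly.

## Synthetic scenes

The generator mirrors the validation protocol: shapes of known volume
placed in the simulated canister, rendered from a ring of 40 cameras at
equidistant (9°) angles, by default 300 mm from the axis at canister
mid-height with 800 × 600 images (f = 1000 px) — a geometry in which the
canister fills most of the frame, as on the physical rig. Renders trace the
same optics forward (refraction on or off) and supersample 2 × 2 per pixel
with majority vote to limit aliasing. Shapes: axis-aligned cubes spanning
the validation range (50 mm = 125 mL up to 125 mm = 1953.125 mL),
spheres, finite cylinders, and randomized branching roots built from
tapered capsules grown down from the net-pot plane (seed-deterministic;
branch radii taper by 0.6 per generation, everything clamped inside the
liquid with a 10 mm margin). Non-analytic volumes come from seeded
Monte-Carlo sampling with reported standard error; test tolerances include
3 SE. The optional realism layer is additive Gaussian intensity noise on
the backlit images.

What the generator does **not** emulate: felt/net-pot occlusion, algae and
shadows, soft lighting gradients, root-hair-scale structure, pose error of
a physical arm (poses are exact unless noise is explicitly added to marker
detections). Passing tests therefore demonstrate the correctness of the
geometry/optics/carving machinery and its convergence behavior, not
robustness to the full mess of laboratory imagery — on real data the known
failure modes (blobbed silhouettes of complex roots, aggressive culling of
thin laterals under pose error) still apply.

## Biomass and density

Apparent density is wet mass (g) over reconstructed volume (mL); cohort
summaries use the unweighted arithmetic mean of per-plant densities (a
mass-weighted variant is available but not default). Densities and volumes
are displayed at 3 decimals; computation is full precision. Recomputing the
packaged 18-plant radish table: rounding reproduces 13 of the 16 tabulated
densities exactly and truncation 12, so rounding is the adopted display
rule; the three remaining tabulated values differ by exactly one unit in
the last decimal from their own tabulated mass and volume (consistent with
the original division having used unrounded lab values) and the cohort mean is
0.034 g/mL either way. Failed reconstructions carry no density and are
counted separately. Percent water is 100 (wet − dry)/wet.

## Numerical and design choices

* Leaf size defaults to 0.27 mm, the calibration-experiment resolution;
  the validation-cube
  acceptance run carves to 0.298 mm leaves (root cube 152.4 mm / 2⁹), which
  yields ~91 % volume accuracy at ~2 min on one CPU. Tests use coarser
  leaves (1–5 mm) and smaller ray grids to keep the suite fast; problem
  sizes are stated in each test.
* A discrete hull cannot beat its surface layer: for a 20-mm sphere the
  layer is ~9 % of the volume at 1-mm leaves and falls below 5 % only at
  ~0.5 mm. Convergence tests assert the conservative, from-above behavior
  at the resolutions where the geometric bound permits.
* Intersection tolerances: quadratic roots accepted for t > 1e-9; Snell
  consistency holds to 1e-12 and is asserted at that level.
* The pose refit is run to xtol = ftol = 1e-14; exact synthetic poses are
  recovered to < 1e-6 (rotation entries and mm).
* Degenerate inputs raise typed exceptions (constant images, collinear
  points, zero views, camera inside the canister, dry > wet, volume ≤ 0)
  rather than returning sentinel values.

## Known limitations

* Shoot reconstruction, root skeletonization, photoconsistency carving, and
  detector-level marker decoding are out of scope.
* The hull overestimates concave and self-occluding root systems by
  construction; the unobserved-volume report flags the part of the bound
  attributable to never-seen voxels, but occlusion inside the silhouette
  cone is invisible to any silhouette method.
* The projective backend's bounding-box footprint slightly loosens the hull
  relative to an exact convex-footprint rasterization (≈ 0.2 leaf across
  the surface); the ray-field backend does not share this approximation.
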