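# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mesh model and I/O

The unit of analysis is a triangulated polygon mesh: an (V, 3) float64
vertex array and an (F, 3) int64 face-index array, 0-based. Faces with
more than three vertices are rejected at parse time rather than fan
triangulated, because all three metrics are defined on triangles and a
silent re-triangulation would change DNE and OPCR. Vertex properties
beyond x, y, z (stored normals, colors) are discarded: normals stored by
scanners or editors are untrusted and always recomputed from geometry.
ASCII PLY output carries 6 significant digits, which exceeds typical
scanner precision while keeping files diff-able; binary PLY input is
decoded (little or big endian, float32 coordinates, uchar-count integer
index lists) only through the explicit conversion routine, so ASCII
remains the single analysis format.

## Normals

Face normals are the normalized cross products of the winding-ordered
edge vectors; areas are half the cross-product magnitudes. Faces whose
doubled area falls below 1e-12 (squared mesh units) are degenerate and
excluded everywhere, with a warning rather than an abort so one bad face
cannot kill a batch. Vertex normals are the renormalized **unweighted**
mean of incident face normals; area weighting is available as an option
(default off) because the unweighted average is the conventional choice
in this metric family and changing it changes DNE slightly. Vertices
whose incident normals cancel to (numerically) zero length are flagged
and their incident faces treated as degenerate for DNE.

## DNE

Per face, with u = p1−p0, v = p2−p0 and n_u = n1−n0, n_v = n2−n0 from
the vertex normals, e(p) = tr(G⁻¹H) is evaluated in closed form for the
2×2 symmetric matrices (the Gram matrix G of the edges and its normal
map analogue H). e(p) is invariant to the choice of edge basis — any
affine reparametrization of (u, v) applies the same Jacobian factors to
G and H and cancels in tr(G⁻¹H) — which the suite checks on random
triangles. The condition number of G is the ratio of its eigenvalues
(equal to its singular values for a symmetric PSD matrix), computed in
closed form.

Exclusions apply in a fixed precedence — degenerate → boundary →
condition → outlier — and each face records the first reason that
applied. The precedence matters only for the outlier percentile, which
is computed over faces that already passed the earlier filters so that
boundary spikes cannot distort the cutoff. Defaults: boundary discard
on; condition check on with threshold 1e5 (G within float precision of
singular is discarded regardless of the threshold because its e(p) is
not finite); outlier discard on at the 99.9th percentile of per-face
energy (e·area), with energy density as an alternative basis. The
percentile uses the linear-interpolation quantile definition; quantile
conventions differ between tools and this one is pinned for
reproducibility. Faces strictly above the cutoff are discarded.

An optional implicit-fairing smooth can run before DNE for
compatibility with pipelines that force smoothing; it is **off** by
default so the metric reflects the mesh as given. Each iteration solves
(I − λL)X′ = X with the uniform-weight (umbrella) graph Laplacian
L = D⁻¹A − I and a direct sparse factorization reused across
iterations; backward-Euler diffusion is unconditionally stable, so the
conventional λ = 0.6 and large iteration counts are safe. Uniform
weights were chosen over cotangent weights for robustness on the
irregular, sometimes obtuse triangles of scan meshes.

DNE is dimensionless: density scales as 1/s² and area as s² under
uniform scaling s, so the total is scale-free, and it is exactly
rotation invariant up to floating-point noise. On noisy meshes total
DNE grows with triangle count (each noisy face contributes positive
energy), so comparative samples must be simplified to a common face
count upstream; on noiseless analytic meshes it instead converges to
the continuum integral, and the suite verifies both regimes.

## RFI

3da is the summed triangle area. 2da rasterizes the XY projection:
`resolution` pixels (default 1000, minimum 100) span the longest side
of the XY bounding box, and a pixel counts once if its center lies
inside any projected triangle, regardless of how many surfaces stack
above it — undercuts therefore count fully toward 3da and once toward
2da, which is the point of measuring relief on a true 3D mesh. Pixel
centers exactly on a shared triangle edge satisfy the inclusive (≥ 0)
half-plane test for both incident triangles; since filling is a single
OR over faces this is deterministic and equivalent to any tie-break
rule except on the outermost silhouette boundary, where the
discretization error is in any case O(perimeter × pixel size). The
rasterization mirrors the classic occlusal-bitmap pixel-counting
workflow, which is why it is the default rather than an exact polygon
union.

Orientation is an explicit precondition: the occlusal plane must be
parallel to XY before calling RFI (use the `meshrotate` subcommand).
Relief is known to be sensitive to orientation, and silently
auto-orienting would hide that sensitivity. Both published report forms
(ratio ×100 and ln ratio) are always emitted.

## 3D-OPCR

Aspect = atan2(n_y, n_x) mapped to [0°, 360°); bin k covers
[45k, 45(k+1)°), half-open, measured from +X. The bin phase is a free
choice (only the 45° width is fixed by the method); rotation averaging
makes the phase immaterial, and the half-open interval resolves
boundary ties deterministically. Normals whose XY norm is below 1e-8
have no defined aspect and stay unbinned — a perfectly horizontal plane
yields OPC 0. Downward-pointing normals are binned by their aspect like
any other face: overhanging surface is exactly what the mesh-based
algorithm can see and a raster DEM cannot.

Patches are connected components over **edge** adjacency (vertex
adjacency would let patches leak through single points), found by an
explicit-queue flood fill with no recursion-depth hazard on large
meshes. OPC counts patches with at least `min_patch_size` faces
(default 5, the conventional setting for ~10,000-face molar meshes; the
larger mesh minimum relative to DEM implementations reflects the finer
resolution of mesh data, and the parameter is always user-settable).
OPCR is the mean OPC over rotations k·5.625°, k = 0…7. Each rotation is
implemented as a constant aspect offset, which is mathematically
identical to rotating the vertices and re-deriving normals (a Z
rotation by θ adds θ to every aspect); the suite confirms the
equivalence against literal mesh rotation. Because 45°-wide bins make
OPC exactly 45°-periodic, the rotation set {0°, …, 39.375°} equals
{5.625°, …, 45°}; both readings of "eight rotations spanning 45°" give
the same OPCR. The mesh is centered on the origin first, a conventional
step kept for parity even though normals are translation invariant.

## Synthetic fixtures

The generators stand in for scanned specimens, which are large binary
assets with no analytic ground truth. Each fixture has a property known
in closed form: planes (area, zero bending, zero or one patch),
icospheres (face/vertex counts, area → 4πr² from below, DNE → 8π,
OPC = 8, closed manifold), hemispheres (area → 2πr², RFI → 2, a single
boundary rim), and Gaussian-cusp heightfields (analytic gradient for
quadrature oracles; cusp count drives complexity). Optional seeded
Gaussian noise displaces vertices along their normals, emulating
scanner noise for the smoothing and outlier-discard options; identical
spec and seed reproduce bit-identical meshes. What the fixtures do
**not** emulate: irregular scan triangulations (they are regular
grids/subdivisions), wear facets, cropping artifacts, or holes other
than a single rim — so passing tests demonstrate correctness of the
algorithms, not robustness to every pathology of real scan data.

## Species-comparison statistics

The validation sample is 36 second mandibular molars from four
cercopithecoid species (Cercocebus atys 7, Cercopithecus mitis 10,
Colobus guereza 10, Theropithecus gelada 9), each scored with raster
DEM-OPCR and mesh 3D-OPCR. The raw per-specimen table is not
redistributable; the packaged plain-text table carries the published
per-species summary statistics (mean and SD of DEM-OPCR, 3D-OPCR, and
their difference ΔOPCR). These moments are sufficient statistics for
the entire analysis:

- one-way ANOVA depends only on group sizes, means, and SDs;
- Tukey HSD depends on group means, sizes, and the pooled within-group
  mean square — the Tukey–Kramer form is used because the groups are
  unbalanced (plain Tukey assumes equal n); it is the same adjustment
  mainstream statistics packages apply;
- since ΔOPCR = 3D − DEM is linear in the two treatments, the three SDs
  per species determine the within-species covariance via
  Var(Δ) = Var(3D) + Var(DEM) − 2·Cov, and with the group means this
  fixes the pooled covariance of any pair of the three variables —
  hence the OLS slope, intercept, and R² of ΔOPCR on either treatment.

`synthesize_specimen_table` draws standard-normal pairs per species,
empirically whitens them (exact sample mean and identity sample
covariance, ddof = 1), and recolors to the target moments, so the
synthetic table's per-species sample moments equal the published values
to machine precision for **every** seed; the seed only permutes
residual directions. Any statistic that is a function of those moments
is therefore exact, not a stochastic approximation. Statistics that
depend on higher moments (normality diagnostics, robust estimators)
would not transfer and are not offered. The dem/3D ANOVA p-values come
from the F distribution, Tukey p-values from the studentized-range
distribution via statsmodels; an independent scipy implementation
serves as a cross-check in the tests, with agreement tolerance 1e-3 on
p.

## Batch driver and CLI

Files are processed independently in lexicographic order; a failing
file logs an error and becomes an NA row instead of aborting the batch
(exit code 2 signals partial failure, 1 fatal, 0 clean). The options in
effect are echoed as comment lines atop the results TSV for provenance,
and re-running an identical configuration is byte-identical.

## Problem sizes and tolerances in the suite

Analytic convergence tests use icosphere subdivisions 2–4 (80–5,120
faces) and raster resolutions 250–1000 — sizes where each stated
tolerance (2% for the sphere DNE limit and hemisphere RFI, 0.5% for
sphere area, 1e-9 relative for algebraic invariances) is comfortably
met while the whole suite stays fast. The hemisphere fixture trims
whole faces at the equator, so its area deficit shrinks with
subdivision and the 2% relief tolerance is assessed at subdivision 4.
Patch-labeling equivalence against a brute-force connected-components
oracle is checked exhaustively on meshes up to 450 faces.

## Known limitations

- No mesh repair, simplification, or hole filling: meshes are analyzed
  as given, and cross-specimen DNE comparability requires a common face
  count prepared upstream.
- RFI requires correct occlusal orientation; the package will happily
  compute a meaningless relief index for a sideways mesh.
- The raster 2da is a biased (slightly resolution-dependent) estimator;
  its convergence is monotone on convex silhouettes but not guaranteed
  monotone for arbitrary concave outlines.
- DEM-OPCR itself is not implemented (it belongs to raster GIS
  tooling); the statistics layer consumes its published values.
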