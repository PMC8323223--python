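# Methods

This note documents the models, conventions and numerical choices behind
neurorender, and what the synthetic test data does and does not show.

## Data model and coordinates

All geometry lives in world-space millimetres, RAS orientation assumed,
stored at 32-bit float precision (the native precision of all supported
file formats). Voxel indices are 0-based; slice indices are half-open
`[0, n_axis)`. A `Volume` carries its voxel→world affine; fibers and mesh
vertices are kept directly in world space.

**TrackVis `.trk`.** The 1000-byte v2 header is parsed directly. The
header's voxel→RAS matrix is applied to the points at load time when it
is a valid non-zero matrix; v1-style all-zero matrices are tolerated and
the points used as stored. The original matrix is retained on the object
for provenance. On write the points are emitted in world space with an
identity matrix — re-emitting a non-identity transform over
already-transformed points would double-apply it on the next read and
break the round-trip identity. Truncated payloads and track counts that
disagree with the header are errors, never silently dropped data.

**BrainVISA `.bundles`.** The header is a `minf`-style text dictionary
(`attributes = {...}`) with `curves_count`, `byte_order` (`DCBA` =
little-endian, honored on read), `data_file_name` and a flat `bundles`
list alternating bundle name and starting fiber index; the companion
`.bundlesdata` holds, per fiber, an int32 point count followed by float32
xyz triples. Because the format encodes bundles as contiguous index
ranges, writing renumbers fibers bundle-by-bundle; an unlabeled
tractography becomes a single bundle named `"all"` (the format requires
at least one label).

**NIfTI and GIfTI** go through nibabel. Header slope/intercept scaling is
applied when declared; data are promoted to float32; 4D images are
rejected (this is a 3D renderer). GIfTI arrays are matched by intent code
(pointset / triangle / vector-for-normals). BrainVISA `.mesh` is the
binary AIMS layout (`binar` magic, byte-order marker, `VOID` texture
type, triangles only).

## Fiber operations

**Sampling.** The selection size is `max(1, ⌊percent/100 · n_eligible⌋)`.
Floor is the only rounding consistent with the whole-brain reference
count (10% of 204,052 fibers → 20,405); the minimum-1 rule prevents empty
renders at 1% of tiny bundles. The subset is the prefix of a seeded
random permutation, which makes samples reproducible and *nested*: for a
fixed seed the 10% sample is contained in the 20% sample, so increasing
the percentage only adds fibers. Sampling is global over the eligible set
(not stratified per bundle); restricting to named bundles first is the
`within` argument.

**Bundle colors.** "Random color per bundle" is implemented as hues
equally spaced around the color wheel after a seeded random rotation,
at full saturation and value. Plain independent draws would not guarantee
distinctness; equal spacing does, for up to 360 bundles (beyond that hues
may collide but the operation still succeeds).

**Equidistant resampling** linearly interpolates along the cumulative
chord-length parameterization; endpoints are preserved exactly. Spacing
is equal in arc length along the source polyline; chord distances between
output points are shorter wherever a corner falls between two samples,
so the polyline length of a resampled fiber converges to the original
from below as the point count grows.

**Line pseudo-normals.** When fibers are drawn as 1-pixel lines there is
no true surface normal; each point uses the direction of its outgoing
segment (the last point reuses the incoming one; zero-length segments
inherit the nearest non-degenerate direction). These unit vectors are fed
to the Phong model unchanged.

**Tubes.** The cylinder display mode expands each polyline into an open
tube: one ring of `n_sides` vertices per fiber point, rings joined by
quads split into two triangles, radially outward vertex normals. Ring
frames are propagated by parallel transport (project the previous frame
vector off the new tangent and renormalize), which avoids the twisting
that a fixed reference vector produces at bends.

## Volume operations

**Otsu threshold.** 256-bin histogram over `[min, max]`; the returned
threshold is the lower edge of the first bin of the upper class at the
split maximizing the between-class variance `w₀w₁(μ₀−μ₁)²`. Ties are
broken toward the lowest qualifying bin. A consequence worth knowing:
for two well-separated intensity classes the variance is *exactly flat*
across the empty histogram gap between them, so the threshold lands just
above the lower class rather than mid-gap. Every above-threshold voxel is
renderable; everything below is treated as empty space. The test suite
checks the implementation against an exhaustive brute-force maximizer
written independently.

**Gradients** are central differences (one-sided at boundaries) scaled by
the per-axis voxel size, in intensity/mm. They are exact for affine
intensity fields, including at boundaries.

**Slice plan.** The number of view-perpendicular planes is
`n_s = ⌈sf · √(n_x² + n_y² + n_z²)⌉` with `sf = 0.2` by default. The
formula leaves `n_s` fractional; the ceiling is chosen so that
`spacing · n_s` always covers the world bounding-box diagonal. Planes are
ordered far → near so that iterating the list and compositing "over" is
back-to-front. For the 240×256×160 whole-head profile at the default
factor this gives 78 planes.

**Plane sampling** is nearest-neighbor everywhere. The underlying design
prescribes no in-plane interpolation for axis slices; the same rule is
extended to oblique view-aligned planes for consistency (the GPU original
leaves its texture filtering unspecified). Samples outside the voxel grid
are NaN sentinels and contribute zero opacity — this avoids the faint
bounding-box "ghost" that a numeric fill value would produce.

## Meshes

Vertex normals are the normalized area-weighted average of incident face
normals (accumulating raw cross products gives the area weighting for
free); counter-clockwise winding with the right-hand rule defines the
outward side; degenerate triangles contribute nothing and isolated
vertices default to (0,0,1). A mesh that already carries normals is
returned unchanged. Transparency ordering sorts triangles by
centroid-to-eye distance (stable for ties). The centroid key is the
standard painter's-algorithm compromise: cheap and usually right, but
mutually intersecting transparent triangles can still be drawn in the
wrong order — accepted and documented rather than solved with exact
order-independent transparency.

## Camera

The pose is a focus point, an orbit radius `r > 0` (clamped to
`[10⁻³, 10⁶]` mm by zoom) and a unit quaternion. At the identity
orientation the eye sits at `center + r·ẑ` with up `+ŷ`; `θ` tilts about
the camera-right axis and `φ` turns about world-up (the axis binding
itself is a convention choice, made to match common arcball cameras).
Storing the composed rotation as a quaternion rather than the two angles
avoids gimbal lock under incremental orbiting; every operation
re-normalizes, so drift stays below 1e-9 over 10⁴ composed operations.
The "rotate" gesture of the original interface is exposed as `roll`
about the view axis. Zoom divides the radius (pinch-out magnifies). The
view matrix is a standard look-at: rows are right/up/backward, the eye
maps to the origin and the focus point to `(0, 0, −r)`.

Orbit pre-multiplies the θ-increment then the φ-increment in a fixed
order; a combined orbit is inverted by applying the negated increments
in reverse order, and single-axis orbits are inverted by simple negation.

## Renderer

Two passes. Opaque first — axis slices and opaque meshes as
depth-tested triangles, fibers as Bresenham lines (or tube meshes in
cylinder mode). Then transparency — volume plane stacks far → near and
transparent meshes back-to-front, composited with the non-premultiplied
"over" operator against the opaque depth buffer (tested, not written).

* Projection: perspective, 45° default vertical field of view, near/far
  at `0.01r`/`100r`. There is no near-plane clipping: a primitive with a
  vertex behind the near plane is skipped entirely. This is a real
  limitation for cameras inside the data; orbiting cameras at sensible
  radii never hit it.
* Triangles: perspective-correct barycentric interpolation (attributes
  weighted by 1/depth); a pixel belongs to a triangle when its center
  lies inside. Shading is Gouraud: the Phong model is evaluated at the
  vertices (as the original vertex-shader formulation does) and the
  resulting colors interpolated.
* Phong: dot products are clamped at zero and the specular term is gated
  on a positive diffuse term; without the clamps the model produces
  negative light from back-facing geometry. The light direction `l̂` is
  the unit vector toward the light; by default the light is a headlight
  (at the camera), which keeps ambient-only renders camera-invariant and
  reproduces the look of the reference screenshots. Because the original
  interface never states its default illumination constants, the package
  defaults (`L_a=0.8, L_d=0.9, L_s=0.5`, `K_a=K_d=1, K_s=0.5, f=14`)
  were fixed once, guided by the published example settings.
* Lines: integer Bresenham between the floored projected endpoints, depth
  interpolated hyperbolically (linear in 1/z), color interpolated between
  the endpoint Phong evaluations.
* Volume stack: each plane fragment looks up its nearest voxel; voxels
  below the Otsu threshold are skipped; the rest are shaded with the
  (viewer-facing) unit gradient as normal and composited with per-slice
  opacity `α/n_s`. The division by `n_s` makes the accumulated opacity
  approximately independent of the sampling factor; the per-slice alpha
  model is this package's choice — the original describes the threshold
  but not its blending equation.

Rendering is deterministic: identical scene, camera and seeds give
bitwise-identical images, which the tests assert.

## Synthetic data

The generators emulate the *structure* of real data, not its anatomy:

* tractographies are sinusoidally perturbed chords inside a 100 mm cube,
  evenly split into contiguous named bundles, 21 points per fiber by
  default (the convention of resampled whole-brain datasets); scale
  presets reach 204,052 fibers / 36 bundles, the published whole-brain
  profile used for the sampling-count checks;
* volumes are a Gaussian-intensity ellipsoid (foreground, mean 150, sd 5
  by default) inside a Gaussian background (mean 50), the canonical
  two-class Otsu scenario; 32³ voxels by default, with the 240×256×160 /
  1.0×1.0×1.1 mm whole-head profile used where the slice-count formula is
  exercised;
* meshes are unit icospheres (20·4^level triangles, watertight, outward
  CCW winding).

Every generator is a pure function of its seed. Passing tests on these
fixtures demonstrates format conformance, count laws, geometric
invariants and rendering determinism; it does **not** demonstrate
anatomical plausibility, robustness to scanner artifacts, or the
behavior of malformed third-party files beyond the specific corruptions
tested. Default scales are small (hundreds of fibers, 32³ volumes) so
the full suite runs in seconds; the whole-brain-scale objects are
generated only where the headline counts require them.

## Known limitations

No anti-aliasing; no near-plane clipping; no DICOM or 4D volumes; no
per-voxel transfer functions (the Otsu gate is binary); no mesh label
colormaps; painter's-algorithm artifacts for intersecting transparent
triangles; `.bundles` writing renumbers fibers into contiguous bundle
ranges; interactive viewing is out of scope — the CLI renders one frame
per invocation.
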