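# neurorender

A headless software renderer for combined 3D visualization of brain-imaging
data: diffusion-MRI tractography (fibers as lines or tubes), MRI volumes
(axis slices and slice-stack volume rendering) and surface meshes
(opaque, transparent or wireframe). It is aimed at researchers who need
reproducible, scriptable renderings of tractography datasets with
anatomical context — on servers, in CI, or in notebooks — without a GPU
or a display.

## What it does

* **Formats.** Reads and writes TrackVis `.trk`, BrainVISA
  `.bundles`/`.bundlesdata`, NIfTI-1 `.nii`/`.nii.gz`, GIfTI `.gii` and
  BrainVISA `.mesh`/`.mesh.minf`. All geometry is float32 world-space
  millimetres; every writer round-trips bit-exactly.
* **Fiber processing.** Percentage sampling from 1% to 100% with the count
  law `|S| = max(1, ⌊p/100 · n⌋)` over a seeded permutation prefix (nested,
  reproducible subsets), bundle selection by label, deterministic per-bundle
  random colors, equidistant arc-length resampling, direction pseudo-normals
  for line lighting, and polyline→tube expansion with parallel-transported
  ring frames.
* **Volume rendering.** Slice-based: a stack of
  `n_s = ⌈sf·√(n_x² + n_y² + n_z²)⌉` view-perpendicular planes (default
  `sf = 0.2`) composited far to near, voxel opacity gated by the Otsu
  threshold and shaded with central-difference gradient normals.
* **Shading.** Phong illumination
  `I = L_a K_a + L_d K_d (l̂·n̂) + L_s K_s (r̂·v̂)^f` with clamped dot
  products, evaluated per vertex (Gouraud) for meshes and tubes and per
  point for lines.
* **Camera.** Spherical-coordinate orbit camera whose angles are stored as
  a unit quaternion; orbit / roll / pan / zoom operations and a look-at
  view matrix with perspective projection.
* **Rasterizer.** Deterministic z-buffered software passes: Bresenham lines
  with depth interpolation, perspective-correct barycentric triangles, and
  painter's-algorithm "over" compositing for transparent objects.
* **Fixtures.** Seeded synthetic generators for every supported format, so
  the whole pipeline is testable offline at anything from toy to
  whole-brain scale (hundreds of thousands of fibers).

## Worked example

```bash
neurorender fixtures --kind tractography --out demo.bundles --n-fibers 500 --n-bundles 5 --seed 1
neurorender fixtures --kind volume --out demo.nii.gz --dims 32 32 32 --seed 1
neurorender info demo.bundles demo.nii.gz
```

```
demo.bundles: tractography (bundles), 500 fibers, 5 bundles, 10,500 points
  bundle_000: 100 fibers
  ...
demo.nii.gz: volume 32x32x32 voxels, 1x1x1 mm, intensity [29.848, 168.9]
```

500 synthetic fibers (21 points each, 10,500 points total) in 5 labeled
bundles, and a two-class volume whose foreground/background intensities
make a natural Otsu target. Sampling 10% keeps exactly
`max(1, ⌊0.10·500⌋) = 50` fibers:

```bash
neurorender sample demo.bundles --percent 10 --seed 0 --out demo10.bundles
# wrote demo10.bundles: 50 of 500 fibers (10%)
```

Rendering is driven by a declarative YAML scene:

```yaml
# scene.yaml
objects:
  - type: tractography
    path: demo.bundles
    percent: 50            # seeded 50% sample, colored by bundle
  - type: slice
    path: demo.nii.gz
    axis: z
    index: 16              # grayscale axis slice for anatomical context
camera:
  center: [50, 50, 50]
  radius: 300
image:
  width: 320
  height: 240
seed: 1
output: demo.png
```

```bash
neurorender render scene.yaml
# wrote demo.png (320x240) and demo.png.yaml
```

The sidecar `demo.png.yaml` logs every effective parameter; re-rendering
it reproduces the PNG byte for byte.

The same operations are available as a library:

```python
import neurorender as nr

t = nr.read_tractography("demo.bundles")
sel = nr.sample_fibers(t, percent=10, seed=0)     # 50 of 500 fibers
scene = nr.Scene(objects=[nr.TractographyItem(tractography=t, selection=sel,
                                              palette=nr.assign_bundle_colors(t, seed=1))])
img = nr.render_scene(scene, nr.make_camera([50, 50, 50], r=300), 320, 240)
```

## Limitations

Near-plane clipping is not implemented (primitives with a vertex behind
the eye are skipped), transparency uses centroid-sorted painter's
compositing (intersecting transparent triangles can sort imperfectly), and
sampling of volume planes is nearest-neighbor throughout. See
`docs/methods.md` for the full account of the model and its numerical
choices.
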