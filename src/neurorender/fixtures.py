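"""Deterministic synthetic data generators.

Everything the package can read it can also fabricate: tractographies
(smooth sinusoidally-perturbed chords inside a 100 mm cube with evenly
assigned bundle labels), two-class volumes (a Gaussian-intensity
ellipsoid in a Gaussian background, a natural target for Otsu
thresholding), and icospheres.  Generators are pure functions of their
seed, so files written from them are reproducible byte for byte.

Scale presets default to small, fast objects; the constructor arguments
reach up to whole-brain scale (hundreds of thousands of fibers at 21
points each, matching published whole-brain tractography profiles) when
a test needs it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Mesh, Tractography, Volume

__all__ = [
    "FixtureSpec",
    "synth_tractography",
    "synth_volume_two_class",
    "synth_icosphere",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic generators (one seed drives them all)."""

    seed: int = 0
    n_fibers: int = 200
    n_bundles: int = 4
    points_per_fiber: int = 21
    volume_dims: tuple[int, int, int] = (32, 32, 32)
    fg_mean: float = 150.0
    bg_mean: float = 50.0
    class_sd: float = 5.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    icosphere_level: int = 1

    def __post_init__(self) -> None:
        if min(self.n_fibers, self.n_bundles, self.points_per_fiber) < 1:
            raise ValueError("fiber/bundle/point counts must be positive")
        if self.points_per_fiber < 2:
            raise ValueError("fibers need at least 2 points")
        if min(self.volume_dims) < 4:
            raise ValueError("volume dims must be >= 4 per axis")


def synth_tractography(spec: FixtureSpec) -> Tractography:
    """Generate smooth synthetic fibers with evenly assigned bundle labels.

    Each fiber is a straight chord between two random points in a 100 mm
    cube, bent by a low-frequency sinusoidal perturbation perpendicular to
    the chord.  Fibers are split into ``n_bundles`` contiguous, near-equal
    groups named ``bundle_000`` ... so bundle index ranges are contiguous
    (as .bundles files store them).
    """
    rng = np.random.default_rng(spec.seed)
    F, P = spec.n_fibers, spec.points_per_fiber
    start = rng.uniform(0.0, 100.0, size=(F, 3))
    end = rng.uniform(0.0, 100.0, size=(F, 3))
    t = np.linspace(0.0, 1.0, P)[None, :, None]
    chord = start[:, None, :] * (1 - t) + end[:, None, :] * t
    # perpendicular sinusoidal bend, amplitude a few mm, 1-2 half-waves
    direction = end - start
    norms = np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-9)
    direction /= norms
    probe = rng.normal(size=(F, 3))
    perp = np.cross(direction, probe)
    perp /= np.maximum(np.linalg.norm(perp, axis=1, keepdims=True), 1e-9)
    amp = rng.uniform(1.0, 5.0, size=(F, 1))
    waves = rng.integers(1, 3, size=(F, 1))
    bend = (amp * np.sin(np.pi * waves * t[..., 0])) [:, :, None] * perp[:, None, :]
    points = (chord + bend).astype(np.float32)

    bundles: dict[str, set[int]] = {}
    edges = np.linspace(0, F, spec.n_bundles + 1).astype(int)
    for b in range(spec.n_bundles):
        bundles[f"bundle_{b:03d}"] = set(range(edges[b], edges[b + 1]))
    return Tractography(fibers=list(points), bundles=bundles)


def synth_volume_two_class(spec: FixtureSpec) -> Volume:
    """A centered ellipsoidal foreground inside a background, both Gaussian.

    Foreground voxels (inside an ellipsoid with semi-axes at 60% of each
    half-dimension) draw intensities from N(fg_mean, sd²); background from
    N(bg_mean, sd²).  With sd = 0 the volume holds exactly two values.
    """
    rng = np.random.default_rng(spec.seed)
    dims = spec.volume_dims
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in dims], indexing="ij"), axis=-1
    )
    center = (np.array(dims) - 1) / 2.0
    semi = 0.6 * np.array(dims) / 2.0
    mask = (((grid - center) / semi) ** 2).sum(axis=-1) <= 1.0
    data = rng.normal(spec.bg_mean, spec.class_sd, size=dims)
    data[mask] = rng.normal(spec.fg_mean, spec.class_sd, size=int(mask.sum()))
    return Volume(data=data.astype(np.float32), voxel_size=spec.voxel_size)


def synth_icosphere(level: int = 1) -> Mesh:
    """Unit icosphere: subdivided icosahedron projected to the unit sphere.

    ``20 * 4**level`` triangles, watertight, counter-clockwise winding seen
    from outside.
    """
    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    tris = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(verts)
    for _ in range(level):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_tris = []
        for a, b, c in tris:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_tris += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        tris = new_tris
    return Mesh(vertices=np.array(verts, dtype=np.float32), triangles=np.array(tris, dtype=np.int32))
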