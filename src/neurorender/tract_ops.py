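"""Fiber-level processing.

Percentage sampling and bundle selection decide *which* fibers are shown;
equidistant resampling, segment pseudo-normals and tube expansion decide
*how* each fiber is shown.  Sampling follows the count law
``|selection| = max(1, floor(percent/100 * n_eligible))`` using a seeded
shuffle, so for a fixed seed the 10% sample is a subset of the 20% sample.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import Mesh, Tractography

__all__ = [
    "FiberSelection",
    "BundlePalette",
    "sample_fibers",
    "select_bundles",
    "assign_bundle_colors",
    "resample_fiber_equidistant",
    "fiber_segment_directions",
    "fiber_to_tube_mesh",
]


@dataclass
class FiberSelection:
    """An ordered set of fiber indices chosen for display."""

    indices: np.ndarray
    percent: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class BundlePalette:
    """Deterministic bundle-name → RGB color mapping, components in [0, 1]."""

    colors: dict[str, tuple[float, float, float]]
    seed: int = 0

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.colors[name]


def _eligible_indices(t: Tractography, within: Optional[Iterable[str]]) -> np.ndarray:
    if within is None:
        return np.arange(t.n_fibers)
    idx: set[int] = set()
    for name in within:
        if name not in t.bundles:
            raise KeyError(f"unknown bundle {name!r}")
        idx |= t.bundles[name]
    return np.array(sorted(idx), dtype=np.int64)


def sample_fibers(
    t: Tractography,
    percent: int,
    seed: int = 0,
    within: Optional[Iterable[str]] = None,
) -> FiberSelection:
    """Uniform random subset of the eligible fibers, without replacement.

    The subset size is ``floor(percent/100 * n_eligible)`` but never 0 when
    eligible fibers exist.  Sampling takes a seeded random permutation and
    keeps its prefix, so results are reproducible and nested across
    percentages for a fixed seed.
    """
    percent = int(percent)
    if not 1 <= percent <= 100:
        raise ValueError(f"percent must be in [1, 100], got {percent}")
    eligible = _eligible_indices(t, within)
    n = len(eligible)
    if n == 0:
        return FiberSelection(indices=np.array([], dtype=np.int64), percent=percent, seed=seed)
    k = max(1, (percent * n) // 100)
    if k == n:
        chosen = eligible
    else:
        perm = np.random.default_rng(seed).permutation(n)
        chosen = np.sort(eligible[perm[:k]])
    return FiberSelection(indices=chosen, percent=percent, seed=seed)


def select_bundles(t: Tractography, names: Sequence[str]) -> FiberSelection:
    """Union of the named bundles' fiber index sets (percent = 100)."""
    if not t.bundles:
        raise ValueError("tractography carries no bundle labels")
    return FiberSelection(indices=_eligible_indices(t, names), percent=100)


def assign_bundle_colors(t: Tractography, seed: int = 0) -> BundlePalette:
    """One color per bundle from a seeded pseudo-random palette.

    Hues are spaced equally around the color wheel after a seeded random
    rotation (full saturation and value), which guarantees pairwise-distinct
    hues for up to 360 bundles while still looking "random" per seed.
    """
    if not t.bundles:
        raise ValueError("tractography carries no bundle labels")
    names = list(t.bundles)
    offset = float(np.random.default_rng(seed).random())
    colors = {}
    for i, name in enumerate(names):
        h = (offset + i / len(names)) % 1.0
        colors[name] = colorsys.hsv_to_rgb(h, 1.0, 1.0)
    return BundlePalette(colors=colors, seed=seed)


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points.astype(np.float64), axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_fiber_equidistant(f: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a fiber to ``n_points`` equidistant points along its arc.

    Linear interpolation on the original polyline; endpoints are preserved.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pts = np.asarray(f, dtype=np.float64)
    s = _arc_lengths(pts)
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length fiber")
    target = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(target, s, pts[:, k]) for k in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return out.astype(np.float32)


def fiber_segment_directions(f: np.ndarray) -> np.ndarray:
    """Per-point unit pseudo-normals from the local fiber direction.

    Point ``i`` gets the direction of the segment to point ``i+1``; the last
    point reuses the preceding segment's direction.  Zero-length segments
    inherit the nearest non-degenerate direction (previous if any, else next).
    These stand in for surface normals when fibers are drawn as lines.
    """
    pts = np.asarray(f, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("fiber needs at least 2 points")
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if not (norms > 0).any():
        raise ValueError("all fiber points coincide")
    dirs = np.zeros_like(seg)
    good = norms > 0
    dirs[good] = seg[good] / norms[good, None]
    # forward-fill zero segments from the previous direction, backfill the head
    last = None
    for i in range(len(dirs)):
        if good[i]:
            last = dirs[i]
        elif last is not None:
            dirs[i] = last
    first_good = int(np.argmax(good))
    dirs[:first_good] = dirs[first_good]
    return np.vstack([dirs, dirs[-1]]).astype(np.float32)


def _initial_perpendicular(d: np.ndarray) -> np.ndarray:
    probe = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, probe)
    return u / np.linalg.norm(u)


def fiber_to_tube_mesh(f: np.ndarray, radius: float, n_sides: int) -> Mesh:
    """Expand a fiber polyline into an open tube (generalized cylinder).

    One ring of ``n_sides`` vertices is placed perpendicular to the local
    direction at every fiber point; rings are connected by quads split into
    two triangles each.  Ring frames are parallel-transported along the
    fiber so tubes do not twist at bends.  Vertex normals point radially
    outward.
    """
    if n_sides < 3:
        raise ValueError("n_sides must be >= 3")
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(f, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("fiber needs at least 2 points")
    dirs = fiber_segment_directions(pts).astype(np.float64)

    n_pts = len(pts)
    angles = 2 * np.pi * np.arange(n_sides) / n_sides
    verts = np.empty((n_pts, n_sides, 3))
    normals = np.empty_like(verts)
    u = _initial_perpendicular(dirs[0])
    for i in range(n_pts):
        d = dirs[i]
        # parallel transport: project previous u off the new tangent
        u = u - np.dot(u, d) * d
        nu = np.linalg.norm(u)
        u = _initial_perpendicular(d) if nu < 1e-12 else u / nu
        w = np.cross(d, u)
        ring_n = np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * w
        normals[i] = ring_n
        verts[i] = pts[i] + radius * ring_n

    tris = []
    for i in range(n_pts - 1):
        a0 = i * n_sides
        b0 = (i + 1) * n_sides
        for j in range(n_sides):
            jn = (j + 1) % n_sides
            tris.append((a0 + j, b0 + j, b0 + jn))
            tris.append((a0 + j, b0 + jn, a0 + jn))
    return Mesh(
        vertices=verts.reshape(-1, 3).astype(np.float32),
        triangles=np.array(tris, dtype=np.int32),
        normals=normals.reshape(-1, 3).astype(np.float32),
    )
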