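"""Volume-domain computation for slice and volume rendering.

Slices are exact voxel planes (no in-plane interpolation); intensities are
mapped to [0, 1] by an affine min/max normalization.  Volume rendering
rests on three pieces computed here: the Otsu threshold that gates voxel
opacity, the central-difference intensity gradient used as a shading
normal, and the view-aligned slicing plan whose plane count is

    n_s = ceil(sf * sqrt(n_x^2 + n_y^2 + n_z^2)),   sf = 0.2 by default.

The ceiling guarantees the plane stack covers the volume diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import Volume

__all__ = [
    "AxisSlice",
    "WorldPlane",
    "SlicingPlan",
    "AXES",
    "extract_axis_slice",
    "normalize_intensity",
    "otsu_threshold",
    "central_gradient",
    "plan_view_slices",
    "sample_plane",
]

AXES = ("x", "y", "z")


@dataclass
class WorldPlane:
    """A sampled plane: pixel (i, j) sits at ``origin + i*du + j*dv`` (mm)."""

    origin: np.ndarray
    du: np.ndarray
    dv: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.du = np.asarray(self.du, dtype=np.float64).reshape(3)
        self.dv = np.asarray(self.dv, dtype=np.float64).reshape(3)
        self.shape = (int(self.shape[0]), int(self.shape[1]))

    def grid_world(self) -> np.ndarray:
        """(n_u, n_v, 3) world coordinates of every pixel sample."""
        iu = np.arange(self.shape[0])[:, None, None]
        iv = np.arange(self.shape[1])[None, :, None]
        return self.origin + iu * self.du + iv * self.dv

    def corners(self) -> np.ndarray:
        """(4, 3) world corners of the covered rectangle (row-major order)."""
        nu, nv = self.shape
        o = self.origin - 0.5 * self.du - 0.5 * self.dv
        return np.array([o, o + nu * self.du, o + nu * self.du + nv * self.dv, o + nv * self.dv])


@dataclass
class AxisSlice:
    """One axis-aligned voxel plane of a volume."""

    axis: str
    index: int
    image: np.ndarray
    world_plane: WorldPlane


@dataclass
class SlicingPlan:
    """View-aligned plane stack for slice-based volume rendering."""

    n_s: int
    sf: float
    spacing: float
    view_dir: np.ndarray
    planes: list[WorldPlane] = field(default_factory=list)  # ordered far → near

    def __post_init__(self) -> None:
        self.view_dir = np.asarray(self.view_dir, dtype=np.float64).reshape(3)


def extract_axis_slice(v: Volume, axis: str, index: int) -> AxisSlice:
    """Exact voxel plane of *v* perpendicular to an image axis.

    No interpolation: the returned image is the raw voxel plane.  The
    world-space plane geometry is derived from the volume affine.
    """
    axis = str(axis).lower()
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    ax = AXES.index(axis)
    n_axis = v.data.shape[ax]
    index = int(index)
    if not 0 <= index < n_axis:
        raise IndexError(f"slice index {index} outside [0, {n_axis})")
    sel: list = [slice(None)] * 3
    sel[ax] = index
    image = v.data[tuple(sel)]
    u_ax, v_ax = [a for a in range(3) if a != ax]
    vox0 = np.zeros(3)
    vox0[ax] = index
    R, t = v.affine[:3, :3], v.affine[:3, 3]
    plane = WorldPlane(
        origin=R @ vox0 + t,
        du=R[:, u_ax],
        dv=R[:, v_ax],
        shape=(v.data.shape[u_ax], v.data.shape[v_ax]),
    )
    return AxisSlice(axis=axis, index=index, image=image, world_plane=plane)


def normalize_intensity(values: np.ndarray) -> np.ndarray:
    """Affine map of finite values onto [0, 1]; constant input maps to zeros."""
    x = np.asarray(values, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def otsu_threshold(v: Volume, n_bins: int = 256) -> float:
    """Otsu's histogram threshold for a volume.

    Builds an ``n_bins`` histogram spanning [min, max] and returns the lower
    edge of the first bin of the upper class, choosing the split that
    maximizes the between-class variance (ties broken toward the lowest
    qualifying bin).  The value is in the volume's original intensity units.
    """
    data = v.data.ravel().astype(np.float64)
    lo, hi = data.min(), data.max()
    if lo == hi:
        raise ValueError("Otsu threshold undefined for a constant volume")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)                       # weight of class {bins < t} at split t-1
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    # between-class variance for splits t = 1..n_bins-1 (class 0 = bins [0, t))
    w0s, w1s = w0[:-1], 1.0 - w0[:-1]
    valid = (w0s > 0) & (w1s > 0)
    sigma_b = np.full(n_bins - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b[valid] = (mu_t * w0s - mu[:-1])[valid] ** 2 / (w0s * w1s)[valid]
    t = int(np.argmax(sigma_b)) + 1         # argmax takes the lowest tie
    return float(edges[t])


def central_gradient(v: Volume) -> np.ndarray:
    """Intensity gradient field, shape ``(*dims, 3)``, units intensity/mm.

    Central differences in the interior, one-sided at the boundaries,
    scaled by the voxel size per axis.
    """
    gx, gy, gz = np.gradient(v.data.astype(np.float64), *[float(s) for s in v.voxel_size])
    return np.stack([gx, gy, gz], axis=-1)


def _plane_basis(view_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probe = np.array([0.0, 1.0, 0.0]) if abs(view_dir[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(probe, view_dir)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(view_dir, e1)


def plan_view_slices(
    v: Volume,
    view_dir: np.ndarray,
    sf: float = 0.2,
    samples_per_mm: float = 1.0,
) -> SlicingPlan:
    """Plan the view-perpendicular plane stack for volume rendering.

    The number of planes is ``ceil(sf * sqrt(n_x^2 + n_y^2 + n_z^2))``;
    planes are perpendicular to *view_dir*, uniformly spaced so the stack
    spans the world bounding-box diagonal, ordered far → near (so that
    compositing front-to-back of the list is back-to-front in depth).
    ``samples_per_mm`` sets the in-plane sampling density of each plane.
    """
    if sf <= 0:
        raise ValueError("sf must be positive")
    d = np.asarray(view_dir, dtype=np.float64).reshape(3)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("view direction must be non-zero")
    d = d / nd
    nx, ny, nz = v.data.shape
    n_s = int(np.ceil(sf * float(np.sqrt(nx * nx + ny * ny + nz * nz))))

    lo, hi = v.world_bounds()
    center = 0.5 * (lo + hi)
    diag = float(np.linalg.norm(hi - lo))
    if diag == 0:
        diag = 1.0
    spacing = diag / n_s
    e1, e2 = _plane_basis(d)
    half = 0.5 * diag
    n_pix = max(2, int(np.ceil(diag * samples_per_mm)))
    step = diag / n_pix
    planes = []
    # offsets run from the far side (-view_dir is toward the viewer)
    for i in range(n_s):
        offset = half - (i + 0.5) * spacing
        c = center + offset * d
        origin = c - (half - 0.5 * step) * e1 - (half - 0.5 * step) * e2
        planes.append(WorldPlane(origin=origin, du=step * e1, dv=step * e2, shape=(n_pix, n_pix)))
    return SlicingPlan(n_s=n_s, sf=float(sf), spacing=spacing, view_dir=d, planes=planes)


def world_to_voxel(v: Volume, world: np.ndarray) -> np.ndarray:
    """Map world-mm coordinates to (fractional) voxel indices."""
    inv = np.linalg.inv(v.affine)
    w = np.asarray(world, dtype=np.float64)
    return w @ inv[:3, :3].T + inv[:3, 3]


def sample_plane(
    v: Volume,
    plane: WorldPlane,
    resolution: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Nearest-voxel intensities of *v* over a world-space plane.

    Pixels whose world position falls outside the voxel grid are NaN
    ("empty"; they get zero opacity downstream).  Raises when no sample
    lands inside the volume at all.
    """
    if resolution is not None:
        nu, nv = plane.shape
        ru, rv = int(resolution[0]), int(resolution[1])
        plane = WorldPlane(
            origin=plane.origin,
            du=plane.du * (nu / ru) if ru > 1 else plane.du * nu,
            dv=plane.dv * (nv / rv) if rv > 1 else plane.dv * nv,
            shape=(ru, rv),
        )
    world = plane.grid_world()
    vox = world_to_voxel(v, world.reshape(-1, 3))
    idx = np.round(vox).astype(np.int64)
    dims = np.array(v.data.shape)
    inside = ((idx >= 0) & (idx < dims)).all(axis=1)
    if not inside.any():
        raise ValueError("plane does not intersect the volume")
    out = np.full(len(idx), np.nan)
    ii = idx[inside]
    out[inside] = v.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out.reshape(plane.shape)
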