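"""Software rasterization and compositing of combined 3D brain-data scenes.

The renderer draws what a GPU pipeline would, as plain array passes:

* fibers as Bresenham lines (pseudo-normals from the local fiber
  direction) or as expanded tube meshes;
* axis-aligned volume slices as textured quads (nearest-voxel lookup,
  min/max intensity normalization);
* slice-stack volume rendering: view-perpendicular planes composited far
  to near, voxel opacity gated by the Otsu threshold, shading normals
  from the intensity gradient;
* meshes with Gouraud-interpolated Phong illumination, transparent ones
  depth-sorted back to front (painter's algorithm);

all lit by the Phong model

    I = La*Ka + Ld*Kd*(l.n) + Ls*Ks*(r.v)^f

with clamped dot products and the specular term gated on a positive
diffuse term.  Opaque primitives use a z-buffer; transparent ones are
composited with the non-premultiplied "over" operator against it.
Rendering is fully deterministic for a fixed scene and camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .camera import CameraPose, view_matrix
from .io_formats import Mesh, Tractography, Volume
from .mesh_ops import compute_vertex_normals, depth_sort_triangles, extract_wireframe_edges
from .tract_ops import BundlePalette, FiberSelection, fiber_segment_directions, fiber_to_tube_mesh
from .volume_ops import (
    central_gradient,
    extract_axis_slice,
    normalize_intensity,
    otsu_threshold,
    plan_view_slices,
    world_to_voxel,
)

__all__ = [
    "LightingParams",
    "Material",
    "Scene",
    "RasterImage",
    "TractographyItem",
    "SliceItem",
    "VolumeItem",
    "MeshItem",
    "phong_intensity",
    "composite_over",
    "project_point",
    "render_scene",
]

# defaults used when a scene does not override them
DEFAULT_FOV_DEG = 45.0
DEFAULT_LIGHTING = dict(L_a=0.8, L_d=0.9, L_s=0.5)
DEFAULT_MATERIAL = dict(K_a=1.0, K_d=1.0, K_s=0.5, f=14.0)


@dataclass
class LightingParams:
    """Global light: ambient/diffuse/specular components and light direction.

    ``light_dir`` points *toward* the light; ``None`` means headlight
    (light at the camera), resolved at render time.
    """

    L_a: float = DEFAULT_LIGHTING["L_a"]
    L_d: float = DEFAULT_LIGHTING["L_d"]
    L_s: float = DEFAULT_LIGHTING["L_s"]
    light_dir: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("L_a", "L_d", "L_s"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            setattr(self, name, v)
        if self.light_dir is not None:
            d = np.asarray(self.light_dir, dtype=np.float64).reshape(3)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("light_dir must be non-zero")
            self.light_dir = d / n


@dataclass
class Material:
    """Reflection constants, shininess, base color and opacity of an object."""

    K_a: float = DEFAULT_MATERIAL["K_a"]
    K_d: float = DEFAULT_MATERIAL["K_d"]
    K_s: float = DEFAULT_MATERIAL["K_s"]
    f: float = DEFAULT_MATERIAL["f"]
    base_color: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K_a", "K_d", "K_s", "alpha"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            setattr(self, name, v)
        if self.f < 0:
            raise ValueError("shininess must be >= 0")


@dataclass
class TractographyItem:
    tractography: Tractography
    selection: Optional[FiberSelection] = None
    palette: Optional[BundlePalette] = None
    mode: str = "lines"  # "lines" | "cylinders"
    material: Material = field(default_factory=Material)
    radius: float = 0.3
    n_sides: int = 6

    def __post_init__(self) -> None:
        if self.mode not in ("lines", "cylinders"):
            raise ValueError(f"unknown tractography mode {self.mode!r}")


@dataclass
class SliceItem:
    volume: Volume
    axis: str = "z"
    index: int = 0


@dataclass
class VolumeItem:
    volume: Volume
    sf: float = 0.2
    alpha: float = 1.0
    material: Material = field(default_factory=Material)


@dataclass
class MeshItem:
    mesh: Mesh
    material: Material = field(default_factory=Material)
    wireframe: bool = False
    wire_color: tuple[float, float, float] = (1.0, 1.0, 1.0)


SceneObject = Union[TractographyItem, SliceItem, VolumeItem, MeshItem]


@dataclass
class Scene:
    objects: list = field(default_factory=list)
    lighting: LightingParams = field(default_factory=LightingParams)
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class RasterImage:
    """RGBA framebuffer (channels in [0, 1]) plus camera-space depth buffer."""

    rgba: np.ndarray
    depth: np.ndarray

    @property
    def width(self) -> int:
        return self.rgba.shape[1]

    @property
    def height(self) -> int:
        return self.rgba.shape[0]

    def to_uint8(self) -> np.ndarray:
        return np.round(np.clip(self.rgba, 0.0, 1.0) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# shading and compositing primitives
# ---------------------------------------------------------------------------


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64).reshape(3)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError(f"{name} must be unit length")
    return v


def phong_intensity(lp: LightingParams, mat: Material, n: np.ndarray, v: np.ndarray) -> float:
    """Phong illumination at a surface point with unit normal *n* seen along *v*.

    ``I = La*Ka + Ld*Kd*max(0, l.n) + Ls*Ks*max(0, r.v)^f`` where ``r`` is
    the reflection of the light direction about the normal.  The specular
    term is forced to 0 when the light is behind the surface.
    """
    n = _check_unit(n, "normal")
    v = _check_unit(v, "view vector")
    if lp.light_dir is None:
        raise ValueError("phong_intensity needs an explicit light direction")
    l = lp.light_dir
    I = lp.L_a * mat.K_a
    ln = float(np.dot(l, n))
    if ln > 0:
        I += lp.L_d * mat.K_d * ln
        r = 2.0 * ln * n - l
        rv = max(0.0, float(np.dot(r, v)))
        I += lp.L_s * mat.K_s * rv**mat.f
    return I


def _phong_shade(
    lp: LightingParams,
    mat: Material,
    normals: np.ndarray,
    views: np.ndarray,
    light: np.ndarray,
) -> np.ndarray:
    """Vectorized Phong over (N, 3) normals and unit view vectors."""
    ln = np.clip(normals @ light, 0.0, None)
    I = np.full(len(normals), lp.L_a * mat.K_a)
    lit = ln > 0
    if lit.any():
        I[lit] += lp.L_d * mat.K_d * ln[lit]
        r = 2.0 * ln[lit, None] * normals[lit] - light
        rv = np.clip(np.einsum("ij,ij->i", r, views[lit]), 0.0, None)
        I[lit] += lp.L_s * mat.K_s * rv**mat.f
    return I


def composite_over(front: np.ndarray, back: np.ndarray) -> np.ndarray:
    """Non-premultiplied "over" of two RGBA values (or arrays).

    ``C = af*Cf + (1-af)*ab*Cb``, ``a = af + (1-af)*ab``, stored color
    renormalized by ``a`` where positive.
    """
    front = np.asarray(front, dtype=np.float64)
    back = np.asarray(back, dtype=np.float64)
    af, ab = front[..., 3:4], back[..., 3:4]
    a = af + (1.0 - af) * ab
    c = front[..., :3] * af + back[..., :3] * (1.0 - af) * ab
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(a > 0, c / np.where(a > 0, a, 1.0), 0.0)
    return np.concatenate([c, a], axis=-1)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _projector(c: CameraPose, width: int, height: int, fov: float):
    """Build a vectorized world→screen mapper for one camera/image setup."""
    M = view_matrix(c)
    focal = 1.0 / np.tan(np.deg2rad(fov) / 2.0)
    aspect = width / height
    near, far = 0.01 * c.r, 100.0 * c.r

    def project(pts: np.ndarray):
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        cam = pts @ M[:3, :3].T + M[:3, 3]
        depth = -cam[:, 2]
        visible = (depth > near) & (depth < far)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_ndc = (focal / aspect) * cam[:, 0] / depth
            y_ndc = focal * cam[:, 1] / depth
        px = (x_ndc + 1.0) * 0.5 * width
        py = (1.0 - y_ndc) * 0.5 * height
        return px, py, depth, visible

    return project


def project_point(
    p: np.ndarray,
    c: CameraPose,
    width: int,
    height: int,
    fov: float = DEFAULT_FOV_DEG,
) -> tuple[float, float, float, bool]:
    """Perspective-project a world point to continuous pixel coordinates.

    Returns ``(px, py, depth, visible)`` with the pixel origin at the
    top-left corner; ``visible`` is False behind the near plane (0.01 r)
    or beyond the far plane (100 r).  The focus point lands on the image
    center.
    """
    p = np.asarray(p, dtype=np.float64).reshape(3)
    if np.allclose(p, c.eye):
        raise ValueError("cannot project the eye point itself")
    px, py, depth, vis = _projector(c, width, height, fov)(p[None, :])
    return float(px[0]), float(py[0]), float(depth[0]), bool(vis[0])


# ---------------------------------------------------------------------------
# rasterization primitives
# ---------------------------------------------------------------------------


def _bresenham(x0: int, y0: int, x1: int, y1: int) -> list[tuple[int, int]]:
    """Integer Bresenham segment, endpoints inclusive."""
    pts = []
    dx, dy = abs(x1 - x0), -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    while True:
        pts.append((x0, y0))
        if x0 == x1 and y0 == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy
    return pts


def _triangle_fragments(p2d: np.ndarray, depths: np.ndarray, attrs: np.ndarray, width: int, height: int):
    """Pixel fragments covered by one screen-space triangle.

    Returns ``(xs, ys, z, a)``: integer pixel coords, perspective-correct
    depths and interpolated attributes (``attrs`` is (3, k) per-vertex).
    Pixels are covered when their center lies inside the triangle.
    """
    x0 = max(int(np.floor(p2d[:, 0].min())), 0)
    x1 = min(int(np.ceil(p2d[:, 0].max())), width - 1)
    y0 = max(int(np.floor(p2d[:, 1].min())), 0)
    y1 = min(int(np.ceil(p2d[:, 1].max())), height - 1)
    if x1 < x0 or y1 < y0:
        return None
    a, b, cpt = p2d
    area = (b[0] - a[0]) * (cpt[1] - a[1]) - (b[1] - a[1]) * (cpt[0] - a[0])
    if abs(area) < 1e-12:
        return None
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px = xs.ravel() + 0.5
    py = ys.ravel() + 0.5
    w0 = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) / area
    w1 = ((cpt[0] - b[0]) * (py - b[1]) - (cpt[1] - b[1]) * (px - b[0])) / area
    # barycentric: l0 multiplies vertex a, etc.
    l2, l0 = w0, w1
    l1 = 1.0 - l0 - l2
    inside = (l0 >= 0) & (l1 >= 0) & (l2 >= 0)
    if not inside.any():
        return None
    L = np.stack([l0[inside], l1[inside], l2[inside]], axis=1)  # (N, 3)
    inv_z = L @ (1.0 / depths)
    z = 1.0 / inv_z
    a_over_z = attrs / depths[:, None]
    interp = (L @ a_over_z) * z[:, None]
    return xs.ravel()[inside], ys.ravel()[inside], z, interp


def _blend_fragments(img: RasterImage, xs, ys, z, colors, alpha, *, opaque: bool) -> None:
    """Depth-test fragments against the z-buffer and write/composite them."""
    if opaque:
        # resolve duplicate pixels: keep the nearest fragment per pixel
        order = np.lexsort((z, ys, xs))
        xs, ys, z, colors = xs[order], ys[order], z[order], colors[order]
        keep = np.ones(len(xs), dtype=bool)
        keep[1:] = (xs[1:] != xs[:-1]) | (ys[1:] != ys[:-1])
        xs, ys, z, colors = xs[keep], ys[keep], z[keep], colors[keep]
        passed = z < img.depth[ys, xs]
        xs, ys, z, colors = xs[passed], ys[passed], z[passed], colors[passed]
        img.rgba[ys, xs, :3] = np.clip(colors, 0.0, 1.0)
        img.rgba[ys, xs, 3] = 1.0
        img.depth[ys, xs] = z
    else:
        passed = z < img.depth[ys, xs]
        xs, ys, z, colors = xs[passed], ys[passed], z[passed], colors[passed]
        for x, y, col in zip(xs, ys, colors):  # sequential: over-compositing order matters
            front = np.array([*np.clip(col, 0.0, 1.0), alpha])
            img.rgba[y, x] = composite_over(front, img.rgba[y, x])


def _draw_line(img: RasterImage, p0, p1, z0, z1, c0, c1) -> None:
    """Opaque Bresenham line with per-pixel depth and color interpolation."""
    x0, y0 = int(np.floor(p0[0])), int(np.floor(p0[1]))
    x1, y1 = int(np.floor(p1[0])), int(np.floor(p1[1]))
    pts = _bresenham(x0, y0, x1, y1)
    n = max(len(pts) - 1, 1)
    for i, (x, y) in enumerate(pts):
        if not (0 <= x < img.width and 0 <= y < img.height):
            continue
        t = i / n
        z = 1.0 / ((1.0 - t) / z0 + t / z1)
        if z < img.depth[y, x]:
            col = (1.0 - t) * np.asarray(c0) + t * np.asarray(c1)
            img.rgba[y, x, :3] = np.clip(col, 0.0, 1.0)
            img.rgba[y, x, 3] = 1.0
            img.depth[y, x] = z


# ---------------------------------------------------------------------------
# per-object passes
# ---------------------------------------------------------------------------


def _resolve_light(scene: Scene, cam: CameraPose) -> np.ndarray:
    if scene.lighting.light_dir is not None:
        return scene.lighting.light_dir
    return -cam.view_dir  # headlight: toward the camera


def _shade_mesh_vertices(
    mesh: Mesh, mat: Material, lp: LightingParams, light: np.ndarray, eye: np.ndarray
) -> np.ndarray:
    """Per-vertex shaded colors (Gouraud): Phong at each vertex."""
    mesh = compute_vertex_normals(mesh)
    views = eye - mesh.vertices.astype(np.float64)
    views /= np.maximum(np.linalg.norm(views, axis=1, keepdims=True), 1e-12)
    I = _phong_shade(lp, mat, mesh.normals.astype(np.float64), views, light)
    return np.clip(I[:, None] * np.asarray(mat.base_color), 0.0, 1.0)


def _draw_mesh(
    img: RasterImage,
    project,
    mesh: Mesh,
    mat: Material,
    lp: LightingParams,
    light: np.ndarray,
    eye: np.ndarray,
    *,
    opaque: bool,
) -> None:
    colors = _shade_mesh_vertices(mesh, mat, lp, light, eye)
    verts = mesh.vertices.astype(np.float64)
    px, py, z, vis = project(verts)
    tris = mesh.triangles
    if not opaque:
        tris = tris[depth_sort_triangles(mesh, eye).order]
    for tri in tris:
        if not vis[tri].all():
            continue
        frag = _triangle_fragments(
            np.column_stack([px[tri], py[tri]]), z[tri], colors[tri], img.width, img.height
        )
        if frag is None:
            continue
        xs, ys, fz, fc = frag
        _blend_fragments(img, xs, ys, fz, fc, mat.alpha, opaque=opaque)


def _draw_wireframe(img: RasterImage, project, mesh: Mesh, color) -> None:
    verts = mesh.vertices.astype(np.float64)
    px, py, z, vis = project(verts)
    z_bias = 1.0 - 1e-4  # pull edges slightly forward so they win over faces
    col = np.asarray(color, dtype=np.float64)
    for i, j in extract_wireframe_edges(mesh):
        if vis[i] and vis[j]:
            _draw_line(img, (px[i], py[i]), (px[j], py[j]), z[i] * z_bias, z[j] * z_bias, col, col)


def _fiber_color_map(item: TractographyItem) -> dict[int, np.ndarray]:
    base = np.asarray(item.material.base_color, dtype=np.float64)
    cmap: dict[int, np.ndarray] = {}
    if item.palette is not None:
        for name, idx in item.tractography.bundles.items():
            col = np.asarray(item.palette[name], dtype=np.float64)
            for i in idx:
                cmap[i] = col
    return {i: cmap.get(i, base) for i in range(item.tractography.n_fibers)}


def _draw_tractography(
    img: RasterImage,
    project,
    item: TractographyItem,
    lp: LightingParams,
    light: np.ndarray,
    eye: np.ndarray,
) -> None:
    t = item.tractography
    indices = item.selection.indices if item.selection is not None else np.arange(t.n_fibers)
    cmap = _fiber_color_map(item)
    for fi in indices:
        fiber = t.fibers[int(fi)]
        color = cmap[int(fi)]
        if item.mode == "cylinders":
            tube = fiber_to_tube_mesh(fiber, item.radius, item.n_sides)
            mat = Material(
                K_a=item.material.K_a, K_d=item.material.K_d, K_s=item.material.K_s,
                f=item.material.f, base_color=tuple(color), alpha=1.0,
            )
            _draw_mesh(img, project, tube, mat, lp, light, eye, opaque=True)
            continue
        pts = fiber.astype(np.float64)
        normals = fiber_segment_directions(fiber).astype(np.float64)
        views = eye - pts
        views /= np.maximum(np.linalg.norm(views, axis=1, keepdims=True), 1e-12)
        I = _phong_shade(lp, item.material, normals, views, light)
        cols = np.clip(I[:, None] * color, 0.0, 1.0)
        px, py, z, vis = project(pts)
        for i in range(len(pts) - 1):
            if vis[i] and vis[i + 1]:
                _draw_line(
                    img, (px[i], py[i]), (px[i + 1], py[i + 1]), z[i], z[i + 1], cols[i], cols[i + 1]
                )


def _draw_axis_slice(img: RasterImage, project, item: SliceItem) -> None:
    sl = extract_axis_slice(item.volume, item.axis, item.index)
    norm_vol = normalize_intensity(item.volume.data)
    plane = sl.world_plane
    corners = plane.corners()
    px, py, z, vis = project(corners)
    if not vis.all():
        return
    for tri in ((0, 1, 2), (0, 2, 3)):
        idx = list(tri)
        frag = _triangle_fragments(
            np.column_stack([px[idx], py[idx]]), z[idx], corners[idx], img.width, img.height
        )
        if frag is None:
            continue
        xs, ys, fz, fworld = frag
        vox = np.round(world_to_voxel(item.volume, fworld)).astype(np.int64)
        dims = np.array(item.volume.data.shape)
        ok = ((vox >= 0) & (vox < dims)).all(axis=1)
        if not ok.any():
            continue
        vals = norm_vol[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
        gray = np.repeat(vals[:, None], 3, axis=1)
        _blend_fragments(img, xs[ok], ys[ok], fz[ok], gray, 1.0, opaque=True)


def _draw_volume(
    img: RasterImage,
    project,
    item: VolumeItem,
    lp: LightingParams,
    light: np.ndarray,
    cam: CameraPose,
) -> None:
    vol = item.volume
    thr = otsu_threshold(vol)
    grad = central_gradient(vol)
    norm_vol = normalize_intensity(vol.data)
    plan = plan_view_slices(vol, cam.view_dir, item.sf)
    slice_alpha = min(1.0, item.alpha / plan.n_s)
    base = np.asarray(item.material.base_color, dtype=np.float64)
    dims = np.array(vol.data.shape)
    toward_eye = -cam.view_dir
    for plane in plan.planes:  # far → near
        corners = plane.corners()
        px, py, z, vis = project(corners)
        if not vis.all():
            continue
        for tri in ((0, 1, 2), (0, 2, 3)):
            idx = list(tri)
            frag = _triangle_fragments(
                np.column_stack([px[idx], py[idx]]), z[idx], corners[idx], img.width, img.height
            )
            if frag is None:
                continue
            xs, ys, fz, fworld = frag
            vox = np.round(world_to_voxel(vol, fworld)).astype(np.int64)
            ok = ((vox >= 0) & (vox < dims)).all(axis=1)
            if not ok.any():
                continue
            xs, ys, fz, vox = xs[ok], ys[ok], fz[ok], vox[ok]
            vals = vol.data[vox[:, 0], vox[:, 1], vox[:, 2]]
            lit = vals >= thr  # Otsu gate: below-threshold voxels are empty
            if not lit.any():
                continue
            xs, ys, fz, vox = xs[lit], ys[lit], fz[lit], vox[lit]
            g = grad[vox[:, 0], vox[:, 1], vox[:, 2]]
            gn = np.linalg.norm(g, axis=1, keepdims=True)
            normals = np.where(gn > 1e-12, g / np.maximum(gn, 1e-12), toward_eye)
            # flip normals toward the viewer so shading is side-independent
            flip = (normals @ toward_eye) < 0
            normals[flip] *= -1.0
            views = np.broadcast_to(toward_eye, normals.shape)
            I = _phong_shade(lp, item.material, normals, views, light)
            intens = norm_vol[vox[:, 0], vox[:, 1], vox[:, 2]]
            cols = np.clip((I * intens)[:, None] * base, 0.0, 1.0)
            _blend_fragments(img, xs, ys, fz, cols, slice_alpha, opaque=False)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------


def render_scene(
    s: Scene,
    c: CameraPose,
    width: int,
    height: int,
    fov: float = DEFAULT_FOV_DEG,
) -> RasterImage:
    """Render a scene to an RGBA raster image.

    Two passes: opaque objects (axis slices, opaque meshes, fibers as lines
    or cylinders) are rasterized with z-buffer depth testing; transparent
    objects (volume slice stacks far→near, transparent meshes back-to-front)
    are then composited with the "over" operator against the depth buffer.
    Deterministic for a fixed scene and camera.
    """
    width, height = int(width), int(height)
    if width < 1 or height < 1:
        raise ValueError("image must be at least 1x1 pixels")
    bg = np.asarray(s.background, dtype=np.float64).reshape(3)
    rgba = np.empty((height, width, 4))
    rgba[..., :3] = bg
    rgba[..., 3] = 1.0
    img = RasterImage(rgba=rgba, depth=np.full((height, width), np.inf))
    project = _projector(c, width, height, fov)
    light = _resolve_light(s, c)
    lp = s.lighting
    eye = c.eye

    # opaque pass
    for obj in s.objects:
        if isinstance(obj, SliceItem):
            _draw_axis_slice(img, project, obj)
        elif isinstance(obj, MeshItem) and obj.material.alpha >= 1.0:
            _draw_mesh(img, project, obj.mesh, obj.material, lp, light, eye, opaque=True)
            if obj.wireframe:
                _draw_wireframe(img, project, obj.mesh, obj.wire_color)
        elif isinstance(obj, TractographyItem):
            _draw_tractography(img, project, obj, lp, light, eye)

    # transparent pass
    for obj in s.objects:
        if isinstance(obj, VolumeItem):
            _draw_volume(img, project, obj, lp, light, c)
        elif isinstance(obj, MeshItem) and obj.material.alpha < 1.0:
            _draw_mesh(img, project, obj.mesh, obj.material, lp, light, eye, opaque=False)
            if obj.wireframe:
                _draw_wireframe(img, project, obj.mesh, obj.wire_color)

    np.clip(img.rgba, 0.0, 1.0, out=img.rgba)
    return img
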