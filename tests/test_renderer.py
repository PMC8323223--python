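"""Phong shading, compositing, projection and full-scene rasterization."""

import numpy as np
import pytest

from neurorender.camera import make_camera, orbit
from neurorender.io_formats import Mesh, Tractography
from neurorender.renderer import (
    LightingParams,
    Material,
    MeshItem,
    Scene,
    SliceItem,
    TractographyItem,
    VolumeItem,
    composite_over,
    phong_intensity,
    project_point,
    render_scene,
)
from neurorender.tract_ops import sample_fibers

EZ = np.array([0.0, 0.0, 1.0])


def ambient_only(value=1.0):
    return LightingParams(L_a=value, L_d=0.0, L_s=0.0, light_dir=EZ)


# ---------------------------------------------------------------------- phong


def test_phong_ambient_only_independent_of_geometry():
    lp = LightingParams(L_a=1.0, L_d=1.0, L_s=1.0, light_dir=EZ)
    mat = Material(K_a=1.0, K_d=0.0, K_s=0.0, f=1.0)
    for n in ([0, 0, 1], [1, 0, 0], [0, -1, 0]):
        assert phong_intensity(lp, mat, n, EZ) == pytest.approx(1.0)


def test_phong_fully_aligned_unit_case():
    lp = LightingParams(L_a=1.0, L_d=1.0, L_s=1.0, light_dir=EZ)
    mat = Material(K_a=1.0, K_d=1.0, K_s=1.0, f=1.0)
    # n = l and v = r = l: every dot product is 1
    assert phong_intensity(lp, mat, EZ, EZ) == pytest.approx(3.0)


def test_phong_orthogonal_light_leaves_ambient_term():
    lp = LightingParams(L_a=0.5, L_d=1.0, L_s=1.0, light_dir=[1, 0, 0])
    mat = Material(K_a=0.5, K_d=1.0, K_s=1.0, f=2.0)
    assert phong_intensity(lp, mat, EZ, EZ) == pytest.approx(0.25)


def test_phong_light_behind_surface_kills_specular():
    lp = LightingParams(L_a=0.0, L_d=1.0, L_s=1.0, light_dir=[0, 0, -1])
    mat = Material(K_a=0.0, K_d=1.0, K_s=1.0, f=1.0)
    assert phong_intensity(lp, mat, EZ, EZ) == pytest.approx(0.0)


def test_phong_rejects_non_unit_vectors():
    lp = LightingParams(light_dir=EZ)
    with pytest.raises(ValueError):
        phong_intensity(lp, Material(), [0, 0, 2], EZ)
    with pytest.raises(ValueError):
        phong_intensity(lp, Material(), EZ, [0, 0, 0.5])


def test_lighting_constants_validated():
    with pytest.raises(ValueError):
        LightingParams(L_a=1.5)
    with pytest.raises(ValueError):
        Material(K_d=-0.1)


# ----------------------------------------------------------------- compositing


def test_over_identities():
    front = np.array([0.2, 0.4, 0.6, 1.0])
    back = np.array([0.9, 0.1, 0.3, 0.7])
    assert np.allclose(composite_over(front, back), front)
    transparent = np.array([0.5, 0.5, 0.5, 0.0])
    assert np.allclose(composite_over(transparent, back), back)


def test_over_half_red_on_blue():
    out = composite_over([1, 0, 0, 0.5], [0, 0, 1, 1.0])
    assert np.allclose(out, [0.5, 0, 0.5, 1.0])


def test_over_alpha_associative():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b, c = rng.random((3, 4))
        left = composite_over(a, composite_over(b, c))
        right_alpha = composite_over(composite_over(a, b), c)[3]
        assert left[3] == pytest.approx(right_alpha, abs=1e-12)


# ------------------------------------------------------------------ projection


def test_center_projects_to_image_center():
    cam = make_camera([5, 5, 5], 100.0, theta=0.4, phi=1.0)
    px, py, depth, vis = project_point([5, 5, 5], cam, 64, 48)
    assert (px, py) == pytest.approx((32.0, 24.0), abs=1e-9)
    assert depth == pytest.approx(100.0)
    assert vis


def test_projecting_eye_point_rejected():
    cam = make_camera([0, 0, 0], 10.0)
    with pytest.raises(ValueError):
        project_point(cam.eye, cam, 64, 64)


def test_symmetric_points_project_symmetrically():
    cam = make_camera([0, 0, 0], 50.0)
    pl = project_point([-7, 0, 0], cam, 100, 100)
    pr = project_point([7, 0, 0], cam, 100, 100)
    assert pl[0] == pytest.approx(100 - pr[0], abs=1e-9)
    assert pl[1] == pytest.approx(pr[1], abs=1e-9)


def test_point_behind_eye_flagged():
    cam = make_camera([0, 0, 0], 10.0)
    assert project_point([0, 0, 20], cam, 64, 64)[3] is False


# ---------------------------------------------------------------- scene render


def test_empty_scene_background_fill():
    img = render_scene(Scene(background=(0, 0, 0)), make_camera([0, 0, 0], 10.0), 32, 16)
    assert img.rgba.shape == (16, 32, 4)
    assert np.all(img.rgba[..., :3] == 0.0) and np.all(img.rgba[..., 3] == 1.0)
    img2 = render_scene(Scene(background=(0.2, 0.4, 0.6)), make_camera([0, 0, 0], 10.0), 8, 8)
    assert np.allclose(img2.rgba[..., :3], [0.2, 0.4, 0.6])


def test_zero_size_image_rejected():
    with pytest.raises(ValueError):
        render_scene(Scene(), make_camera([0, 0, 0], 10.0), 0, 10)


def _oracle_bresenham(x0, y0, x1, y1):
    """Independent octant-based Bresenham (decision-variable formulation)."""
    pts = []
    steep = abs(y1 - y0) > abs(x1 - x0)
    if steep:
        x0, y0, x1, y1 = y0, x0, y1, x1
    swapped = x0 > x1
    if swapped:
        x0, y0, x1, y1 = x1, y1, x0, y0
    dx, dy = x1 - x0, abs(y1 - y0)
    d = 2 * dy - dx
    y, ystep = y0, (1 if y0 < y1 else -1)
    for x in range(x0, x1 + 1):
        pts.append((y, x) if steep else (x, y))
        if d > 0:
            y += ystep
            d -= 2 * dx
        d += 2 * dy
    if swapped:
        pts.reverse()
    return pts


def test_single_fiber_line_matches_bresenham_oracle():
    a, b = np.array([-19.0, -11.0, 0.0]), np.array([21.0, 13.0, 0.0])
    t = Tractography(fibers=[np.array([a, b], dtype=np.float32)])
    scene = Scene(
        objects=[TractographyItem(tractography=t, material=Material(base_color=(1, 1, 1)))],
        lighting=ambient_only(),
        background=(0, 0, 0),
    )
    cam = make_camera([0, 0, 0], 80.0)
    img = render_scene(scene, cam, 64, 64)
    lit = {(x, y) for y, x in zip(*np.where(img.rgba[..., 0] > 0))}
    pa = project_point(a, cam, 64, 64)
    pb = project_point(b, cam, 64, 64)
    expected = set(
        _oracle_bresenham(
            int(np.floor(pa[0])), int(np.floor(pa[1])),
            int(np.floor(pb[0])), int(np.floor(pb[1])),
        )
    )
    assert lit == expected


def _big_triangle(z=0.0):
    verts = np.array([[-30, -30, z], [30, -30, z], [0, 40, z]], dtype=np.float32)
    return Mesh(vertices=verts, triangles=np.array([[0, 1, 2]]))


def test_opaque_vs_half_transparent_triangle_over_white():
    cam = make_camera([0, 0, 0], 50.0)
    for alpha, expected in ((1.0, (1, 0, 0)), (0.5, (1, 0.5, 0.5))):
        scene = Scene(
            objects=[MeshItem(mesh=_big_triangle(), material=Material(
                K_a=1.0, base_color=(1, 0, 0), alpha=alpha))],
            lighting=ambient_only(),
            background=(1, 1, 1),
        )
        img = render_scene(scene, cam, 33, 33)
        assert np.allclose(img.rgba[16, 16, :3], expected, atol=1e-6)


def test_ambient_only_color_invariant_under_orbit(icosphere):
    mesh = Mesh(vertices=(icosphere.vertices * 10).astype(np.float32), triangles=icosphere.triangles)
    scene = Scene(
        objects=[MeshItem(mesh=mesh, material=Material(K_a=0.6, base_color=(0.5, 1.0, 0.25)))],
        lighting=LightingParams(L_a=1.0, L_d=0.0, L_s=0.0),  # headlight, but only ambient
        background=(0, 0, 0),
    )
    cam = make_camera([0, 0, 0], 60.0)
    expected = np.array([0.3, 0.6, 0.15])
    rng = np.random.default_rng(8)
    for _ in range(5):
        cam = orbit(cam, rng.uniform(-1, 1), rng.uniform(-1, 1))
        img = render_scene(scene, cam, 40, 40)
        obj = img.rgba[..., :3][np.any(img.rgba[..., :3] != 0.0, axis=-1)]
        assert len(obj) > 0
        assert np.allclose(obj, expected, atol=1e-6)


def test_painter_consistency_nearer_opaque_wins():
    far_tri = _big_triangle(z=0.0)
    near_tri = _big_triangle(z=10.0)
    cam = make_camera([0, 0, 0], 50.0)
    for order in ([far_tri, near_tri], [near_tri, far_tri]):
        scene = Scene(
            objects=[
                MeshItem(mesh=order[0], material=Material(K_a=1.0, base_color=(1, 0, 0))),
                MeshItem(mesh=order[1], material=Material(K_a=1.0, base_color=(0, 1, 0))),
            ],
            lighting=ambient_only(),
        )
        img = render_scene(scene, cam, 33, 33)
        near_color = (0, 1, 0) if order[1] is near_tri else (1, 0, 0)
        assert np.allclose(img.rgba[16, 16, :3], near_color)
        assert img.depth[16, 16] == pytest.approx(40.0, rel=1e-6)


def test_full_sample_render_equals_unsampled(small_tract):
    cam = make_camera([50, 50, 50], 250.0, theta=0.3, phi=0.2)
    lighting = LightingParams()
    base = Scene(objects=[TractographyItem(tractography=small_tract)], lighting=lighting)
    sel = sample_fibers(small_tract, 100, seed=0)
    sampled = Scene(
        objects=[TractographyItem(tractography=small_tract, selection=sel)], lighting=lighting
    )
    img_a = render_scene(base, cam, 64, 64)
    img_b = render_scene(sampled, cam, 64, 64)
    assert np.array_equal(img_a.rgba, img_b.rgba)


def test_render_bitwise_deterministic(small_tract, two_class_volume, icosphere):
    mesh = Mesh(vertices=(icosphere.vertices * 20 + 50).astype(np.float32),
                triangles=icosphere.triangles)
    scene = Scene(
        objects=[
            TractographyItem(tractography=small_tract, mode="cylinders", radius=0.5, n_sides=4),
            SliceItem(volume=two_class_volume, axis="z", index=8),
            VolumeItem(volume=two_class_volume, alpha=0.6),
            MeshItem(mesh=mesh, material=Material(alpha=0.5), wireframe=True),
        ],
    )
    cam = make_camera([30, 30, 30], 150.0, theta=0.5, phi=0.7)
    img_a = render_scene(scene, cam, 48, 48)
    img_b = render_scene(scene, cam, 48, 48)
    assert np.array_equal(img_a.rgba, img_b.rgba)
    assert np.array_equal(img_a.depth, img_b.depth)


def test_volume_item_renders_foreground(two_class_volume):
    scene = Scene(objects=[VolumeItem(volume=two_class_volume, alpha=1.0)],
                  lighting=LightingParams(L_a=1.0, L_d=0.0, L_s=0.0))
    cam = make_camera([7.5, 7.5, 7.5], 60.0, theta=0.3, phi=0.4)
    img = render_scene(scene, cam, 48, 48)
    assert (img.rgba[..., :3] > 0).any()  # Otsu-gated foreground is visible
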