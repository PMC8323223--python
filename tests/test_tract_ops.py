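"""Fiber sampling, selection, coloring, resampling and tube expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorender.fixtures import FixtureSpec, synth_tractography
from neurorender.io_formats import Tractography
from neurorender.tract_ops import (
    assign_bundle_colors,
    fiber_segment_directions,
    fiber_to_tube_mesh,
    resample_fiber_equidistant,
    sample_fibers,
    select_bundles,
)


def _tract_with_n(n):
    pts = np.tile(np.array([[0, 0, 0], [1, 0, 0]], dtype=np.float32), (n, 1, 1))
    return Tractography(fibers=list(pts))


# ------------------------------------------------------------------- sampling


@settings(derandomize=True, max_examples=200)
@given(n=st.integers(1, 1000), percent=st.integers(1, 100))
def test_sampling_count_law(n, percent):
    """|selection| = max(1, floor(percent/100 * n)) for all n, percent."""
    sel = sample_fibers(_tract_with_n(n), percent, seed=0)
    assert len(sel) == max(1, (percent * n) // 100)
    assert len(set(sel.indices.tolist())) == len(sel)
    assert sel.indices.min() >= 0 and sel.indices.max() < n


def test_sampling_deterministic_and_nested():
    t = _tract_with_n(500)
    a = sample_fibers(t, 20, seed=42)
    b = sample_fibers(t, 20, seed=42)
    assert np.array_equal(a.indices, b.indices)
    sizes = []
    prev = set()
    for p in (5, 10, 25, 50, 100):
        s = set(sample_fibers(t, p, seed=42).indices.tolist())
        assert prev <= s  # seeded permutation prefix ⇒ nested subsets
        sizes.append(len(s))
        prev = s
    assert sizes == sorted(sizes)


def test_sampling_minimum_one():
    assert len(sample_fibers(_tract_with_n(1), 1, seed=0)) == 1


def test_sampling_within_bundles(small_tract):
    sel = sample_fibers(small_tract, 100, seed=0, within=["bundle_000"])
    assert set(sel.indices.tolist()) == small_tract.bundles["bundle_000"]
    sel = sample_fibers(small_tract, 40, seed=0, within=["bundle_000"])
    assert len(sel) == 2
    assert set(sel.indices.tolist()) <= small_tract.bundles["bundle_000"]


def test_sampling_validation(small_tract):
    for p in (0, 101, -5):
        with pytest.raises(ValueError):
            sample_fibers(small_tract, p)
    with pytest.raises(KeyError):
        sample_fibers(small_tract, 50, within=["nope"])


# ------------------------------------------------------------------ selection


def test_select_single_bundle(small_tract):
    sel = select_bundles(small_tract, ["bundle_000"])
    assert set(sel.indices.tolist()) == set(range(5))
    assert sel.percent == 100


def test_select_union(small_tract):
    sel = select_bundles(small_tract, ["bundle_000", "bundle_001"])
    assert set(sel.indices.tolist()) == set(range(10))


def test_select_unknown_or_unlabeled(small_tract):
    with pytest.raises(KeyError):
        select_bundles(small_tract, ["C"])
    with pytest.raises(ValueError):
        select_bundles(Tractography(fibers=small_tract.fibers), ["bundle_000"])


# -------------------------------------------------------------------- palette


def test_palette_deterministic(small_tract):
    p1 = assign_bundle_colors(small_tract, seed=0)
    p2 = assign_bundle_colors(small_tract, seed=0)
    assert p1.colors == p2.colors
    assert assign_bundle_colors(small_tract, seed=1).colors != p1.colors


def test_palette_100_distinct():
    t = synth_tractography(FixtureSpec(seed=0, n_fibers=100, n_bundles=100, points_per_fiber=3))
    pal = assign_bundle_colors(t, seed=0)
    assert len(set(pal.colors.values())) == 100
    assert all(0 <= c <= 1 for rgb in pal.colors.values() for c in rgb)


def test_palette_361_bundles_succeeds():
    t = synth_tractography(FixtureSpec(seed=0, n_fibers=361, n_bundles=361, points_per_fiber=3))
    assert len(assign_bundle_colors(t, seed=0).colors) == 361


def test_palette_requires_bundles(small_tract):
    with pytest.raises(ValueError):
        assign_bundle_colors(Tractography(fibers=small_tract.fibers), seed=0)


# ----------------------------------------------------------------- resampling


def test_resample_straight_line_21_points():
    f = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], dtype=np.float32)
    out = resample_fiber_equidistant(f, 21)
    assert out.shape == (21, 3)
    assert np.allclose(out[:, 0], np.arange(21), atol=1e-5)
    assert np.allclose(out[:, 1:], 0)


def test_resample_right_angle_arc_walk():
    # brute-force arc-length walk: targets 0, 0.5, 1.0, 1.5, 2.0 along the bend
    f = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=np.float32)
    out = resample_fiber_equidistant(f, 5)
    expected = np.array([[0, 0, 0], [0.5, 0, 0], [1, 0, 0], [1, 0.5, 0], [1, 1, 0]])
    assert np.allclose(out, expected, atol=1e-6)


def test_resample_fixed_point():
    f = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=np.float32)
    assert np.allclose(resample_fiber_equidistant(f, 4), f, atol=1e-6)


def _arc_position_on_polyline(poly, p):
    """Arc-length coordinate of a point lying on a polyline (oracle walk)."""
    poly = poly.astype(np.float64)
    seg = np.diff(poly, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    best = (np.inf, 0.0)
    for i, (a, d, L) in enumerate(zip(poly[:-1], seg, lens)):
        if L == 0:
            continue
        t = np.clip(np.dot(p - a, d) / (L * L), 0.0, 1.0)
        dist = np.linalg.norm(a + t * d - p)
        if dist < best[0]:
            best = (dist, cum[i] + t * L)
    return best[1]


def test_resample_endpoints_and_equidistant_arc_spacing(small_tract):
    for fiber in small_tract.fibers:
        out = resample_fiber_equidistant(fiber, 21)
        assert np.allclose(out[0], fiber[0]) and np.allclose(out[-1], fiber[-1])
        s = np.array([_arc_position_on_polyline(fiber, p) for p in out.astype(np.float64)])
        gaps = np.diff(s)
        assert np.allclose(gaps, gaps[0], rtol=1e-5)


def test_resample_preserves_arc_length(small_tract):
    def arclen(p):
        return np.linalg.norm(np.diff(p.astype(np.float64), axis=0), axis=1).sum()

    for fiber in small_tract.fibers:
        # dense output: the inscribed-chord shortfall at corners vanishes with n
        out = resample_fiber_equidistant(fiber, 64 * len(fiber))
        assert arclen(out) == pytest.approx(arclen(fiber), rel=1e-4)


def test_resample_degenerate_rejected():
    f = np.zeros((3, 3), dtype=np.float32)
    with pytest.raises(ValueError):
        resample_fiber_equidistant(f, 5)
    with pytest.raises(ValueError):
        resample_fiber_equidistant(np.array([[0, 0, 0], [1, 0, 0]]), 1)


# ----------------------------------------------------------- pseudo-normals


def test_directions_straight_fiber():
    f = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=np.float32)
    assert np.allclose(fiber_segment_directions(f), [[1, 0, 0]] * 3)


def test_directions_3_4_5():
    f = np.array([[0, 0, 0], [0, 3, 4]], dtype=np.float32)
    assert np.allclose(fiber_segment_directions(f), [[0, 0.6, 0.8]] * 2, atol=1e-7)


def test_directions_right_angle_rule():
    f = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=np.float32)
    assert np.allclose(fiber_segment_directions(f), [[1, 0, 0], [0, 1, 0], [0, 1, 0]])


def test_directions_zero_segment_inherits():
    f = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=np.float32)
    d = fiber_segment_directions(f)
    assert np.allclose(d[1], [1, 0, 0])  # zero segment inherits previous
    assert np.allclose(np.linalg.norm(d, axis=1), 1.0)


def test_directions_all_coincident_rejected():
    with pytest.raises(ValueError):
        fiber_segment_directions(np.zeros((4, 3), dtype=np.float32))


# ----------------------------------------------------------------- tube mesh


def test_tube_counts():
    f = np.array([[0, 0, 0], [0, 0, 5]], dtype=np.float32)
    tube = fiber_to_tube_mesh(f, radius=1.0, n_sides=6)
    assert tube.n_vertices == 2 * 6
    assert tube.n_triangles == 1 * 6 * 2


def test_tube_straight_z_radius():
    f = np.array([[0, 0, 0], [0, 0, 5], [0, 0, 10]], dtype=np.float32)
    tube = fiber_to_tube_mesh(f, radius=1.0, n_sides=8)
    r = np.linalg.norm(tube.vertices[:, :2], axis=1)
    assert np.allclose(r, 1.0, atol=1e-6)
    assert np.allclose(np.linalg.norm(tube.normals, axis=1), 1.0, atol=1e-5)


def test_tube_interior_edges_shared_by_two_triangles():
    f = np.array([[0, 0, 0], [5, 0, 0], [5, 5, 0], [5, 5, 5]], dtype=np.float32)
    tube = fiber_to_tube_mesh(f, radius=0.5, n_sides=5)
    from collections import Counter

    count = Counter()
    for a, b, c in tube.triangles:
        for e in ((a, b), (b, c), (a, c)):
            count[tuple(sorted(e))] += 1
    # open tube: end-ring edges belong to 1 triangle, all others to exactly 2
    assert set(count.values()) <= {1, 2}
    assert sum(1 for v in count.values() if v == 2) > 0
    boundary = [e for e, v in count.items() if v == 1]
    assert len(boundary) == 2 * 5  # 5 boundary edges on each open end


def test_tube_validation():
    f = np.array([[0, 0, 0], [1, 0, 0]], dtype=np.float32)
    with pytest.raises(ValueError):
        fiber_to_tube_mesh(f, radius=1.0, n_sides=2)
    with pytest.raises(ValueError):
        fiber_to_tube_mesh(f, radius=0.0, n_sides=6)
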