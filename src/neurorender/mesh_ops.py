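"""Mesh preparation: vertex normals, painter's-algorithm depth sort, wireframe.

Faces are oriented by counter-clockwise winding; normals follow the
right-hand rule.  Transparency is handled downstream by drawing triangles
back to front, so the sort here is the load-bearing step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Mesh

__all__ = [
    "TriangleOrder",
    "face_normals",
    "compute_vertex_normals",
    "depth_sort_triangles",
    "extract_wireframe_edges",
]


@dataclass
class TriangleOrder:
    """Back-to-front triangle permutation for a given eye point."""

    order: np.ndarray
    eye: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.eye = np.asarray(self.eye, dtype=np.float64).reshape(3)


def face_normals(m: Mesh, normalize: bool = True) -> np.ndarray:
    """Per-face normals (CCW winding, right-hand rule).

    With ``normalize=False`` returns the raw cross products, whose norms are
    twice the triangle areas — handy for area weighting.
    """
    v = m.vertices.astype(np.float64)
    t = m.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    if not normalize:
        return cross
    norms = np.linalg.norm(cross, axis=1)
    out = np.zeros_like(cross)
    ok = norms > 0
    out[ok] = cross[ok] / norms[ok, None]
    return out


def compute_vertex_normals(m: Mesh) -> Mesh:
    """Return *m* with per-vertex normals, computing them when absent.

    Normals are the normalized area-weighted average of incident face
    normals (accumulating raw cross products achieves the area weighting);
    degenerate faces contribute nothing and isolated vertices get (0,0,1).
    A mesh that already carries normals is returned unchanged.
    """
    if m.normals is not None:
        return m
    if m.n_triangles < 1:
        raise ValueError("mesh has no triangles")
    acc = np.zeros((m.n_vertices, 3))
    cross = face_normals(m, normalize=False)
    for c in range(3):
        np.add.at(acc, m.triangles[:, c], cross)
    norms = np.linalg.norm(acc, axis=1)
    ok = norms > 1e-20
    normals = np.zeros_like(acc)
    normals[ok] = acc[ok] / norms[ok, None]
    normals[~ok] = (0.0, 0.0, 1.0)
    return Mesh(vertices=m.vertices, triangles=m.triangles, normals=normals.astype(np.float32))


def depth_sort_triangles(m: Mesh, eye: np.ndarray) -> TriangleOrder:
    """Sort triangles back to front by centroid–eye distance.

    Stable: equal distances keep original index order.  Centroid distance is
    the standard painter's-algorithm key; intersecting triangles can still
    sort "wrongly" — an accepted limitation.
    """
    if m.n_triangles == 0:
        raise ValueError("mesh has no triangles")
    eye = np.asarray(eye, dtype=np.float64).reshape(3)
    centroids = m.vertices.astype(np.float64)[m.triangles].mean(axis=1)
    d = np.linalg.norm(centroids - eye, axis=1)
    order = np.argsort(-d, kind="stable")
    return TriangleOrder(order=order, eye=eye)


def extract_wireframe_edges(m: Mesh) -> np.ndarray:
    """Unique undirected edges of all triangles, lower vertex index first."""
    if m.n_triangles == 0:
        raise ValueError("mesh has no triangles")
    t = m.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)
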