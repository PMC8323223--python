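"""Readers and writers for the supported on-disk formats.

Four families of formats are handled and mapped onto three in-memory
domain types:

* tractography — TrackVis ``.trk`` (binary, 1000-byte header) and
  BrainVISA ``.bundles``/``.bundlesdata`` (text header + binary payload)
  → :class:`Tractography`;
* MRI volumes — NIfTI-1 ``.nii``/``.nii.gz`` → :class:`Volume`
  (via nibabel);
* surface meshes — GIfTI ``.gii`` (via nibabel) and BrainVISA
  ``.mesh``/``.mesh.minf`` (binary) → :class:`Mesh`.

All coordinates are world-space millimetres, RAS orientation assumed,
stored at 32-bit float precision.  Voxel indices are 0-based.  Every
writer round-trips through the matching reader bit-exactly at float32.
"""

from __future__ import annotations

import ast
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import nibabel as nib

__all__ = [
    "Tractography",
    "Volume",
    "Mesh",
    "FormatError",
    "read_tractography",
    "write_tractography",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Tractography:
    """A set of fibers (3D polylines) with optional named bundles.

    Parameters
    ----------
    fibers:
        Sequence of ``(n_i, 3)`` float32 arrays, ``n_i >= 2``, in mm.
    bundles:
        Ordered mapping bundle-name → set of fiber indices.  Bundle sets
        must be disjoint; when non-empty their union covers all fibers.
    transform:
        Optional 4x4 voxel/world affine carried by the source file
        (kept for provenance; points are already in world space).
    source_format:
        ``"trk"``, ``"bundles"`` or ``None`` for in-memory objects.
    """

    fibers: list[np.ndarray]
    bundles: dict[str, set[int]] = field(default_factory=dict)
    transform: Optional[np.ndarray] = None
    source_format: Optional[str] = None

    def __post_init__(self) -> None:
        self.fibers = [np.ascontiguousarray(f, dtype=np.float32) for f in self.fibers]
        for i, f in enumerate(self.fibers):
            if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 2:
                raise ValueError(f"fiber {i}: need an (n>=2, 3) point array, got {f.shape}")
            if not np.isfinite(f).all():
                raise ValueError(f"fiber {i}: non-finite coordinates")
        n = len(self.fibers)
        seen: set[int] = set()
        for name, idx in self.bundles.items():
            idx = set(int(i) for i in idx)
            self.bundles[name] = idx
            if idx and (min(idx) < 0 or max(idx) >= n):
                raise ValueError(f"bundle {name!r}: fiber index out of range")
            if idx & seen:
                raise ValueError(f"bundle {name!r}: overlaps another bundle")
            seen |= idx
        if self.bundles and seen != set(range(n)):
            raise ValueError("bundles present but their union does not cover all fibers")
        if self.transform is not None:
            self.transform = np.asarray(self.transform, dtype=np.float64).reshape(4, 4)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)


@dataclass
class Volume:
    """A 3D scalar grid with voxel dimensions and a voxel→world affine."""

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("volume dims must be >= 1 per axis")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if not (self.voxel_size > 0).all():
            raise ValueError("voxel_size must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_bounds(self) -> np.ndarray:
        """(2, 3) min/max world coordinates of the 8 voxel-grid corners."""
        dims = np.array(self.data.shape) - 1
        corners = np.array(
            [[i * dims[0], j * dims[1], k * dims[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        world = corners @ self.affine[:3, :3].T + self.affine[:3, 3]
        return np.stack([world.min(axis=0), world.max(axis=0)])


@dataclass
class Mesh:
    """Triangle mesh: vertices (mm), triangle index triples, optional unit normals."""

    vertices: np.ndarray
    triangles: np.ndarray
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float32).reshape(-1, 3)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int32).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float32).reshape(-1, 3)
            if len(self.normals) != len(self.vertices):
                raise ValueError("normal count must equal vertex count")
            norms = np.linalg.norm(self.normals.astype(np.float64), axis=1)
            if not np.allclose(norms, 1.0, atol=1e-5):
                raise ValueError("normals must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


# ---------------------------------------------------------------------------
# TrackVis .trk
# ---------------------------------------------------------------------------

_TRK_HDR_SIZE = 1000
# TrackVis v2 header: name, struct format, offset
_TRK_FIELDS = (
    ("id_string", "6s", 0),
    ("dim", "3h", 6),
    ("voxel_size", "3f", 12),
    ("origin", "3f", 24),
    ("n_scalars", "h", 36),
    ("n_properties", "h", 238),
    ("vox_to_ras", "16f", 440),
    ("voxel_order", "4s", 948),
    ("n_count", "i", 988),
    ("version", "i", 992),
    ("hdr_size", "i", 996),
)


def _trk_unpack(buf: bytes, name: str):
    for n, fmt, off in _TRK_FIELDS:
        if n == name:
            vals = struct.unpack_from("<" + fmt, buf, off)
            return vals if len(vals) > 1 else vals[0]
    raise KeyError(name)


def _read_trk(path: Path) -> Tractography:
    raw = path.read_bytes()
    if len(raw) < _TRK_HDR_SIZE:
        raise FormatError(f"{path}: file shorter than the {_TRK_HDR_SIZE}-byte header")
    hdr = raw[:_TRK_HDR_SIZE]
    if not hdr[:5].startswith(b"TRACK"):
        raise FormatError(f"{path}: not a TrackVis file (bad magic)")
    n_scalars = int(_trk_unpack(hdr, "n_scalars"))
    n_properties = int(_trk_unpack(hdr, "n_properties"))
    n_count = int(_trk_unpack(hdr, "n_count"))
    vox_to_ras = np.array(_trk_unpack(hdr, "vox_to_ras"), dtype=np.float64).reshape(4, 4)

    payload = memoryview(raw)[_TRK_HDR_SIZE:]
    fibers: list[np.ndarray] = []
    off = 0
    while off < len(payload):
        if n_count and len(fibers) >= n_count:
            break
        if off + 4 > len(payload):
            raise FormatError(f"{path}: truncated track header at byte {off}")
        (npts,) = struct.unpack_from("<i", payload, off)
        off += 4
        if npts < 2:
            raise FormatError(f"{path}: track with {npts} points")
        nbytes = npts * (3 + n_scalars) * 4
        if off + nbytes + n_properties * 4 > len(payload):
            raise FormatError(f"{path}: truncated track payload (declared {npts} points)")
        pts = np.frombuffer(payload, dtype="<f4", count=npts * (3 + n_scalars), offset=off)
        pts = pts.reshape(npts, 3 + n_scalars)[:, :3].copy()
        off += nbytes + n_properties * 4
        fibers.append(pts)
    if n_count and len(fibers) != n_count:
        raise FormatError(f"{path}: header declares {n_count} tracks, file holds {len(fibers)}")

    transform: Optional[np.ndarray] = None
    apply = not np.allclose(vox_to_ras, 0.0) and np.isfinite(vox_to_ras).all()
    if apply:
        transform = vox_to_ras
        if not np.allclose(vox_to_ras, np.eye(4)):
            R, t = vox_to_ras[:3, :3], vox_to_ras[:3, 3]
            fibers = [(f @ R.T.astype(np.float32) + t.astype(np.float32)) for f in fibers]
    return Tractography(fibers=fibers, transform=transform, source_format="trk")


def _write_trk(t: Tractography, path: Path) -> None:
    hdr = bytearray(_TRK_HDR_SIZE)
    struct.pack_into("<6s", hdr, 0, b"TRACK")
    struct.pack_into("<3h", hdr, 6, 1, 1, 1)
    struct.pack_into("<3f", hdr, 12, 1.0, 1.0, 1.0)
    struct.pack_into("<h", hdr, 36, 0)  # n_scalars
    struct.pack_into("<h", hdr, 238, 0)  # n_properties
    # points are kept in world mm: emit identity so a re-read is a no-op
    struct.pack_into("<16f", hdr, 440, *np.eye(4, dtype=np.float32).ravel())
    struct.pack_into("<4s", hdr, 948, b"RAS\x00")
    struct.pack_into("<i", hdr, 988, t.n_fibers)
    struct.pack_into("<i", hdr, 992, 2)
    struct.pack_into("<i", hdr, 996, _TRK_HDR_SIZE)
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for f in t.fibers:
            fh.write(struct.pack("<i", len(f)))
            fh.write(np.ascontiguousarray(f, dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# BrainVISA .bundles / .bundlesdata
# ---------------------------------------------------------------------------


def _parse_minf(text: str) -> dict:
    """Parse a BrainVISA minf-style ``attributes = {...}`` text header."""
    idx = text.find("{")
    if idx < 0:
        raise FormatError("header lacks an attribute dictionary")
    try:
        return ast.literal_eval(text[idx:].strip().rstrip(";"))
    except (SyntaxError, ValueError) as exc:
        raise FormatError(f"malformed header dictionary: {exc}") from exc


def _format_minf(attrs: dict) -> str:
    items = ",\n".join(f"    {k!r} : {v!r}" for k, v in attrs.items())
    return "attributes = {\n" + items + "\n}\n"


def _read_bundles(path: Path) -> Tractography:
    attrs = _parse_minf(path.read_text())
    if "curves_count" not in attrs:
        raise FormatError(f"{path}: .bundles header lacking curve count")
    n_fibers = int(attrs["curves_count"])
    byte_order = attrs.get("byte_order", "DCBA")
    endian = "<" if byte_order == "DCBA" else ">"
    data_path = path.with_name(attrs.get("data_file_name", "*.bundlesdata").replace("*", path.stem))
    if not data_path.exists():
        raise FormatError(f"{path}: companion data file {data_path.name} missing")

    raw = data_path.read_bytes()
    fibers: list[np.ndarray] = []
    off = 0
    for i in range(n_fibers):
        if off + 4 > len(raw):
            raise FormatError(f"{data_path}: truncated at fiber {i} of {n_fibers}")
        (npts,) = struct.unpack_from(endian + "i", raw, off)
        off += 4
        nbytes = npts * 12
        if npts < 2 or off + nbytes > len(raw):
            raise FormatError(f"{data_path}: truncated fiber {i} (declared {npts} points)")
        pts = np.frombuffer(raw, dtype=endian + "f4", count=npts * 3, offset=off)
        fibers.append(pts.reshape(npts, 3).astype(np.float32))
        off += nbytes

    bundles: dict[str, set[int]] = {}
    flat = list(attrs.get("bundles", []))
    if flat:
        names = [str(x) for x in flat[0::2]]
        starts = [int(x) for x in flat[1::2]]
        stops = starts[1:] + [n_fibers]
        for name, a, b in zip(names, starts, stops):
            bundles[name] = set(range(a, b))
    return Tractography(fibers=fibers, bundles=bundles, source_format="bundles")


def _write_bundles(t: Tractography, path: Path) -> None:
    # contiguous renumbering so bundles map to [start, next-start) ranges
    if t.bundles:
        order: list[int] = []
        flat: list = []
        for name, idx in t.bundles.items():
            flat += [name, len(order)]
            order += sorted(idx)
    else:
        order = list(range(t.n_fibers))
        flat = ["all", 0]
    data_name = path.stem + ".bundlesdata"
    attrs = {
        "binary": 1,
        "bundles": flat,
        "byte_order": "DCBA",
        "curves_count": t.n_fibers,
        "data_file_name": "*.bundlesdata",
        "format": "bundles_1.0",
        "space_dimension": 3,
    }
    path.write_text(_format_minf(attrs))
    with open(path.with_name(data_name), "wb") as fh:
        for i in order:
            f = t.fibers[i]
            fh.write(struct.pack("<i", len(f)))
            fh.write(np.ascontiguousarray(f, dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# tractography dispatch
# ---------------------------------------------------------------------------


def read_tractography(path) -> Tractography:
    """Read a ``.trk`` or ``.bundles`` tractography file.

    ``.trk``: the header's voxel→RAS matrix is applied to the points when it
    is a valid non-zero matrix, and kept on ``transform``.  ``.bundles``:
    bundle names and fiber index ranges are populated from the header; the
    companion ``.bundlesdata`` file must sit next to the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".trk":
        return _read_trk(path)
    if ext == ".bundles":
        return _read_bundles(path)
    raise FormatError(f"unknown tractography extension {ext!r}")


def write_tractography(t: Tractography, path) -> None:
    """Write *t* in the dialect selected by the extension of *path*.

    Points are written in world mm at float32.  An unlabeled tractography
    written to ``.bundles`` becomes a single bundle named ``"all"`` (the
    format requires at least one label).
    """
    path = Path(path)
    for i, f in enumerate(t.fibers):
        if len(f) < 2:
            raise ValueError(f"fiber {i} has fewer than 2 points")
    ext = path.suffix.lower()
    if ext == ".trk":
        _write_trk(t, path)
    elif ext == ".bundles":
        _write_bundles(t, path)
    else:
        raise FormatError(f"unknown tractography extension {ext!r}")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume (``.nii`` or ``.nii.gz``).

    Header slope/intercept scaling is applied when declared; data are
    promoted to float32.  4D (or higher) images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types on bad magic
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    shape = img.shape
    if len(shape) != 3:
        raise FormatError(f"{path}: unsupported dimensionality {len(shape)} (only 3D volumes)")
    data = np.asanyarray(img.dataobj).astype(np.float32)  # dataobj applies scl slope/inter
    voxel_size = np.array(img.header.get_zooms()[:3], dtype=np.float64)
    return Volume(data=data, voxel_size=voxel_size, affine=np.asarray(img.affine, dtype=np.float64))


def write_volume(v: Volume, path) -> None:
    """Write *v* as NIfTI-1; gzip-compressed iff the path ends in ``.nii.gz``."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(tuple(float(z) for z in v.voxel_size))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# GIfTI meshes
# ---------------------------------------------------------------------------

_GII_POINTSET = 1008  # NIFTI_INTENT_POINTSET
_GII_TRIANGLE = 1009  # NIFTI_INTENT_TRIANGLE
_GII_VECTOR = 1007  # NIFTI_INTENT_VECTOR


def _read_gii(path: Path) -> Mesh:
    img = nib.load(str(path))
    if not isinstance(img, nib.gifti.GiftiImage):
        raise FormatError(f"{path}: not a GIfTI image")
    verts = tris = norms = None
    for da in img.darrays:
        intent = int(da.intent)
        if intent == _GII_POINTSET and verts is None:
            verts = da.data
        elif intent == _GII_TRIANGLE and tris is None:
            tris = da.data
        elif intent == _GII_VECTOR and norms is None:
            norms = da.data
    if verts is None or tris is None:
        raise FormatError(f"{path}: GIfTI lacking a point-set or triangle array")
    return Mesh(vertices=verts, triangles=tris, normals=norms)


def _write_gii(m: Mesh, path: Path) -> None:
    darrays = [
        nib.gifti.GiftiDataArray(
            np.ascontiguousarray(m.vertices, dtype=np.float32),
            intent=_GII_POINTSET, datatype="NIFTI_TYPE_FLOAT32",
        ),
        nib.gifti.GiftiDataArray(
            np.ascontiguousarray(m.triangles, dtype=np.int32),
            intent=_GII_TRIANGLE, datatype="NIFTI_TYPE_INT32",
        ),
    ]
    if m.normals is not None:
        darrays.append(
            nib.gifti.GiftiDataArray(
                np.ascontiguousarray(m.normals, dtype=np.float32),
                intent=_GII_VECTOR, datatype="NIFTI_TYPE_FLOAT32",
            )
        )
    nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))


# ---------------------------------------------------------------------------
# BrainVISA .mesh / .mesh.minf
# ---------------------------------------------------------------------------


def _read_brainvisa_mesh(path: Path) -> Mesh:
    minf = path.with_name(path.name + ".minf")
    if not minf.exists():
        raise FormatError(f"{path}: companion file {minf.name} missing")
    raw = path.read_bytes()
    if raw[:5] != b"binar":
        raise FormatError(f"{path}: only binary .mesh files are supported")
    off = 5
    marker = raw[off : off + 4]
    if marker == b"DCBA":
        endian = "<"
    elif marker == b"ABCD":
        endian = ">"
    else:
        raise FormatError(f"{path}: bad byte-order marker {marker!r}")
    off += 4

    def u32() -> int:
        nonlocal off
        (v,) = struct.unpack_from(endian + "I", raw, off)
        off += 4
        return v

    tex_len = u32()
    off += tex_len  # texture type string, e.g. "VOID"
    poly_dim = u32()
    if poly_dim != 3:
        raise FormatError(f"{path}: polygon dimension {poly_dim}, only triangles supported")
    n_time = u32()
    if n_time < 1:
        raise FormatError(f"{path}: no time steps")
    u32()  # instant of first (only) time step read
    n_vertices = u32()
    verts = np.frombuffer(raw, dtype=endian + "f4", count=n_vertices * 3, offset=off)
    off += n_vertices * 12
    n_normals = u32()
    normals = None
    if n_normals:
        if n_normals != n_vertices:
            raise FormatError(f"{path}: {n_normals} normals for {n_vertices} vertices")
        normals = np.frombuffer(raw, dtype=endian + "f4", count=n_normals * 3, offset=off)
        normals = normals.reshape(-1, 3).astype(np.float32)
        off += n_normals * 12
    n_tex = u32()
    off += n_tex * 4
    n_poly = u32()
    tris = np.frombuffer(raw, dtype=endian + "u4", count=n_poly * 3, offset=off)
    return Mesh(
        vertices=verts.reshape(-1, 3).astype(np.float32),
        triangles=tris.reshape(-1, 3).astype(np.int32),
        normals=normals,
    )


def _write_brainvisa_mesh(m: Mesh, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(b"binar")
        fh.write(b"DCBA")  # little-endian marker
        fh.write(struct.pack("<I", 4) + b"VOID")
        fh.write(struct.pack("<I", 3))  # polygon dimension
        fh.write(struct.pack("<I", 1))  # one time step
        fh.write(struct.pack("<I", 0))  # instant
        fh.write(struct.pack("<I", m.n_vertices))
        fh.write(np.ascontiguousarray(m.vertices, dtype="<f4").tobytes())
        if m.normals is not None:
            fh.write(struct.pack("<I", m.n_vertices))
            fh.write(np.ascontiguousarray(m.normals, dtype="<f4").tobytes())
        else:
            fh.write(struct.pack("<I", 0))
        fh.write(struct.pack("<I", 0))  # no texture
        fh.write(struct.pack("<I", m.n_triangles))
        fh.write(np.ascontiguousarray(m.triangles, dtype="<u4").tobytes())
    minf = path.with_name(path.name + ".minf")
    minf.write_text(
        _format_minf({"vertex_number": m.n_vertices, "polygon_number": m.n_triangles})
    )


def read_mesh(path) -> Mesh:
    """Read a ``.gii`` (GIfTI) or BrainVISA ``.mesh`` surface.

    Normals are loaded when present in the file and left absent otherwise;
    computing missing normals is the job of
    :func:`neurorender.mesh_ops.compute_vertex_normals`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".gii":
        return _read_gii(path)
    if ext == ".mesh":
        return _read_brainvisa_mesh(path)
    raise FormatError(f"unknown mesh extension {ext!r}")


def write_mesh(m: Mesh, path) -> None:
    """Write *m* as GIfTI or BrainVISA mesh according to the extension."""
    path = Path(path)
    if m.n_triangles == 0:
        raise ValueError("refusing to write a mesh with no triangles")
    ext = path.suffix.lower()
    if ext == ".gii":
        _write_gii(m, path)
    elif ext == ".mesh":
        _write_brainvisa_mesh(m, path)
    else:
        raise FormatError(f"unknown mesh extension {ext!r}")
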