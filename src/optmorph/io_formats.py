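"""Volumes, meshes and landmark configurations: containers and file I/O.

Conventions used throughout the package:

* right-handed axes, all physical coordinates in micrometres (µm);
* a :class:`Volume` grid is indexed ``grid[i, j, k]`` with voxel centre at
  ``origin + (i*sx, j*sy, k*sz)`` (0-based indices);
* TIFF stacks carry no trustworthy spacing metadata, so ``spacing_override``
  is mandatory for TIFF input; NRRD and MHD spacing is read from the header.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import trimesh as _trimesh
from scipy import ndimage

DARK_STAIN = "dark-stain"
BRIGHT_STAIN = "bright-stain"

#: columns of the canonical CSV landmark dialect, in order
LANDMARK_CSV_COLUMNS = [
    "specimen_id", "structure", "side", "group",
    "landmark_id", "role", "curve_id", "ordinal", "x", "y", "z",
]

ROLE_ANATOMICAL = "anatomical"
ROLE_CURVE = "curve"
ROLE_SURFACE = "surface"
_VALID_ROLES = (ROLE_ANATOMICAL, ROLE_CURVE, ROLE_SURFACE)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Grey values; any real dtype.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in µm, strictly positive.
    origin : tuple of float
        Physical position (µm) of the centre of voxel ``(0, 0, 0)``.
    polarity : str
        ``"dark-stain"`` if signal is darker than background (NBT/BCIP
        transmission imaging) or ``"bright-stain"`` otherwise.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    polarity: str = DARK_STAIN

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("volume grid must be 3D with each axis >= 1")
        if not np.all(np.isfinite(np.asarray(self.grid, dtype=float))):
            raise ValueError("volume grid contains non-finite grey values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")
        self.origin = tuple(float(v) for v in self.origin)
        if self.polarity not in (DARK_STAIN, BRIGHT_STAIN):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates (µm) of voxel centres along one axis."""
        n = self.grid.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class TriMesh:
    """Triangle surface mesh in physical µm coordinates.

    Degenerate (zero-area) faces are dropped on construction.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")
        if self.faces.size:
            v = self.vertices
            a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            area2 = np.linalg.norm(np.cross(a, b), axis=1)
            self.faces = self.faces[area2 > 0.0]

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        return cls(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        """Enclosed volume (µm³) by the divergence theorem; sign-corrected."""
        return float(abs(self.to_trimesh().volume))

    def surface_area(self) -> float:
        return float(self.to_trimesh().area)


@dataclass
class LandmarkSet:
    """One specimen's landmark configuration for one structure.

    ``roles[i]`` is one of ``anatomical | curve | surface``; curve points
    additionally carry ``curve_ids[i]`` and a contiguous ``ordinals[i]``
    within their curve.
    """

    specimen_id: str
    structure: str
    points: np.ndarray
    side: str = "none"
    group: str = ""
    roles: list[str] = field(default_factory=list)
    curve_ids: list[str | None] = field(default_factory=list)
    ordinals: list[int | None] = field(default_factory=list)
    landmark_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        k = len(self.points)
        if k < 1:
            raise ValueError("a landmark set needs k >= 1 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if not self.roles:
            self.roles = [ROLE_ANATOMICAL] * k
        if not self.curve_ids:
            self.curve_ids = [None] * k
        if not self.ordinals:
            self.ordinals = [None] * k
        if not self.landmark_ids:
            self.landmark_ids = [f"L{i}" for i in range(k)]
        if not (len(self.roles) == len(self.curve_ids)
                == len(self.ordinals) == len(self.landmark_ids) == k):
            raise ValueError("per-point metadata length mismatch")
        for role in self.roles:
            if role not in _VALID_ROLES:
                raise ValueError(f"unknown landmark role {role!r}")
        # curve metadata consistency: each curve's ordinals contiguous from 0
        by_curve: dict[str, list[int]] = {}
        for role, cid, o in zip(self.roles, self.curve_ids, self.ordinals):
            if role == ROLE_CURVE:
                if cid is None or o is None:
                    raise ValueError("curve points need curve_id and ordinal")
                by_curve.setdefault(str(cid), []).append(int(o))
        for cid, ords in by_curve.items():
            if sorted(ords) != list(range(len(ords))):
                raise ValueError(
                    f"curve {cid!r} ordinals not contiguous from 0: {sorted(ords)}"
                )

    @property
    def k(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return replace(self, points=np.asarray(points, dtype=float))

    def same_scheme(self, other: "LandmarkSet") -> bool:
        return (
            self.k == other.k
            and self.roles == other.roles
            and list(map(str, self.landmark_ids)) == list(map(str, other.landmark_ids))
        )


# ---------------------------------------------------------------------------
# volumes on disk
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8, "unsigned char": np.uint8,
    "int8": np.int8, "uint16": np.uint16, "int16": np.int16, "short": np.int16,
    "uint32": np.uint32, "int32": np.int32, "int": np.int32,
    "uint64": np.uint64, "int64": np.int64,
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in {
    "uint8": np.uint8, "int8": np.int8, "uint16": np.uint16, "int16": np.int16,
    "uint32": np.uint32, "int32": np.int32, "uint64": np.uint64,
    "int64": np.int64, "float": np.float32, "double": np.float64,
}.items()}

_MHD_TYPES = {
    "MET_UCHAR": np.uint8, "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16, "MET_SHORT": np.int16,
    "MET_UINT": np.uint32, "MET_INT": np.int32,
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(v): k for k, v in _MHD_TYPES.items()}


def _read_nrrd(path: str) -> tuple[np.ndarray, tuple, tuple]:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("utf-8").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, val = text.split(":", 1)
            fields[key.strip().lower()] = val.lstrip("=").strip()
        raw = fh.read()
    if fields.get("encoding", "raw") != "raw":
        raise ValueError("only raw NRRD encoding is supported")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]])
    if fields.get("endian", "little") == "big" and dtype.itemsize > 1:
        dtype = dtype.newbyteorder(">")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 3:
        raise ValueError("only 3D NRRD volumes are supported")
    n = int(np.prod(sizes))
    grid = np.frombuffer(raw, dtype=dtype, count=n).reshape(sizes, order="F")
    spacing = None
    if "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    elif "space directions" in fields:
        vecs = re.findall(r"\(([^)]*)\)", fields["space directions"])
        mat = np.array([[float(x) for x in v.split(",")] for v in vecs])
        spacing = tuple(np.linalg.norm(mat, axis=1))
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = tuple(
            float(x) for x in fields["space origin"].strip("()").split(",")
        )
    return np.asarray(grid), spacing, origin


def _write_nrrd(volume: Volume, path: str) -> None:
    grid = np.ascontiguousarray(volume.grid)
    name = _NRRD_NAMES.get(grid.dtype)
    if name is None:
        grid = grid.astype(np.float64)
        name = "double"
    sx, sy, sz = volume.spacing
    ox, oy, oz = volume.origin
    header = (
        "NRRD0004\n"
        f"type: {name}\n"
        "dimension: 3\n"
        "space: right-anterior-superior\n"
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        f"space origin: ({ox},{oy},{oz})\n"
        "endian: little\n"
        "encoding: raw\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("utf-8"))
        fh.write(np.asfortranarray(grid).tobytes(order="F"))


def _read_mhd(path: str) -> tuple[np.ndarray, tuple, tuple]:
    fields: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
    if int(fields.get("NDims", "0")) != 3:
        raise ValueError("only 3D MHD volumes are supported")
    sizes = tuple(int(s) for s in fields["DimSize"].split())
    dtype = np.dtype(_MHD_TYPES[fields["ElementType"]])
    if fields.get("ElementByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    datafile = fields["ElementDataFile"]
    raw_path = os.path.join(os.path.dirname(path) or ".", datafile)
    grid = np.fromfile(raw_path, dtype=dtype, count=int(np.prod(sizes)))
    grid = grid.reshape(sizes, order="F")
    spacing = tuple(
        float(s) for s in fields.get("ElementSpacing", "1 1 1").split()
    )
    origin = tuple(float(s) for s in fields.get("Offset", "0 0 0").split())
    return grid, spacing, origin


def _write_mhd(volume: Volume, path: str) -> None:
    grid = np.ascontiguousarray(volume.grid)
    name = _MHD_NAMES.get(grid.dtype)
    if name is None:
        grid = grid.astype(np.float64)
        name = "MET_DOUBLE"
    raw_name = os.path.splitext(os.path.basename(path))[0] + ".raw"
    sx, sy, sz = volume.spacing
    ox, oy, oz = volume.origin
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        f"ElementSpacing = {sx} {sy} {sz}\n"
        f"Offset = {ox} {oy} {oz}\n"
        f"ElementType = {name}\n"
        f"ElementDataFile = {raw_name}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
    with open(os.path.join(os.path.dirname(path) or ".", raw_name), "wb") as fh:
        fh.write(np.asfortranarray(grid).tobytes(order="F"))


def read_volume(
    path: str,
    spacing_override: tuple[float, float, float] | None = None,
    polarity: str = DARK_STAIN,
) -> Volume:
    """Read a 3D volume from NRRD, MHD+RAW or a multi-page TIFF stack.

    Grey values of integer inputs are preserved bit-exactly.  TIFF carries no
    reliable spacing, so ``spacing_override`` is required for TIFF input.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".nrrd":
        grid, spacing, origin = _read_nrrd(path)
    elif ext == ".mhd":
        grid, spacing, origin = _read_mhd(path)
    elif ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValueError(f"{path}: inconsistent slice dimensions {shapes}")
            arr = tf.asarray()
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D TIFF stack")
        grid = np.ascontiguousarray(arr.transpose(2, 1, 0))  # (z,y,x) -> (x,y,z)
        spacing, origin = None, (0.0, 0.0, 0.0)
    else:
        raise ValueError(f"unsupported volume format: {ext!r}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path}: no spacing in header; pass spacing_override (required for TIFF)"
        )
    return Volume(grid=grid, spacing=spacing, origin=origin, polarity=polarity)


def write_volume(volume: Volume, path: str) -> None:
    """Write a volume as NRRD, MHD+RAW or multi-page TIFF (by extension)."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".nrrd":
        _write_nrrd(volume, path)
    elif ext == ".mhd":
        _write_mhd(volume, path)
    elif ext in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.ascontiguousarray(volume.grid.transpose(2, 1, 0)),
            photometric="minisblack",
        )
    else:
        raise ValueError(f"unsupported volume format: {ext!r}")


def filter_volume(volume: Volume, method: str = "median", radius: int = 1) -> Volume:
    """Denoise a volume; ``median`` replaces each voxel by the median of its
    ``(2*radius+1)**3`` neighborhood with clamp-to-edge boundary handling."""
    if method != "median":
        raise ValueError(f"unknown filter method {method!r}")
    radius = int(radius)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    filtered = ndimage.median_filter(
        volume.grid, size=2 * radius + 1, mode="nearest"
    )
    return replace(volume, grid=filtered)


# ---------------------------------------------------------------------------
# meshes on disk
# ---------------------------------------------------------------------------

def read_mesh(path: str) -> TriMesh:
    """Read a PLY/OBJ/STL triangle mesh (coordinates taken as µm)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".obj", ".stl"):
        raise ValueError(f"unsupported mesh format: {ext!r}")
    try:
        tm = _trimesh.load(path, file_type=ext[1:], process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise ValueError(f"malformed mesh file {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"malformed mesh file {path}: no triangles")
    if ext == ".stl":
        # STL is a triangle soup; merge identical vertices to recover topology
        tm.merge_vertices()
    return TriMesh.from_trimesh(tm)


def write_mesh(mesh: TriMesh, path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".obj", ".stl"):
        raise ValueError(f"unsupported mesh format: {ext!r}")
    mesh.to_trimesh().export(path)


# ---------------------------------------------------------------------------
# landmarks on disk
# ---------------------------------------------------------------------------

def _landmarks_to_frame(sets: list[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for ls in sets:
        for i in range(ls.k):
            rows.append({
                "specimen_id": ls.specimen_id,
                "structure": ls.structure,
                "side": ls.side,
                "group": ls.group,
                "landmark_id": ls.landmark_ids[i],
                "role": ls.roles[i],
                "curve_id": "" if ls.curve_ids[i] is None else str(ls.curve_ids[i]),
                "ordinal": "" if ls.ordinals[i] is None else int(ls.ordinals[i]),
                "x": ls.points[i, 0],
                "y": ls.points[i, 1],
                "z": ls.points[i, 2],
            })
    return pd.DataFrame(rows, columns=LANDMARK_CSV_COLUMNS)


def _frame_to_landmarks(df: pd.DataFrame) -> list[LandmarkSet]:
    missing = [c for c in LANDMARK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric coordinates in column {col!r}")
        df = df.assign(**{col: vals})
    dup = df.duplicated(subset=["specimen_id", "structure", "landmark_id"])
    if dup.any():
        bad = df.loc[dup, ["specimen_id", "structure", "landmark_id"]].iloc[0]
        raise ValueError(f"duplicate landmark_id {tuple(bad)}")
    out: list[LandmarkSet] = []
    for (sid, struct), sub in df.groupby(
        ["specimen_id", "structure"], sort=False
    ):
        curve_ids = [
            None if (pd.isna(c) or str(c) == "") else str(c)
            for c in sub["curve_id"]
        ]
        ordinals = [
            None if (pd.isna(o) or str(o) == "") else int(float(o))
            for o in sub["ordinal"]
        ]
        out.append(LandmarkSet(
            specimen_id=str(sid),
            structure=str(struct),
            side=str(sub["side"].iloc[0]),
            group=str(sub["group"].iloc[0]),
            points=sub[["x", "y", "z"]].to_numpy(dtype=float),
            roles=[str(r) for r in sub["role"]],
            curve_ids=curve_ids,
            ordinals=ordinals,
            landmark_ids=[str(l) for l in sub["landmark_id"]],
        ))
    return out


def _read_tps(path: str) -> list[LandmarkSet]:
    sets: list[LandmarkSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i, counter = 0, 0
    while i < len(lines):
        m = re.match(r"^LM(3?)\s*=\s*(\d+)$", lines[i], flags=re.IGNORECASE)
        if not m:
            raise ValueError(f"expected LM/LM3 record at line {i + 1!r}: {lines[i]!r}")
        is3d, k = bool(m.group(1)), int(m.group(2))
        coords = []
        i += 1
        for _ in range(k):
            parts = lines[i].split()
            vals = [float(p) for p in parts]
            coords.append(vals if is3d else vals[:2] + [0.0])
            i += 1
        spec_id = f"specimen_{counter}"
        while i < len(lines) and "=" in lines[i] and not re.match(
            r"^LM3?\s*=", lines[i], flags=re.IGNORECASE
        ):
            key, val = lines[i].split("=", 1)
            if key.strip().upper() == "ID":
                spec_id = val.strip()
            i += 1
        sets.append(LandmarkSet(
            specimen_id=spec_id, structure="unspecified",
            points=np.array(coords, dtype=float),
        ))
        counter += 1
    return sets


def _write_tps(sets: list[LandmarkSet], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ls in sets:
            fh.write(f"LM3={ls.k}\n")
            for p in ls.points:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
            fh.write(f"ID={ls.specimen_id}\n")


def read_landmarks(path: str, dialect: str = "csv") -> list[LandmarkSet]:
    """Read landmark configurations (``csv`` dialect or ``tps`` format)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _frame_to_landmarks(pd.read_csv(path, dtype={"landmark_id": str}))
    if dialect == "tps":
        return _read_tps(path)
    raise ValueError(f"unknown landmark dialect {dialect!r}")


def write_landmarks(sets: list[LandmarkSet], path: str, dialect: str = "csv") -> None:
    if dialect == "csv":
        _landmarks_to_frame(sets).to_csv(path, index=False)
    elif dialect == "tps":
        _write_tps(sets, path)
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")
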