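"""Shared data model and file I/O for the toolkit.

Rasters travel as MRC2014 files (mode-2 float32) read and written through
gemmi's CCP4/MRC map support.  Particle coordinates travel as EMAN ``.box``
files (top-left corner + box dimensions), two-column whitespace ``.coord``
files, or a restricted STAR dialect (a single particle loop with
``rlnCoordinateX``/``rlnCoordinateY`` and, for orientation tables,
``rlnAngleRot``/``rlnAngleTilt``/``rlnAnglePsi`` and ``rlnOriginX``/``rlnOriginY``).

Internal coordinate convention: 0-based, x = column, y = row, and every
coordinate refers to the particle CENTER.  ``.box`` corners are converted at
the boundary via ``center = corner + box // 2``.  MRC arrays are row-major:
(y, x) for 2D, (z, y, x) for 3D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import FormatError, ShapeError, ValidationError

__all__ = [
    "Micrograph",
    "Volume",
    "ProbabilityMap",
    "BinaryLabelMap",
    "Pick",
    "PickSet",
    "OrientationRecord",
    "read_mrc",
    "write_mrc",
    "read_coords",
    "write_coords",
    "read_orientations",
    "write_orientations",
]

COORD_DIALECTS = ("box", "coord", "star")


def _check_raster(data: np.ndarray, ndim: int, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim != ndim:
        raise ShapeError(f"{what} must be {ndim}D, got shape {arr.shape}")
    if arr.size == 0:
        raise ShapeError(f"{what} must have at least one element per axis")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite values")
    return arr


@dataclass
class Micrograph:
    """A 2D electron micrograph: (H, W) float raster with a physical pixel size in Å."""

    data: np.ndarray
    pixel_size: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = _check_raster(self.data, 2, "Micrograph data")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class Volume:
    """A 3D density map: (D, H, W) float raster with a voxel size in Å."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = _check_raster(self.data, 3, "Volume data")
        if not self.voxel_size > 0:
            raise ValidationError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProbabilityMap:
    """Per-pixel likelihood that a pixel belongs to a particle, in [0, 1]."""

    data: np.ndarray
    source: str = ""
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = _check_raster(self.data, 2, "ProbabilityMap data")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValidationError("ProbabilityMap values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BinaryLabelMap:
    """Ground-truth segmentation mask: values strictly in {0, 1}."""

    data: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ShapeError(f"BinaryLabelMap must be 2D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("BinaryLabelMap values must be 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Pick:
    """One picked particle: center (x, y) in 0-based pixels, a score, and the box side s."""

    x: float
    y: float
    score: float = 0.0
    box_size: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValidationError("Pick score must be finite")
        if self.box_size < 1:
            raise ValidationError("box_size must be >= 1")


@dataclass
class PickSet:
    """Ordered picks for one micrograph, sorted by descending score, no duplicate centers."""

    picks: list[Pick] = field(default_factory=list)
    micrograph: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for p in self.picks:
            key = (p.x, p.y)
            if key in seen:
                raise ValidationError(f"duplicate pick at {key}")
            seen.add(key)
        self.picks = sorted(self.picks, key=lambda p: -p.score)

    def __len__(self) -> int:
        return len(self.picks)

    def __iter__(self):
        return iter(self.picks)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (x, y) centers."""
        return np.array([(p.x, p.y) for p in self.picks], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class OrientationRecord:
    """Refined orientation of one particle: ZYZ Euler angles (deg), origin shift, micrograph coordinate.

    ``(cx, cy)`` is the coordinate at which the particle was extracted;
    ``(dx, dy)`` is the refinement's translation, so the particle's true
    center on the micrograph is ``(cx - dx, cy - dy)``.
    """

    rot: float
    tilt: float
    psi: float
    dx: float = 0.0
    dy: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    micrograph: str = ""

    def __post_init__(self) -> None:
        for v in (self.rot, self.tilt, self.psi, self.dx, self.dy, self.cx, self.cy):
            if not math.isfinite(v):
                raise ValidationError("OrientationRecord fields must be finite")

    @property
    def center(self) -> tuple[float, float]:
        """True particle center after translation adjustment."""
        return (self.cx - self.dx, self.cy - self.dy)


# ---------------------------------------------------------------------------
# MRC I/O (gemmi CCP4/MRC maps; mode 2 float32)
# ---------------------------------------------------------------------------

def write_mrc(raster, path) -> None:
    """Write a raster object to an MRC2014 file (float32, cell dims encode pixel size)."""
    if isinstance(raster, Micrograph):
        data, spacing = raster.data, raster.pixel_size
    elif isinstance(raster, Volume):
        data, spacing = raster.data, raster.voxel_size
    elif isinstance(raster, ProbabilityMap):
        data, spacing = raster.data, raster.pixel_size
    elif isinstance(raster, BinaryLabelMap):
        data, spacing = raster.data.astype(np.float32), 1.0
    else:
        raise TypeError(f"cannot write object of type {type(raster).__name__} as MRC")
    if not np.all(np.isfinite(data)):
        raise ValidationError("raster contains non-finite values")
    zyx = np.asarray(data, dtype=np.float32)
    if zyx.ndim == 2:
        zyx = zyx[None, :, :]
    # gemmi grids are indexed (x, y, z); our arrays are (z, y, x)
    grid = gemmi.FloatGrid(np.ascontiguousarray(zyx.T))
    nz, ny, nx = zyx.shape
    grid.set_unit_cell(gemmi.UnitCell(nx * spacing, ny * spacing, nz * spacing, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path, kind: str = "auto"):
    """Read an MRC file into a Micrograph (2D), Volume (3D), ProbabilityMap or BinaryLabelMap.

    ``kind`` selects the 2D wrapper: "auto"/"micrograph" -> Micrograph,
    "probability" -> ProbabilityMap, "mask" -> BinaryLabelMap.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"not a valid MRC/CCP4 map: {path} ({exc})") from exc
    arr = np.array(m.grid, copy=True).T.astype(np.float32)  # -> (z, y, x)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path} contains non-finite voxels")
    nx = m.grid.nu
    cell_a = m.grid.unit_cell.a
    spacing = cell_a / nx if nx and cell_a > 0 else 1.0
    name = path.stem
    if arr.shape[0] == 1:
        arr2 = arr[0]
        if kind in ("auto", "micrograph"):
            return Micrograph(arr2, pixel_size=spacing, name=name)
        if kind == "probability":
            return ProbabilityMap(arr2, source=name, pixel_size=spacing)
        if kind == "mask":
            return BinaryLabelMap(arr2.astype(np.uint8), source=name)
        raise ValueError(f"unknown kind {kind!r}")
    if kind not in ("auto", "volume"):
        raise ShapeError(f"{path} holds a 3D map; kind={kind!r} expects 2D")
    return Volume(arr, voxel_size=spacing)


# ---------------------------------------------------------------------------
# Coordinate files
# ---------------------------------------------------------------------------

def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _split_data_lines(path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    return rows


def read_coords(path, dialect: str, box_size: int | None = None) -> PickSet:
    """Read particle coordinates; all dialects are converted to 0-based centers.

    ``box`` lines are ``x_corner y_corner w h`` (EMAN); ``coord`` lines are
    ``x_center y_center``; ``star`` files must contain rlnCoordinateX/Y.
    """
    if dialect not in COORD_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {COORD_DIALECTS}")
    name = Path(path).stem
    picks: list[Pick] = []
    if dialect == "star":
        table = _read_star_loop(path)
        xs = table.get("rlnCoordinateX")
        ys = table.get("rlnCoordinateY")
        if xs is None or ys is None:
            if not table:  # empty file -> empty pick set
                return PickSet([], micrograph=name)
            raise FormatError(f"{path}: STAR loop lacks rlnCoordinateX/Y")
        # without explicit scores, file order is preserved via descending synthetic scores
        scores = table.get("rlnAutopickFigureOfMerit",
                           [float(len(xs) - i) for i in range(len(xs))])
        bs = box_size or 1
        for x, y, sc in zip(xs, ys, scores):
            picks.append(Pick(x=x, y=y, score=sc, box_size=bs))
        return PickSet(picks, micrograph=name)

    rows = _split_data_lines(path)
    ncols = {len(r) for r in rows}
    if len(ncols) > 1:
        raise FormatError(f"{path}: mixed column counts {sorted(ncols)}")
    for i, r in enumerate(rows):
        try:
            vals = [float(v) for v in r]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric token in line {i + 1}") from exc
        if dialect == "box":
            if len(vals) < 4:
                raise FormatError(f"{path}: .box lines need 4 columns (x y w h)")
            xc, yc, w, h = vals[:4]
            bs = int(w)
            picks.append(Pick(x=xc + bs // 2, y=yc + int(h) // 2,
                              score=float(len(rows) - i), box_size=bs))
        else:  # coord
            if len(vals) < 2:
                raise FormatError(f"{path}: .coord lines need 2 columns (x y)")
            score = vals[2] if len(vals) > 2 else float(len(rows) - i)
            picks.append(Pick(x=vals[0], y=vals[1], score=score,
                              box_size=box_size or 1))
    return PickSet(picks, micrograph=name)


def write_coords(picks: PickSet, path, dialect: str) -> None:
    """Write a PickSet; read_coords(write_coords(P)) preserves centers exactly."""
    if dialect not in COORD_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {COORD_DIALECTS}")
    lines: list[str] = []
    if dialect == "box":
        for p in picks:
            lines.append(
                f"{_fmt_num(p.x - p.box_size // 2)}\t{_fmt_num(p.y - p.box_size // 2)}"
                f"\t{p.box_size}\t{p.box_size}"
            )
    elif dialect == "coord":
        for p in picks:
            lines.append(f"{_fmt_num(p.x)}\t{_fmt_num(p.y)}\t{_fmt_num(p.score)}")
    else:  # star
        lines = [
            "data_particles",
            "",
            "loop_",
            "_rlnCoordinateX #1",
            "_rlnCoordinateY #2",
            "_rlnAutopickFigureOfMerit #3",
        ]
        for p in picks:
            lines.append(f"{_fmt_num(p.x)}\t{_fmt_num(p.y)}\t{_fmt_num(p.score)}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Restricted STAR parsing (one loop, named columns) and orientation tables
# ---------------------------------------------------------------------------

def _read_star_loop(path) -> dict[str, list]:
    """Parse the first loop of a STAR file into {column: values}.

    Handles only the restricted dialect used here: one data block, one
    ``loop_`` with ``_rlnXxx`` headers, whitespace-separated rows.
    """
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = in_body = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            if in_body:
                break  # only the first loop is read
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            labels.append(line.split()[0].lstrip("_"))
            in_body = True
            continue
        if in_body:
            tok = line.split()
            if len(tok) != len(labels):
                raise FormatError(f"{path}: row has {len(tok)} fields, header has {len(labels)}")
            rows.append(tok)
    out: dict[str, list] = {}
    for j, lab in enumerate(labels):
        col = [r[j] for r in rows]
        try:
            out[lab] = [float(v) for v in col]
        except ValueError:
            out[lab] = col
    return out


_ORIENT_COLS = ("rlnCoordinateX", "rlnCoordinateY", "rlnAngleRot", "rlnAngleTilt",
                "rlnAnglePsi", "rlnOriginX", "rlnOriginY")


def read_orientations(path, fmt: str = "auto", micrograph: str = "") -> list[OrientationRecord]:
    """Read per-particle orientation records from a STAR subset or a 7-column TSV.

    TSV columns (header optional) follow the STAR names: cx cy rot tilt psi dx dy.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "star" if path.suffix.lower() == ".star" else "tsv"
    if fmt == "star":
        table = _read_star_loop(path)
        missing = [c for c in _ORIENT_COLS if c not in table]
        if missing:
            raise FormatError(f"{path}: missing STAR columns {missing}")
        cols = [table[c] for c in _ORIENT_COLS]
        mics = table.get("rlnMicrographName", [micrograph] * len(cols[0]))
    elif fmt == "tsv":
        rows = [r for r in _split_data_lines(path) if not r[0][0].isalpha()]
        if any(len(r) < 7 for r in rows):
            raise FormatError(f"{path}: TSV orientation rows need 7 numeric columns")
        cols = [[float(r[j]) for r in rows] for j in range(7)]
        mics = [r[7] if len(r) > 7 else micrograph for r in rows]
    else:
        raise ValueError(f"unknown orientation format {fmt!r}")
    cx, cy, rot, tilt, psi, dx, dy = cols
    return [
        OrientationRecord(rot=rot[i], tilt=tilt[i], psi=psi[i], dx=dx[i], dy=dy[i],
                          cx=cx[i], cy=cy[i], micrograph=str(mics[i]))
        for i in range(len(cx))
    ]


def write_orientations(records: Sequence[OrientationRecord], path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "star" if path.suffix.lower() == ".star" else "tsv"
    rows = [
        (r.cx, r.cy, r.rot, r.tilt, r.psi, r.dx, r.dy, r.micrograph) for r in records
    ]
    if fmt == "star":
        lines = ["data_particles", "", "loop_"]
        lines += [f"_{c} #{i + 1}" for i, c in enumerate(_ORIENT_COLS)]
        lines.append(f"_rlnMicrographName #{len(_ORIENT_COLS) + 1}")
        for row in rows:
            lines.append("\t".join(_fmt_num(v) for v in row[:7]) + f"\t{row[7] or 'unknown'}")
    elif fmt == "tsv":
        lines = ["# cx\tcy\trot\ttilt\tpsi\tdx\tdy\tmicrograph"]
        for row in rows:
            lines.append("\t".join(_fmt_num(v) for v in row[:7]) + f"\t{row[7] or 'unknown'}")
    else:
        raise ValueError(f"unknown orientation format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")
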