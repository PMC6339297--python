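"""Automated generation of segmentation training labels by reprojection.

Given a 3D reconstruction and each particle's refined orientation (ZYZ
Euler angles) and translation, the reconstruction is reprojected at the
particle's angles, adjusted by its translation, binarized, and pasted back
at the particle's micrograph coordinate.  The union of the pasted tiles is
the per-micrograph ground-truth segmentation mask; aligned (image, label)
windows sampled from the pair form a training set for a segmentation
network.  Because a high-resolution reconstruction has far better SNR than
any raw micrograph, the binarized reprojection is a more trustworthy
footprint of the particle than a human annotation of the noisy image.

The refinement itself (and any CTF handling) is upstream: angles and
shifts arrive as :class:`~gridpick.formats_io.OrientationRecord` inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu

from .errors import ShapeError
from .formats_io import BinaryLabelMap, Micrograph, OrientationRecord, Volume

__all__ = [
    "LabelTile",
    "LabeledWindow",
    "project_volume",
    "apply_translation",
    "binarize_projection",
    "composite_labels",
    "make_label_map",
    "generate_label_dataset",
]


@dataclass(frozen=True)
class LabelTile:
    """One particle's binarized reprojection plus the record that produced it."""

    mask: BinaryLabelMap
    record: OrientationRecord


@dataclass(frozen=True)
class LabeledWindow:
    """An aligned (micrograph window, label window) training pair."""

    image: np.ndarray
    label: np.ndarray
    micrograph: str
    x0: int
    y0: int


def _euler_matrix_zyx(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Inverse rotation matrix in (z, y, x) index order for ZYZ intrinsic angles."""
    r = Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()
    flip = np.eye(3)[::-1]
    return flip @ r.T @ flip  # inverse (transpose) mapped from xyz to zyx axes


def project_volume(volume: Volume, rot: float, tilt: float, psi: float, box: int) -> np.ndarray:
    """Rotate the volume by ZYZ Euler angles about its center and sum along z.

    Rotation uses trilinear interpolation; the identity rotation takes the
    exact direct-sum path.  The projection is center-cropped / zero-padded
    to ``box`` x ``box``.
    """
    data = volume.data
    if box < 1:
        raise ValueError("box must be >= 1")
    if box > min(data.shape[1:]):
        raise ShapeError(
            f"box {box} exceeds smallest in-plane volume dimension {min(data.shape[1:])}"
        )
    if rot == tilt == psi == 0.0:
        rotated = data.astype(float)
    else:
        m = _euler_matrix_zyx(rot, tilt, psi)
        center = (np.array(data.shape) - 1) / 2.0
        rotated = ndimage.affine_transform(
            data.astype(float), m, offset=center - m @ center, order=1, mode="constant"
        )
    proj = rotated.sum(axis=0)
    return _center_fit(proj, box)


def _center_fit(img: np.ndarray, box: int) -> np.ndarray:
    """Center-crop or zero-pad a 2D image to box x box."""
    out = np.zeros((box, box), dtype=float)
    h, w = img.shape
    sy, oy = (max(0, (h - box) // 2), max(0, (box - h) // 2))
    sx, ox = (max(0, (w - box) // 2), max(0, (box - w) // 2))
    ny, nx = min(h, box), min(w, box)
    out[oy:oy + ny, ox:ox + nx] = img[sy:sy + ny, sx:sx + nx]
    return out


def apply_translation(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift image content by (dx, dy) pixels; integer shifts are exact,
    fractional shifts use bilinear interpolation, vacated area is zero-filled."""
    img = np.asarray(img, dtype=float)
    if dx == 0.0 and dy == 0.0:
        return img.copy()
    return ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)


def binarize_projection(img: np.ndarray, source: str = "") -> BinaryLabelMap:
    """Otsu-threshold a reprojection tile into a {0, 1} mask.

    A constant image has no foreground and maps to all zeros.  The mask is
    ``img >= threshold``, with the threshold maximizing between-class
    variance of the tile's own histogram.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("projection contains non-finite values")
    if np.ptp(img) == 0.0:
        return BinaryLabelMap(np.zeros(img.shape, dtype=np.uint8), source=source)
    t = threshold_otsu(img)
    return BinaryLabelMap((img >= t).astype(np.uint8), source=source)


def composite_labels(
    tiles: Sequence[LabelTile], height: int, width: int, source: str = ""
) -> BinaryLabelMap:
    """Paste each tile centered at its record's adjusted coordinate; overlaps OR together.

    The adjusted center is ``(cx - dx, cy - dy)`` (see
    :class:`~gridpick.formats_io.OrientationRecord`); tile parts falling
    outside the micrograph are clipped.  OR is commutative, so the result
    is independent of tile order.
    """
    canvas = np.zeros((height, width), dtype=np.uint8)
    for tile in tiles:
        mask = tile.mask.data
        bh, bw = mask.shape
        cx, cy = tile.record.center
        x0 = int(round(cx)) - bw // 2
        y0 = int(round(cy)) - bh // 2
        sx0, sy0 = max(0, -x0), max(0, -y0)
        dx0, dy0 = max(0, x0), max(0, y0)
        nx = min(bw - sx0, width - dx0)
        ny = min(bh - sy0, height - dy0)
        if nx <= 0 or ny <= 0:
            continue
        canvas[dy0:dy0 + ny, dx0:dx0 + nx] |= mask[sy0:sy0 + ny, sx0:sx0 + nx]
    return BinaryLabelMap(canvas, source=source)


def make_label_map(
    volume: Volume,
    records: Sequence[OrientationRecord],
    shape: tuple[int, int],
    box: int,
    binarize_after_translation: bool = True,
) -> BinaryLabelMap:
    """Build one micrograph's label map: project, translate, binarize, composite.

    Only the subpixel residual of the adjusted center is applied as an
    image-space shift; the integer part is handled by the paste position.
    ``binarize_after_translation`` controls whether the Otsu step runs
    before or after that residual shift.
    """
    tiles: list[LabelTile] = []
    for rec in records:
        proj = project_volume(volume, rec.rot, rec.tilt, rec.psi, box)
        cx, cy = rec.center
        fx, fy = cx - round(cx), cy - round(cy)
        if binarize_after_translation:
            proj = apply_translation(proj, fx, fy)
            mask = binarize_projection(proj)
        else:
            mask_img = binarize_projection(proj).data.astype(float)
            mask_img = apply_translation(mask_img, fx, fy)
            mask = BinaryLabelMap((mask_img >= 0.5).astype(np.uint8))
        tiles.append(LabelTile(mask=mask, record=rec))
    h, w = shape
    name = records[0].micrograph if records else ""
    return composite_labels(tiles, h, w, source=name)


def generate_label_dataset(
    volume: Volume,
    records: Sequence[OrientationRecord],
    micrographs: Sequence[Micrograph],
    tile: int,
    n_windows: int = 8,
    seed: int = 0,
    box: int | None = None,
) -> list[LabeledWindow]:
    """Produce aligned (image, label) training windows for every micrograph.

    For each micrograph the full label map is generated from its orientation
    records, then ``n_windows`` windows of side ``tile`` are sampled at
    seeded random offsets (identical offsets across runs for a fixed seed).
    ``box`` is the reprojection tile side; default: smallest volume side.
    """
    rng = np.random.default_rng(seed)
    box = box if box is not None else min(volume.shape)
    by_mic: dict[str, list[OrientationRecord]] = {}
    for rec in records:
        by_mic.setdefault(rec.micrograph, []).append(rec)
    out: list[LabeledWindow] = []
    for mic in micrographs:
        h, w = mic.shape
        if tile > h or tile > w:
            raise ShapeError(f"tile {tile} exceeds micrograph shape {(h, w)}")
        label = make_label_map(volume, by_mic.get(mic.name, []), (h, w), box)
        for _ in range(n_windows):
            y0 = int(rng.integers(0, h - tile + 1))
            x0 = int(rng.integers(0, w - tile + 1))
            out.append(
                LabeledWindow(
                    image=mic.data[y0:y0 + tile, x0:x0 + tile].copy(),
                    label=label.data[y0:y0 + tile, x0:x0 + tile].copy(),
                    micrograph=mic.name,
                    x0=x0,
                    y0=y0,
                )
            )
    return out
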