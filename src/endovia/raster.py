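"""Image and mask data model shared by the whole pipeline.

The pipeline works on photographs of trypan-blue-stained corneal endothelium
taken under a surgical microscope.  This module provides the two in-memory
containers everything else consumes — :class:`RasterImage` (8/16-bit, gray or
RGB) and :class:`BinaryMask` — together with the handful of primitive
operations the downstream stages share: luma grayscale conversion, masking,
lossless right-angle rotation, and binary image moments.

Conventions
-----------
* 0-based, row-major pixel coordinates; pixel centers sit at integer
  coordinates; distances are Euclidean in pixel units unless a physical
  ``mm_per_pixel`` scale is attached.
* Rotations are restricted to multiples of 90 degrees and are exact pixel
  permutations (no interpolation), counter-clockwise for positive turns.
* Masks persist as single-channel PNG with 0 = background, 255 = member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "RasterImage",
    "BinaryMask",
    "Centroid",
    "to_gray",
    "apply_mask",
    "rotate_right_angle",
    "rotate_centroid",
    "mask_moments",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: Rec.601 luma weights, the default of mainstream CV stacks.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class RasterImage:
    """A gray or RGB raster with optional physical scale.

    Parameters
    ----------
    pixels
        ``(H, W)`` array for gray images or ``(H, W, 3)`` for RGB; dtype
        uint8 or uint16.
    mm_per_pixel
        Optional physical scale in millimetres per pixel.
    """

    pixels: np.ndarray
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.pixels)
        if a.ndim == 2:
            pass
        elif a.ndim == 3 and a.shape[2] == 3:
            pass
        else:
            raise ValueError(
                f"expected (H, W) or (H, W, 3) pixel array, got shape {a.shape}"
            )
        if a.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"expected uint8 or uint16 pixels, got {a.dtype}")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive when present")
        self.pixels = a

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Boolean membership grid annotating an image of the same shape."""

    membership: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.membership)
        if a.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {a.shape}")
        self.membership = a.astype(bool)

    @property
    def height(self) -> int:
        return self.membership.shape[0]

    @property
    def width(self) -> int:
        return self.membership.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.membership.shape

    @property
    def area(self) -> int:
        """Number of member pixels."""
        return int(self.membership.sum())

    def is_empty(self) -> bool:
        return not self.membership.any()


@dataclass(frozen=True)
class Centroid:
    """Sub-pixel centroid in (row, col) coordinates."""

    row: float
    col: float


def to_gray(image: RasterImage, weights: tuple[float, float, float] = REC601_WEIGHTS) -> RasterImage:
    """Convert an RGB image to single-channel gray via a weighted luma sum.

    Gray input passes through unchanged.  The result is rounded back to the
    input dtype so downstream integer arithmetic stays exact.
    """
    if image.channels == 1:
        return RasterImage(image.pixels.copy(), image.mm_per_pixel)
    if image.channels != 3:
        raise ValueError(
            f"cannot convert image with {image.channels} channels to gray; "
            "expected 1 or 3"
        )
    w = np.asarray(weights, dtype=np.float64)
    luma = image.pixels.astype(np.float64) @ w
    gray = np.round(luma).astype(image.pixels.dtype)
    return RasterImage(gray, image.mm_per_pixel)


def apply_mask(image: RasterImage, mask: BinaryMask, fill: int = 0) -> RasterImage:
    """Set pixels outside ``mask`` to ``fill``; member pixels pass through."""
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    out = image.pixels.copy()
    out[~mask.membership] = fill
    return RasterImage(out, image.mm_per_pixel)


def rotate_right_angle(obj, quarter_turns: int):
    """Rotate an image or mask by ``quarter_turns`` × 90° counter-clockwise.

    A lossless pixel permutation: four applications of one quarter turn
    reproduce the input bit-exactly.  Any angle that is not a multiple of 90°
    is rejected — no interpolation is ever performed.
    """
    if quarter_turns not in (0, 1, 2, 3):
        raise ValueError(
            f"quarter_turns must be one of 0, 1, 2, 3; got {quarter_turns!r} "
            "(right angles only; interpolation is not permitted)"
        )
    if isinstance(obj, RasterImage):
        return RasterImage(
            np.ascontiguousarray(np.rot90(obj.pixels, quarter_turns)),
            obj.mm_per_pixel,
        )
    if isinstance(obj, BinaryMask):
        rotated = np.ascontiguousarray(np.rot90(obj.membership, quarter_turns))
        out = type(obj).__new__(type(obj))
        # preserve subclass attributes (e.g. CorneaMask provenance)
        out.__dict__.update(obj.__dict__)
        out.membership = rotated
        return out
    raise TypeError(f"cannot rotate object of type {type(obj).__name__}")


def rotate_centroid(c: Centroid, shape: tuple[int, int], quarter_turns: int) -> Centroid:
    """Map a centroid through the same rotation as :func:`rotate_right_angle`."""
    if quarter_turns not in (0, 1, 2, 3):
        raise ValueError("quarter_turns must be one of 0, 1, 2, 3")
    h, w = shape
    r, col = c.row, c.col
    for _ in range(quarter_turns):
        r, col = (w - 1) - col, r
        h, w = w, h
    return Centroid(r, col)


def mask_moments(mask: BinaryMask) -> Centroid:
    """Centroid of a binary mask from its zeroth and first image moments."""
    rows, cols = np.nonzero(mask.membership)
    if rows.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    return Centroid(float(rows.mean()), float(cols.mean()))


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path, mm_per_pixel: float | None = None) -> RasterImage:
    """Read a PNG or TIFF raster; RGBA alpha is dropped."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        a = tifffile.imread(path)
    else:
        a = iio.imread(path)
    a = np.asarray(a)
    if a.ndim == 3 and a.shape[2] == 4:
        a = a[:, :, :3]
    if a.dtype not in (np.uint8, np.uint16):
        a = a.astype(np.uint8)
    return RasterImage(a, mm_per_pixel)


def write_image(image: RasterImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Persist a mask as 8-bit PNG, 0 = background and 255 = member."""
    iio.imwrite(Path(path), mask.membership.astype(np.uint8) * 255)


def read_mask(path: str | Path) -> BinaryMask:
    a = np.asarray(iio.imread(Path(path)))
    if a.ndim == 3:
        a = a[:, :, 0]
    return BinaryMask(a > 0)
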