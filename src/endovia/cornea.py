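"""Cornea (endothelium) segmentation: promptable backends plus a classical fallback.

The first pipeline stage isolates the corneal endothelium from the scleral
rim and the surgical background.  In routine use this is done by a promptable
foundation segmenter (the user clicks one or more include/exclude points);
here that segmenter is a *plugin*: any callable taking ``(image, prompts)``
and returning a boolean mask satisfies the contract, so no model weights are
bundled.  A classical, weight-free fallback based on multi-Otsu thresholding
is provided for fully automatic operation, and every mask — prompted,
fallback or loaded from file — is normalised to the same guarantees: exactly
one 8-connected component and no interior holes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import disk

from .raster import BinaryMask, RasterImage, read_mask, to_gray

__all__ = [
    "PointPrompt",
    "CorneaMask",
    "SegmenterBackend",
    "register_backend",
    "get_backend",
    "segment_cornea_prompted",
    "segment_cornea_fallback",
    "load_cornea_mask",
    "postprocess_mask",
]

log = logging.getLogger(__name__)

# 8-connectivity for components, 4-connectivity for holes (standard duality).
_STRUCT8 = np.ones((3, 3), bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class PointPrompt:
    """A user-supplied point of interest for a promptable segmenter."""

    row: int
    col: int
    polarity: str = "include"  # include | exclude

    def __post_init__(self) -> None:
        if self.polarity not in ("include", "exclude"):
            raise ValueError(f"polarity must be include or exclude, got {self.polarity!r}")


class CorneaMask(BinaryMask):
    """A validated endothelium mask: single component, hole-free, non-empty."""

    def __init__(self, membership: np.ndarray, provenance: str = "unknown"):
        super().__init__(membership)
        self.provenance = provenance


class SegmenterBackend(Protocol):
    """Contract for promptable segmentation plugins."""

    def __call__(self, image: RasterImage, prompts: list[PointPrompt]) -> np.ndarray: ...


_BACKENDS: dict[str, Callable] = {}


def register_backend(name: str, backend: Callable) -> None:
    _BACKENDS[name] = backend


def get_backend(name: str) -> Callable:
    if name not in _BACKENDS:
        raise KeyError(
            f"no segmenter backend named {name!r} is registered; register one "
            "with cornea.register_backend, or use segment_cornea_fallback "
            "for weight-free automatic segmentation"
        )
    return _BACKENDS[name]


def postprocess_mask(raw: np.ndarray, provenance: str) -> CorneaMask:
    """Normalise any raw cornea mask to the CorneaMask invariants.

    Keeps the largest 8-connected component and fills interior holes
    (4-connected complement).  Raises if the mask is empty.
    """
    raw = np.asarray(raw, dtype=bool)
    if not raw.any():
        raise ValueError("cornea mask is empty")
    labels, n = ndimage.label(raw, structure=_STRUCT8)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        raw = labels == int(np.argmax(sizes))
    filled = ndimage.binary_fill_holes(raw, structure=_STRUCT4)
    changed = int(np.count_nonzero(filled != np.asarray(raw)))
    if changed > 0.005 * filled.size:
        log.warning(
            "cornea mask repair changed %d pixels (%.2f%% of image)",
            changed,
            100 * changed / filled.size,
        )
    return CorneaMask(filled, provenance)


def segment_cornea_prompted(
    image: RasterImage,
    prompts: list[PointPrompt],
    backend: Callable | str,
) -> CorneaMask:
    """Segment the endothelium with a promptable backend.

    The returned mask is post-processed to a single hole-free component and
    checked against the prompt contract: it must contain every include point
    and exclude every exclude point.
    """
    if not any(p.polarity == "include" for p in prompts):
        raise ValueError("at least one include prompt is required")
    for p in prompts:
        if not (0 <= p.row < image.height and 0 <= p.col < image.width):
            raise ValueError(f"prompt ({p.row}, {p.col}) lies outside the image")
    fn = get_backend(backend) if isinstance(backend, str) else backend
    raw = np.asarray(fn(image, list(prompts)), dtype=bool)
    if raw.shape != image.shape:
        raise ValueError(
            f"backend returned mask of shape {raw.shape}, expected {image.shape}"
        )
    if not raw.any():
        raise ValueError("segmenter backend returned an empty mask")
    mask = postprocess_mask(raw, provenance="prompted")
    for p in prompts:
        inside = bool(mask.membership[p.row, p.col])
        if p.polarity == "include" and not inside:
            raise ValueError(
                f"backend contract violation: include prompt ({p.row}, {p.col}) "
                "is outside the returned mask"
            )
        if p.polarity == "exclude" and inside:
            raise ValueError(
                f"backend contract violation: exclude prompt ({p.row}, {p.col}) "
                "is inside the returned mask"
            )
    return mask


def segment_cornea_fallback(image: RasterImage, closing_radius: int = 3) -> CorneaMask:
    """Weight-free cornea segmentation for the standard acquisition geometry.

    Assumes a bright, roughly circular endothelium on a darker background,
    with an even brighter scleral rim around it (the BSS-filled corneoscleral
    rim reflects more light).  Three-class Otsu separates background / cornea
    / sclera; the cornea band is cleaned by morphological closing, reduced to
    its largest component, and hole-filled.  Every step commutes with
    right-angle rotation, so the fallback is rotation-equivariant.
    """
    gray = to_gray(image).pixels
    if gray.max() == gray.min():
        raise ValueError("no cornea found: image has no contrast")
    try:
        t_low, t_high = threshold_multiotsu(gray, classes=3)
    except ValueError as e:  # fewer than 3 distinct gray levels
        raise ValueError(f"no cornea found: {e}") from e
    band = (gray > t_low) & (gray < t_high)
    band = ndimage.binary_closing(
        band, structure=disk(closing_radius), iterations=1
    )
    if not band.any():
        raise ValueError("no cornea found: foreground empty after closing")
    labels, n = ndimage.label(band, structure=_STRUCT8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    if sizes[largest] < 0.01 * gray.size:
        raise ValueError(
            "no cornea found: largest candidate component covers "
            f"{100 * sizes[largest] / gray.size:.2f}% of the image (< 1%)"
        )
    comp = labels == largest
    filled = ndimage.binary_fill_holes(comp, structure=_STRUCT4)
    return CorneaMask(filled, provenance="fallback")


def load_cornea_mask(path: str | Path) -> CorneaMask:
    """Load a mask file and enforce the CorneaMask invariants (with repair)."""
    mask = read_mask(path)
    if mask.is_empty():
        raise ValueError(f"mask file {path} contains no member pixels")
    out = postprocess_mask(mask.membership, provenance="file")
    return out
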