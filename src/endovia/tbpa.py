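"""Six-stage segmentation of trypan-blue-positive areas (TBPAs).

Trypan blue stains dead endothelial cells and denuded Descemet membrane, so
stained regions appear *darker* than the surrounding healthy endothelium.
Within a given cornea mask the algorithm proceeds:

1. grayscale conversion, optional CLAHE when local contrast is insufficient
   (CLAHE before the blur), then Gaussian blur;
2. adaptive (local-mean) thresholding to a coarse candidate mask, cleaned by
   morphological opening;
3. Euclidean distance transform of the candidate mask;
4. a second threshold on the distance map picks seed regions — pixels deep
   inside candidate areas;
5. marker-controlled watershed: seeds grow over the "unknown" margin
   (dilated candidates minus seeds) on the gradient of the preprocessed
   image, with everything outside the cornea held by a single background
   marker to suppress edge artifacts;
6. watershed regions are filtered (minimum area, majority inside the cornea)
   and their union, clipped to the cornea, is the final TBPA mask.

All stage boundaries are uint8/boolean, so the chain is bit-deterministic.
The adaptive threshold is evaluated in exact integer arithmetic (window sums
of a symmetric-padded image), which makes it reproducible across platforms
and directly comparable to a naive sliding-window implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, segmentation
from skimage.morphology import disk

from .cornea import CorneaMask
from .raster import BinaryMask, RasterImage, to_gray

__all__ = [
    "TbpaConfig",
    "DistanceMap",
    "LabelMap",
    "OUTSIDE_LABEL",
    "HEALTHY_LABEL",
    "REGION_START",
    "preprocess_gray",
    "adaptive_threshold",
    "coarse_candidate_mask",
    "distance_transform",
    "seed_mask",
    "watershed_refine",
    "finalize_tbpa",
    "segment_tbpa",
]

log = logging.getLogger(__name__)

# reserved marker labels in LabelMap
OUTSIDE_LABEL = 1  # everything outside the cornea, one uniform region
HEALTHY_LABEL = 2  # inside the cornea, away from any candidate stain
REGION_START = 3  # first stained-region label


@dataclass
class TbpaConfig:
    """Tunable parameters of the TBPA segmentation chain.

    The published description of the algorithm is numeric-free; every default
    below is standard CV practice at surgical-microscope image scale and is
    validated end-to-end on the synthetic suite.

    Attributes
    ----------
    gaussian_kernel
        Odd side length (px) of the Gaussian blur kernel; sigma follows the
        conventional ``0.3·((k−1)/2 − 1) + 0.8`` rule.
    clahe_trigger
        CLAHE is applied when the interquartile range of gray intensities
        inside the cornea falls below this value (8-bit scale).
    clahe_clip, clahe_tiles
        CLAHE clip limit (fraction) and tile grid count per image side.
    adaptive_block, adaptive_block_coarse
        Odd window sides (px) of the local-mean adaptive threshold.  The
        fine window resolves thin scratches and stain edges; the optional
        coarse window (``None`` disables it) additionally flags the cores of
        stained areas wider than the fine window, whose local mean is the
        stain itself.  Candidates are the union of the two scales.
    adaptive_offset
        A pixel is a candidate when darker than its local mean by more than
        this offset (8-bit intensity units).
    opening_kernel, opening_iters
        Elliptical structuring-element side (px) and iteration count of the
        post-threshold morphological opening.
    seed_fraction
        τ ∈ (0, 1]: seeds are pixels whose distance-transform value reaches
        τ · max over the map (global by default, per candidate component when
        ``seed_per_component`` is set).
    min_region_area
        Watershed regions smaller than this (px) are discarded.
    polarity
        ``"dark"``: stains darker than surround (trypan blue); ``"light"``
        for inverted acquisitions.
    flood_surface
        Surface the watershed floods: ``"gradient"`` (default) of the
        preprocessed gray, the raw ``"gray"``, or the ``"inverted_distance"``
        map.
    """

    gaussian_kernel: int = 5
    clahe_trigger: float = 20.0
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    adaptive_block: int = 51
    adaptive_block_coarse: int | None = 151
    adaptive_offset: int = 5
    opening_kernel: int = 3
    opening_iters: int = 2
    seed_fraction: float = 0.2
    seed_per_component: bool = False
    min_region_area: int = 25
    polarity: str = "dark"
    flood_surface: str = "gradient"
    dilate_kernel: int = 3
    dilate_iters: int = 2
    edge_margin: int = 5

    def __post_init__(self) -> None:
        for name in ("gaussian_kernel", "adaptive_block", "opening_kernel", "dilate_kernel"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.adaptive_block_coarse is not None and (
            self.adaptive_block_coarse < 3 or self.adaptive_block_coarse % 2 == 0
        ):
            raise ValueError(
                f"adaptive_block_coarse must be odd and >= 3 or None, "
                f"got {self.adaptive_block_coarse}"
            )
        if not 0 < self.seed_fraction <= 1:
            raise ValueError(f"seed_fraction must lie in (0, 1], got {self.seed_fraction}")
        if self.polarity not in ("dark", "light"):
            raise ValueError(f"polarity must be 'dark' or 'light', got {self.polarity!r}")
        if self.flood_surface not in ("gradient", "gray", "inverted_distance"):
            raise ValueError(f"unknown flood_surface {self.flood_surface!r}")
        if self.min_region_area < 0 or self.adaptive_offset < 0 or self.edge_margin < 0:
            raise ValueError(
                "min_region_area, adaptive_offset and edge_margin must be non-negative"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (px) to the nearest background pixel."""

    distances: np.ndarray

    @property
    def max(self) -> float:
        return float(self.distances.max()) if self.distances.size else 0.0


@dataclass
class LabelMap:
    """Watershed output: integer region labels over the full image.

    Labels 1 and 2 are reserved (outside-cornea background and healthy
    tissue); stained-region labels start at :data:`REGION_START`.
    """

    labels: np.ndarray
    region_labels: list[int] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


# ---------------------------------------------------------------------------
# stage 1 — preprocessing


def _gaussian_kernel_1d(ksize: int) -> np.ndarray:
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize, dtype=np.float64) - (ksize - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def gaussian_blur_u8(gray: np.ndarray, ksize: int) -> np.ndarray:
    """Separable Gaussian blur with symmetric border, rounded back to uint8."""
    k = _gaussian_kernel_1d(ksize)
    f = gray.astype(np.float64)
    f = ndimage.correlate1d(f, k, axis=0, mode="reflect")
    f = ndimage.correlate1d(f, k, axis=1, mode="reflect")
    return np.clip(np.round(f), 0, 255).astype(np.uint8)


def contrast_iqr(gray: np.ndarray, mask: np.ndarray) -> float:
    """Interquartile range of intensities inside a mask — the CLAHE trigger."""
    vals = gray[mask]
    if vals.size == 0:
        return 0.0
    q25, q75 = np.percentile(vals, [25, 75])
    return float(q75 - q25)


def preprocess_gray(
    image: RasterImage, cornea: CorneaMask, cfg: TbpaConfig | None = None
) -> RasterImage:
    """Stage 1: luma conversion, conditional CLAHE, Gaussian blur.

    CLAHE runs only when the cornea-interior intensity IQR falls below
    ``cfg.clahe_trigger`` — i.e. for images with insufficient contrast — and
    always *before* the Gaussian filter.
    """
    cfg = cfg or TbpaConfig()
    if cornea.shape != image.shape:
        raise ValueError(
            f"cornea mask shape {cornea.shape} does not match image {image.shape}"
        )
    gray = to_gray(image).pixels
    if gray.dtype != np.uint8:  # 16-bit input: rescale to the 8-bit lattice
        gray = (gray.astype(np.float64) / gray.max() * 255).round().astype(np.uint8)
    iqr = contrast_iqr(gray, cornea.membership)
    if iqr < cfg.clahe_trigger:
        log.info("low contrast inside cornea (IQR %.1f < %.1f): applying CLAHE",
                 iqr, cfg.clahe_trigger)
        tiles = max(2, cfg.clahe_tiles)
        eq = exposure.equalize_adapthist(
            gray,
            kernel_size=(max(8, gray.shape[0] // tiles), max(8, gray.shape[1] // tiles)),
            clip_limit=cfg.clahe_clip,
            nbins=256,
        )
        gray = np.round(eq * 255).astype(np.uint8)
    blurred = gaussian_blur_u8(gray, cfg.gaussian_kernel)
    return RasterImage(blurred, image.mm_per_pixel)


# ---------------------------------------------------------------------------
# stage 2 — adaptive thresholding


def _extrapolate_fill(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace outside-mask pixels by linear extrapolation across the rim.

    Local-mean windows straddling the cornea rim must not see the dark
    background or bright sclera.  Neither a constant (nearest-value) fill
    nor a mirror fill is enough under radial shading: both turn the monotone
    vignette ramp into a profile whose minimum sits on the rim, so every rim
    pixel falls below its window mean and a spurious ring of candidates
    appears along the limbus.  Continuing the ramp linearly — each outside
    pixel takes ``2·I(nearest boundary) − I(reflected point)`` — keeps the
    local mean unbiased right up to the mask edge.
    """
    if mask.all():
        return gray
    _, (ir, ic) = ndimage.distance_transform_edt(~mask, return_indices=True)
    rows, cols = np.indices(mask.shape)
    mr = np.clip(2 * ir - rows, 0, mask.shape[0] - 1)
    mc = np.clip(2 * ic - cols, 0, mask.shape[1] - 1)
    # where the reflected point falls outside the mask (concave spots),
    # fall back to the nearest boundary value
    bad = ~mask[mr, mc]
    mr[bad] = ir[bad]
    mc[bad] = ic[bad]
    g16 = gray.astype(np.int64)
    extrap = np.clip(2 * g16[ir, ic] - g16[mr, mc], 0, 255).astype(gray.dtype)
    out = gray.copy()
    out[~mask] = extrap[~mask]
    return out


def box_window_sums(a: np.ndarray, block: int) -> np.ndarray:
    """Exact integer sums over centered ``block``×``block`` windows.

    The image is padded symmetrically (edge-mirrored without repeating the
    edge sample's neighbour order, numpy mode ``symmetric``), then summed via
    a 2-D integral image in int64 — no floating point anywhere.
    """
    r = block // 2
    p = np.pad(a.astype(np.int64), r, mode="symmetric")
    ii = np.zeros((p.shape[0] + 1, p.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = p.cumsum(axis=0).cumsum(axis=1)
    h, w = a.shape
    return (
        ii[block : block + h, block : block + w]
        - ii[:h, block : block + w]
        - ii[block : block + h, :w]
        + ii[:h, :w]
    )


def adaptive_threshold(
    gray: np.ndarray, inside: np.ndarray, cfg: TbpaConfig
) -> np.ndarray:
    """The bare local-mean threshold rule over an analysis region.

    A pixel is flagged when ``area·I < Σwindow − area·offset`` (dark
    polarity), with outside-region pixels replaced by linear extrapolation
    before the window sums.  All arithmetic is integer, so the rule agrees
    bit-for-bit with a naive sliding-window evaluation.
    """
    filled = _extrapolate_fill(gray, inside)
    sums = box_window_sums(filled, cfg.adaptive_block)
    area = cfg.adaptive_block * cfg.adaptive_block
    lhs = filled.astype(np.int64) * area
    if cfg.polarity == "dark":
        return (lhs < sums - cfg.adaptive_offset * area) & inside
    return (lhs > sums + cfg.adaptive_offset * area) & inside


def coarse_candidate_mask(
    gray: RasterImage, cornea: CorneaMask, cfg: TbpaConfig | None = None
) -> BinaryMask:
    """Stage 2: local-mean adaptive threshold + morphological opening.

    A cornea pixel is a candidate when its intensity is below the mean of its
    ``adaptive_block`` window by more than ``adaptive_offset`` (strictly; the
    comparison is done in integer arithmetic: ``area·I < Σwindow − area·offset``).
    The opening then removes sub-kernel specks.

    Candidates are searched inside the cornea eroded by ``edge_margin`` px:
    light bleeding from the bright scleral rim into the outermost cornea
    pixels otherwise produces a spurious ring of "dark" pixels along the
    limbus.  Watershed growth and the final clip to the *full* cornea mask
    recover genuine stains that touch the rim.
    """
    cfg = cfg or TbpaConfig()
    if gray.channels != 1:
        raise ValueError("coarse_candidate_mask expects a 1-channel image")
    g = gray.pixels
    inside = cornea.membership
    if cfg.edge_margin > 0:
        inside = ndimage.binary_erosion(
            inside, structure=disk(cfg.edge_margin), border_value=0
        )
    if not inside.any():
        return BinaryMask(np.zeros(g.shape, bool))
    filled = _extrapolate_fill(g, inside)
    cand = adaptive_threshold(g, inside, cfg)
    if cfg.adaptive_block_coarse is not None:
        coarse_cfg = replace(cfg, adaptive_block=cfg.adaptive_block_coarse)
        cand = cand | adaptive_threshold(g, inside, coarse_cfg)
    if cand.any() and cfg.opening_iters > 0:
        cand = ndimage.binary_opening(
            cand, structure=disk(cfg.opening_kernel // 2), iterations=cfg.opening_iters
        )
    if cand.any():
        # a stained area wider than the threshold window yields a ring of
        # candidates around an un-flagged core: the local mean inside the
        # core is itself the stain level.  Reclaim enclosed pixels, but only
        # dark-consistent ones — healthy tissue encircled by thin distinct
        # stains must not be flooded.
        filled_holes = ndimage.binary_fill_holes(
            cand, structure=ndimage.generate_binary_structure(2, 1)
        )
        added = filled_holes & ~cand
        if added.any():
            healthy = inside & ~filled_holes
            mu_cand = filled[cand].mean()
            mu_healthy = filled[healthy].mean() if healthy.any() else 255.0
            if cfg.polarity == "dark":
                dark_core = filled < 0.5 * (mu_cand + mu_healthy)
            else:
                dark_core = filled > 0.5 * (mu_cand + mu_healthy)
            cand = cand | (added & dark_core)
    return BinaryMask(cand & inside)


# ---------------------------------------------------------------------------
# stages 3 & 4 — distance transform and seeding


def distance_transform(candidates: BinaryMask) -> DistanceMap:
    """Stage 3: exact Euclidean distance to the nearest non-candidate pixel."""
    if candidates.is_empty():
        return DistanceMap(np.zeros(candidates.shape, dtype=np.float64))
    return DistanceMap(ndimage.distance_transform_edt(candidates.membership))


def seed_mask(dist: DistanceMap, cfg: TbpaConfig | None = None) -> BinaryMask:
    """Stage 4: threshold the distance map at τ · max to pick seed cores.

    With ``seed_per_component`` the τ-fraction applies to each candidate
    component's own maximum instead of the global one, which protects thin
    stains co-occurring with bulky ones.
    """
    cfg = cfg or TbpaConfig()
    d = dist.distances
    if dist.max == 0:
        return BinaryMask(np.zeros(d.shape, bool))
    if not cfg.seed_per_component:
        return BinaryMask(d >= cfg.seed_fraction * dist.max)
    comp, n = ndimage.label(d > 0, structure=np.ones((3, 3), bool))
    maxima = ndimage.maximum(d, labels=comp, index=np.arange(1, n + 1))
    thresh = np.zeros(n + 1)
    thresh[1:] = cfg.seed_fraction * np.asarray(maxima)
    return BinaryMask((d > 0) & (d >= thresh[comp]))


# ---------------------------------------------------------------------------
# stage 5 — marker-controlled watershed


def watershed_refine(
    gray: RasterImage,
    seeds: BinaryMask,
    candidates: BinaryMask,
    cornea: CorneaMask,
    cfg: TbpaConfig | None = None,
) -> LabelMap:
    """Stage 5: grow seed markers over the unknown margin by watershed.

    Markers: each 8-connected seed component gets its own label (from
    :data:`REGION_START`); everything outside the cornea is one reserved
    background label; cornea tissue away from the dilated candidate zone is a
    second reserved label; the remaining "unknown" margin is flooded.  The
    flooding surface is the Sobel gradient magnitude of the preprocessed
    image by default.  Ridge pixels are assigned to an adjacent region (no
    separate boundary label), so the output has no unlabeled pixels.
    """
    cfg = cfg or TbpaConfig()
    s = seeds.membership
    c = candidates.membership
    if (s & ~c).any():
        warnings.warn(
            "seed mask extends outside the candidate mask; intersecting",
            stacklevel=2,
        )
        s = s & c
    labels = np.zeros(gray.shape, dtype=np.int32)
    labels[~cornea.membership] = OUTSIDE_LABEL
    if not s.any():
        labels[cornea.membership] = HEALTHY_LABEL
        return LabelMap(labels, [])
    seed_labels, n = ndimage.label(s, structure=np.ones((3, 3), bool))
    dilated = ndimage.binary_dilation(
        c, structure=disk(cfg.dilate_kernel // 2), iterations=cfg.dilate_iters
    )
    unknown = dilated & ~s & cornea.membership
    labels[cornea.membership & ~unknown] = HEALTHY_LABEL
    labels[seed_labels > 0] = seed_labels[seed_labels > 0] + (REGION_START - 1)
    g = gray.pixels.astype(np.float64)
    if cfg.flood_surface == "gradient":
        surface = filters.sobel(g)
    elif cfg.flood_surface == "gray":
        surface = g if cfg.polarity == "light" else g.max() - g
    else:  # inverted distance
        surface = -ndimage.distance_transform_edt(c)
    flooded = segmentation.watershed(surface, markers=labels, watershed_line=False)
    region_labels = [int(v) for v in range(REGION_START, REGION_START + n)]
    return LabelMap(flooded.astype(np.int32), region_labels)


# ---------------------------------------------------------------------------
# stage 6 — final mask


def finalize_tbpa(
    labels: LabelMap, cornea: CorneaMask, cfg: TbpaConfig | None = None
) -> BinaryMask:
    """Stage 6: filter watershed regions and emit the final TBPA mask.

    A region is retained when its area is at least ``min_region_area`` px and
    at least half of it lies inside the cornea; the union of retained regions
    clipped to the cornea is the final TBPA indicator.
    """
    cfg = cfg or TbpaConfig()
    lab = labels.labels
    out = np.zeros(lab.shape, bool)
    if not labels.region_labels:
        return BinaryMask(out)
    nmax = max(labels.region_labels)
    total = np.bincount(lab.ravel(), minlength=nmax + 1)
    inside = np.bincount(lab[cornea.membership].ravel(), minlength=nmax + 1)
    keep = []
    for rl in labels.region_labels:
        if total[rl] < cfg.min_region_area:
            continue
        if inside[rl] * 2 < total[rl]:
            continue
        keep.append(rl)
    if keep:
        out = np.isin(lab, keep) & cornea.membership
    return BinaryMask(out)


def segment_tbpa(
    image: RasterImage,
    cornea: CorneaMask,
    cfg: TbpaConfig | None = None,
    return_stages: bool = False,
):
    """Full TBPA chain (stages 1–6).  Deterministic; result ⊆ cornea.

    With ``return_stages`` a dict of the intermediate products (preprocessed
    gray, candidates, distance map, seeds, label map) is returned alongside
    the final mask, mirroring the stage snapshots A–F.
    """
    cfg = cfg or TbpaConfig()
    gray = preprocess_gray(image, cornea, cfg)
    candidates = coarse_candidate_mask(gray, cornea, cfg)
    dist = distance_transform(candidates)
    seeds = seed_mask(dist, cfg)
    labels = watershed_refine(gray, seeds, candidates, cornea, cfg)
    tbpa = finalize_tbpa(labels, cornea, cfg)
    assert not (tbpa.membership & ~cornea.membership).any(), "TBPA must stay inside cornea"
    if return_stages:
        return tbpa, {
            "gray": gray,
            "candidates": candidates,
            "distance": dist,
            "seeds": seeds,
            "labels": labels,
        }
    return tbpa
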