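"""Concentric-ring geometry and endothelial mortality computation.

The segmented cornea is divided into five concentric rings for
interpretability: the centroid comes from the binary image moments of the
cornea mask, the outer radius R is the least-squares estimate given by the
mean distance from the centroid to every outer-contour pixel, and the inner
radii are the fractions k/5 of R (nominally the 2, 4, 6, 8 and 10 mm rings of
an adult cornea).  Mortality of a region is the percentage of its cornea
pixels that are TBPA.

Because R is a least-squares fit and real corneas are not perfectly
circular, cornea pixels can fall outside the fifth ring; they are tracked in
an explicit "outside-rings" bucket so that ring counts always sum exactly to
the whole-cornea counts, and both an annulus-based and a cumulative-disc
reading of "ring k" are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cornea import CorneaMask
from .raster import BinaryMask, Centroid, mask_moments

__all__ = [
    "RingPartition",
    "ViabilityReport",
    "outer_boundary",
    "fit_ring_partition",
    "ring_mortality",
    "mortality_identity_check",
]

_CROSS = ndimage.generate_binary_structure(2, 1)


def outer_boundary(mask: BinaryMask) -> np.ndarray:
    """Boolean map of mask pixels having a 4-neighbour outside the mask."""
    m = mask.membership
    eroded = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~eroded


@dataclass
class RingPartition:
    """Centroid, fitted outer radius, ring radii and per-pixel ring labels.

    ``labels``: 0 outside the cornea; 1..n_rings for the half-open annuli
    [r_{k-1}, r_k); n_rings+1 for cornea pixels at distance >= R
    ("outside-rings").
    """

    centroid: Centroid
    outer_radius: float
    ring_radii: np.ndarray
    labels: np.ndarray
    n_rings: int
    mm_per_pixel: float

    @property
    def outside_label(self) -> int:
        return self.n_rings + 1


def fit_ring_partition(cornea: CorneaMask, n_rings: int = 5) -> RingPartition:
    """Fit the concentric-ring partition to a cornea mask.

    R is the mean Euclidean distance from the moments centroid to each
    outer-boundary pixel center; ring k spans [ (k-1)/n · R, k/n · R ).
    The nominal physical scale assumes the outer ring is the 10-mm ring.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if cornea.is_empty():
        raise ValueError("cannot fit rings to an empty cornea mask")
    c = mask_moments(cornea)
    br, bc = np.nonzero(outer_boundary(cornea))
    dists = np.hypot(br - c.row, bc - c.col)
    R = float(dists.mean())
    radii = np.arange(1, n_rings + 1) * R / n_rings
    rows = np.arange(cornea.height)[:, None] - c.row
    cols = np.arange(cornea.width)[None, :] - c.col
    d = np.hypot(rows, cols)
    # half-open annuli [r_{k-1}, r_k); searchsorted side='right' gives k-1
    lab = np.searchsorted(radii, d, side="right") + 1
    lab = np.minimum(lab, n_rings + 1).astype(np.int16)
    lab[~cornea.membership] = 0
    return RingPartition(
        centroid=c,
        outer_radius=R,
        ring_radii=radii,
        labels=lab,
        n_rings=n_rings,
        mm_per_pixel=10.0 / R if R > 0 else float("nan"),
    )


@dataclass
class ViabilityReport:
    """Per-ring and whole-cornea mortality percentages with pixel counts.

    ``ring_total_px`` / ``ring_tbpa_px`` have length n_rings+1: entries
    0..n_rings-1 are the annuli, the last entry is the outside-rings bucket.
    Undefined rings (no cornea pixels) carry NaN mortality and are listed in
    ``undefined_rings`` — never silently reported as 0.
    """

    n_rings: int
    ring_total_px: np.ndarray
    ring_tbpa_px: np.ndarray
    mortality_annulus: list[float]
    mortality_cumulative: list[float]
    whole_cornea_total_px: int
    whole_cornea_tbpa_px: int
    whole_cornea_mortality: float
    mode: str
    undefined_rings: list[int] = field(default_factory=list)
    outer_radius_px: float = float("nan")
    mm_per_pixel: float = float("nan")
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def mortality(self) -> list[float]:
        """Per-ring mortalities in the report's primary mode."""
        return (
            self.mortality_annulus
            if self.mode == "annulus"
            else self.mortality_cumulative
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "n_rings": self.n_rings,
            "mode": self.mode,
            "ring_total_px": [int(v) for v in self.ring_total_px],
            "ring_tbpa_px": [int(v) for v in self.ring_tbpa_px],
            "mortality_annulus_pct": self.mortality_annulus,
            "mortality_cumulative_pct": self.mortality_cumulative,
            "whole_cornea_total_px": self.whole_cornea_total_px,
            "whole_cornea_tbpa_px": self.whole_cornea_tbpa_px,
            "whole_cornea_mortality_pct": self.whole_cornea_mortality,
            "undefined_rings": self.undefined_rings,
            "outer_radius_px": self.outer_radius_px,
            "mm_per_pixel": self.mm_per_pixel,
            "config": self.config,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV: one row per ring, the outside-rings bucket, whole cornea."""
        lines = ["region,total_px,tbpa_px,mortality_annulus_pct,mortality_cumulative_pct"]
        for k in range(self.n_rings):
            ma = self.mortality_annulus[k]
            mc = self.mortality_cumulative[k]
            lines.append(
                f"ring{k + 1},{int(self.ring_total_px[k])},{int(self.ring_tbpa_px[k])},"
                f"{'' if np.isnan(ma) else f'{ma:.1f}'},"
                f"{'' if np.isnan(mc) else f'{mc:.1f}'}"
            )
        lines.append(
            f"outside_rings,{int(self.ring_total_px[-1])},{int(self.ring_tbpa_px[-1])},,"
        )
        lines.append(
            f"whole_cornea,{self.whole_cornea_total_px},{self.whole_cornea_tbpa_px},"
            f"{self.whole_cornea_mortality:.1f},{self.whole_cornea_mortality:.1f}"
        )
        Path(path).write_text("\n".join(lines) + "\n")


def ring_mortality(
    tbpa: BinaryMask,
    cornea: CorneaMask,
    part: RingPartition,
    mode: str = "annulus",
) -> ViabilityReport:
    """Compute per-ring and whole-cornea mortality percentages.

    Annulus mode: mortality_k = 100·|TBPA ∩ ring_k| / |cornea ∩ ring_k|.
    Cumulative mode: the region for "ring k" is the whole disc of radius
    r_k.  The whole-cornea figure is always computed over the full mask.
    """
    if mode not in ("annulus", "cumulative"):
        raise ValueError(f"mode must be 'annulus' or 'cumulative', got {mode!r}")
    if tbpa.shape != cornea.shape:
        raise ValueError("tbpa and cornea masks must share dimensions")
    if (tbpa.membership & ~cornea.membership).any():
        raise ValueError("TBPA mask must be a subset of the cornea mask")
    n = part.n_rings
    nbins = n + 2
    total = np.bincount(part.labels[cornea.membership].ravel(), minlength=nbins)
    pos = np.bincount(part.labels[tbpa.membership].ravel(), minlength=nbins)
    ring_total = np.concatenate([total[1 : n + 1], total[n + 1 : n + 2]])
    ring_pos = np.concatenate([pos[1 : n + 1], pos[n + 1 : n + 2]])
    undefined = [k + 1 for k in range(n) if ring_total[k] == 0]

    def pct(p: float, t: float) -> float:
        return float("nan") if t == 0 else 100.0 * p / t

    annulus = [pct(ring_pos[k], ring_total[k]) for k in range(n)]
    cum_pos = np.cumsum(ring_pos[:n])
    cum_total = np.cumsum(ring_total[:n])
    cumulative = [pct(cum_pos[k], cum_total[k]) for k in range(n)]
    whole_total = int(cornea.area)
    whole_pos = int(tbpa.area)
    return ViabilityReport(
        n_rings=n,
        ring_total_px=ring_total,
        ring_tbpa_px=ring_pos,
        mortality_annulus=annulus,
        mortality_cumulative=cumulative,
        whole_cornea_total_px=whole_total,
        whole_cornea_tbpa_px=whole_pos,
        whole_cornea_mortality=pct(whole_pos, whole_total),
        mode=mode,
        undefined_rings=undefined,
        outer_radius_px=part.outer_radius,
        mm_per_pixel=part.mm_per_pixel,
    )


def mortality_identity_check(report: ViabilityReport) -> bool:
    """Exact conservation check of a report's pixel counts.

    Whole-cornea TBPA (and total) counts must equal the sum over the annuli
    plus the outside-rings bucket — an integer identity by construction.
    """
    return int(report.ring_tbpa_px.sum()) == report.whole_cornea_tbpa_px and int(
        report.ring_total_px.sum()
    ) == report.whole_cornea_total_px
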