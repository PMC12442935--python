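"""Seeded generator of synthetic stained-cornea images with exact ground truth.

No public image set accompanies the pan-corneal viability protocol, so the
test battery runs on rendered stand-ins that emulate the acquisition
geometry: a dark surgical background, a bright scleral annulus (the
BSS-filled corneoscleral rim), a roughly circular endothelium disc with
smooth radial shading, and darker trypan-blue-stained regions in the
morphologies seen on real tissue — linear scratches, blobs and peripheral
arcs, some of which were mechanically induced in the original experiments.

Stains are rendered as *exact* binary shapes (each stained pixel is darker
than the local cornea shading by the configured contrast depth, with a
slight blue-channel bias as trypan blue would show); Gaussian noise is added
only afterwards, so the recorded ground-truth masks are exact by
construction.  A fixture optionally solves for a global shape scale so that
the pixel-counted whole-cornea mortality hits a requested target.

These renders capture geometry and contrast, not optics: no chromatic
aberration, no specular highlights beyond a simple glare disc, no cellular
texture.  Passing on them demonstrates algorithmic correctness, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import exposure

from .cornea import CorneaMask
from .raster import BinaryMask, RasterImage
from .rings import ViabilityReport, fit_ring_partition, ring_mortality

__all__ = [
    "StainShape",
    "GlareSpec",
    "FixtureSpec",
    "Fixture",
    "preset_spec",
    "generate_fixture",
    "generate_cohort",
    "emulate_ground_truth_protocol",
    "PRESETS",
]

PRESETS = ("clean", "standard", "hard")


@dataclass(frozen=True)
class StainShape:
    """One stain primitive: kind ``line`` | ``blob`` | ``arc`` plus geometry.

    Geometry values are in pixels / radians relative to the cornea center;
    the solver's global ``scale`` multiplies widths, semi-axes and thickness.
    """

    kind: str
    params: tuple  # kind-specific, see _render_shape


@dataclass(frozen=True)
class GlareSpec:
    row_frac: float
    col_frac: float
    radius: float
    amplitude: float


@dataclass
class FixtureSpec:
    """Parameters of one rendered cornea image.

    Intensity levels are 8-bit; ``vignette_strength`` is the fractional
    intensity drop from cornea center to rim (quadratic profile);
    ``stain_contrast`` is how much darker a stained pixel is than the local
    cornea shading; ``target_mortality`` (fraction of cornea area) triggers
    the shape-scaling solver.
    """

    image_size: int = 384
    cornea_radius: float = 150.0
    axis_ratio: float = 1.0  # col semi-axis = cornea_radius * axis_ratio
    background_level: float = 12.0
    sclera_level: float = 228.0
    sclera_width: float = 26.0
    cornea_level: float = 172.0
    vignette_strength: float = 0.3
    noise_sigma: float = 4.0
    glare: GlareSpec | None = None
    stain_contrast: float = 70.0
    stain_shapes: list[StainShape] | None = None
    target_mortality: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        half = self.image_size / 2
        if self.cornea_radius * max(1.0, self.axis_ratio) + self.sclera_width + 4 > half:
            raise ValueError("cornea plus scleral rim must fit inside the image")
        if self.target_mortality is not None and not 0 <= self.target_mortality <= 0.6:
            raise ValueError("target_mortality must lie in [0, 0.6]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class Fixture:
    """A rendered image with its exact ground truth."""

    image: RasterImage
    cornea_truth: CorneaMask
    tbpa_truth: BinaryMask
    true_ring_mortalities: np.ndarray  # rings 1..5 (annulus %) + whole-cornea %
    true_report: ViabilityReport
    spec: FixtureSpec


# ---------------------------------------------------------------------------
# geometry helpers


def _grids(size: int, cr: float, cc: float) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(size, dtype=np.float64)[:, None] - cr
    cols = np.arange(size, dtype=np.float64)[None, :] - cc
    return np.broadcast_to(rows, (size, size)), np.broadcast_to(cols, (size, size))


def _elliptic_radius(dr, dc, rr, rc):
    return np.sqrt((dr / rr) ** 2 + (dc / rc) ** 2)


def _render_shape(shape: StainShape, dr, dc, scale: float) -> np.ndarray:
    """Rasterize one stain primitive as a boolean mask (cornea clip later)."""
    if shape.kind == "line":
        theta, offset, width, length, t0 = shape.params
        n_r, n_c = np.cos(theta), np.sin(theta)  # unit normal
        d_r, d_c = -n_c, n_r  # unit direction
        perp = dr * n_r + dc * n_c - offset
        along = dr * d_r + dc * d_c - t0
        return (np.abs(perp) <= width * scale / 2) & (np.abs(along) <= length / 2)
    if shape.kind == "blob":
        row0, col0, a, b, psi = shape.params
        xr = dr - row0
        xc = dc - col0
        u = xr * np.cos(psi) + xc * np.sin(psi)
        v = -xr * np.sin(psi) + xc * np.cos(psi)
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0
    if shape.kind == "arc":
        rho, thickness, phi0, span = shape.params
        r = np.hypot(dr, dc)
        ang = np.arctan2(dc, dr)
        dphi = np.angle(np.exp(1j * (ang - phi0)))
        radial = np.abs(r - rho) <= thickness * scale / 2
        return radial & (np.abs(dphi) <= span / 2)
    raise ValueError(f"unknown stain kind {shape.kind!r}")


def _sample_shapes(rng: np.random.Generator, n: int, radius: float) -> list[StainShape]:
    """Draw n stain primitives with stratified orientations for spatial spread."""
    kinds = ["line", "blob", "arc"]
    shapes: list[StainShape] = []
    for i in range(n):
        kind = kinds[i % 3]
        base_angle = 2 * np.pi * i / max(n, 1) + rng.uniform(-0.3, 0.3)
        if kind == "line":
            shapes.append(
                StainShape(
                    "line",
                    (
                        base_angle,
                        rng.uniform(-0.6, 0.6) * radius,
                        rng.uniform(6, 14),
                        rng.uniform(0.9, 2.0) * radius,
                        rng.uniform(-0.3, 0.3) * radius,
                    ),
                )
            )
        elif kind == "blob":
            rho = rng.uniform(0.0, 0.78) * radius
            shapes.append(
                StainShape(
                    "blob",
                    (
                        rho * np.cos(base_angle),
                        rho * np.sin(base_angle),
                        rng.uniform(9, 20),
                        rng.uniform(9, 20),
                        rng.uniform(0, np.pi),
                    ),
                )
            )
        else:
            shapes.append(
                StainShape(
                    "arc",
                    (
                        rng.uniform(0.55, 0.88) * radius,
                        rng.uniform(8, 14),
                        base_angle,
                        rng.uniform(0.5, 1.8),
                    ),
                )
            )
    return shapes


def _stain_union(shapes, dr, dc, scale, cornea):
    out = np.zeros(cornea.shape, bool)
    for s in shapes:
        out |= _render_shape(s, dr, dc, scale)
    return out & cornea


def _solve_scale(shapes, dr, dc, cornea, target, tol_pp=0.25, max_iter=40):
    """Bisect the global shape scale to hit the target mortality fraction."""
    area = cornea.sum()
    lo, hi = 0.02, 3.0

    def mortality(s):
        return _stain_union(shapes, dr, dc, s, cornea).sum() / area

    if mortality(hi) < target:
        return None  # caller adds shapes
    best_s, best_err = hi, abs(mortality(hi) - target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = mortality(mid)
        err = abs(m - target)
        if err < best_err:
            best_s, best_err = mid, err
        if err * 100 <= tol_pp:
            return mid
        if m < target:
            lo = mid
        else:
            hi = mid
    return best_s


# ---------------------------------------------------------------------------
# main entry points


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Render one fixture deterministically from its spec and seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = (size - 1) / 2
    # small center jitter so nothing aligns exactly with the pixel grid
    cr = center + rng.uniform(-2, 2)
    cc = center + rng.uniform(-2, 2)
    rr = spec.cornea_radius
    rc = spec.cornea_radius * spec.axis_ratio
    dr, dc = _grids(size, cr, cc)
    e = _elliptic_radius(dr, dc, rr, rc)
    cornea = e <= 1.0
    # the bright scleral rim directly abuts the endothelium disc
    sclera = (e > 1.0) & (
        _elliptic_radius(dr, dc, rr + spec.sclera_width, rc + spec.sclera_width) <= 1.0
    )

    # base shading (background, sclera, vignetted cornea), softly blurred
    base = np.full((size, size), spec.background_level, dtype=np.float64)
    base[sclera] = spec.sclera_level
    vign = spec.cornea_level * (1.0 - spec.vignette_strength * np.clip(e, 0, 1) ** 2)
    base[cornea] = vign[cornea]
    base = ndimage.gaussian_filter(base, sigma=1.5)
    if spec.glare is not None:
        g = spec.glare
        gr = cr + g.row_frac * rr
        gc = cc + g.col_frac * rc
        gdist = np.hypot(dr - (gr - cr), dc - (gc - cc))
        base = base + g.amplitude * np.exp(-0.5 * (gdist / g.radius) ** 2)

    # stains
    if spec.target_mortality is not None and spec.target_mortality > 0:
        target = spec.target_mortality
        n = max(1, int(round(target * cornea.sum() / 2500)))
        shapes = _sample_shapes(rng, n, min(rr, rc))
        scale = _solve_scale(shapes, dr, dc, cornea, target)
        for _ in range(8):
            if scale is not None:
                break
            shapes = shapes + _sample_shapes(rng, max(1, n // 2), min(rr, rc))
            scale = _solve_scale(shapes, dr, dc, cornea, target)
        if scale is None:
            raise ValueError(
                f"cannot reach target mortality {target:.3f} with sampled shapes"
            )
        stain = _stain_union(shapes, dr, dc, scale, cornea)
        achieved = stain.sum() / cornea.sum()
        if abs(achieved - target) > 0.005:
            raise ValueError(
                f"shape solver missed target mortality: {achieved:.4f} vs {target:.4f}"
            )
    elif spec.stain_shapes:
        stain = _stain_union(spec.stain_shapes, dr, dc, 1.0, cornea)
    elif spec.target_mortality is None:
        stain = np.zeros((size, size), bool)
    else:
        stain = np.zeros((size, size), bool)

    # compose RGB: stains darker, with weaker attenuation in blue (TB is blue)
    rgb = np.stack([base, base, base * 0.995], axis=-1)
    depth = np.array([1.0, 1.0, 0.6]) * spec.stain_contrast
    rgb[stain] = rgb[stain] - depth
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0, spec.noise_sigma, rgb.shape)
    img = RasterImage(np.clip(np.round(rgb), 0, 255).astype(np.uint8))

    cornea_mask = CorneaMask(cornea, provenance="truth")
    tbpa_mask = BinaryMask(stain)
    part = fit_ring_partition(cornea_mask)
    report = ring_mortality(tbpa_mask, cornea_mask, part)
    true_vals = np.array(report.mortality_annulus + [report.whole_cornea_mortality])
    return Fixture(
        image=img,
        cornea_truth=cornea_mask,
        tbpa_truth=tbpa_mask,
        true_ring_mortalities=true_vals,
        true_report=report,
        spec=spec,
    )


def preset_spec(
    name: str,
    seed: int = 0,
    target_mortality: float | None = None,
    **overrides,
) -> FixtureSpec:
    """Named difficulty presets.

    ``clean``: no noise, no glare — isolates algorithmic behaviour.
    ``standard``: Gaussian noise σ=4/255 and vignetting — routine acquisition.
    ``hard``: compressed contrast (triggers CLAHE) plus a glare disc and noise.
    """
    if name == "clean":
        kw = dict(noise_sigma=0.0, glare=None)
    elif name == "standard":
        kw = dict(noise_sigma=4.0, glare=None)
    elif name == "hard":
        kw = dict(
            noise_sigma=4.0,
            cornea_level=140.0,
            vignette_strength=0.08,
            stain_contrast=28.0,
            glare=GlareSpec(row_frac=-0.35, col_frac=0.3, radius=20.0, amplitude=45.0),
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    kw.update(overrides)
    return FixtureSpec(seed=seed, target_mortality=target_mortality, **kw)


def generate_cohort(
    n_tissues: int,
    seed: int = 0,
    preset: str = "standard",
    mortality_beta: tuple[float, float] = (2.0, 8.0),
    mortality_scale: float = 0.5,
) -> list[Fixture]:
    """Generate a cohort of fixtures with varied morphology and mortality.

    Per-tissue sub-seeds derive deterministically from the master seed; the
    planted whole-cornea mortalities are Beta(a, b)·scale draws (default
    mean 10%, right-skewed, echoing the spread reported for donor tissue).
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(n_tissues)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    a, b = mortality_beta
    fixtures = []
    for i in range(n_tissues):
        target = float(rng.beta(a, b) * mortality_scale) if mortality_scale > 0 else 0.0
        ratio = float(rng.uniform(0.94, 1.0))
        spec = preset_spec(
            preset, seed=child_seeds[i], target_mortality=target, axis_ratio=ratio
        )
        fixtures.append(generate_fixture(spec))
    return fixtures


def emulate_ground_truth_protocol(
    fixture: Fixture, manual_threshold: int
) -> BinaryMask:
    """Semiautomated-style reference segmentation of a fixture.

    Mirrors the manual reference workflow: take the green channel, apply
    CLAHE (block 127 px, 256 histogram bins, clip corresponding to a maximum
    slope of 3), then keep cornea pixels whose *darkness* (255 − value)
    reaches ``manual_threshold``.  The CLAHE output is mapped to 1..255 so
    the two degenerate thresholds behave as expected: 0 keeps the whole
    cornea region, 255 keeps nothing.
    """
    if fixture.image.channels != 3:
        raise ValueError("ground-truth protocol emulation needs an RGB fixture")
    if not 0 <= manual_threshold <= 255:
        raise ValueError("manual_threshold must lie in [0, 255]")
    green = fixture.image.pixels[:, :, 1]
    eq = exposure.equalize_adapthist(
        green, kernel_size=127, clip_limit=3.0 / 256.0, nbins=256
    )
    val = np.clip(np.round(eq * 254) + 1, 1, 255).astype(np.uint8)
    darkness = 255 - val.astype(np.int32)
    return BinaryMask((darkness >= manual_threshold) & fixture.cornea_truth.membership)


# ---------------------------------------------------------------------------
# disk output (used by the CLI `simulate` command)


def write_fixture(fix: Fixture, out_dir: str | Path, stem: str = "fixture") -> dict:
    from .raster import write_image, write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(fix.image, out / f"{stem}_image.png")
    write_mask(fix.cornea_truth, out / f"{stem}_cornea_truth.png")
    write_mask(fix.tbpa_truth, out / f"{stem}_tbpa_truth.png")
    fix.true_report.to_json(out / f"{stem}_truth.json")
    return {
        "stem": stem,
        "image": f"{stem}_image.png",
        "cornea_truth": f"{stem}_cornea_truth.png",
        "tbpa_truth": f"{stem}_tbpa_truth.png",
        "true_whole_mortality_pct": fix.true_report.whole_cornea_mortality,
        "seed": fix.spec.seed,
    }
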