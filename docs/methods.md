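# Methods

`endovia` estimates pan-corneal endothelial mortality of donor corneas from
photographs of the trypan-blue-stained endothelium. Trypan blue is a vital
dye: it stains the nuclei of dead or severely damaged endothelial cells and
areas of Descemet membrane denuded of cells, so the fraction of the
endothelial surface that is trypan-blue positive (TBPA) is a direct,
pan-corneal readout of endothelial mortality — complementary to endothelial
cell density (ECD), which samples only small central fields. The package
implements the image-analysis side of that assessment: cornea segmentation,
TBPA segmentation, concentric-ring viability reporting, the validation
statistics, and a seeded synthetic-image generator that supplies exact
ground truth for testing.

## Pipeline model and assumptions

The analysis assumes the standard acquisition geometry: the corneoscleral
button photographed face-up under a surgical microscope, endothelium toward
the camera, the whole Schwalbe line inside the frame, BSS filling the rim.
Under those conditions the image contains a dark background, a bright
scleral annulus, and a roughly circular endothelium disc on which stains
appear *darker* than healthy tissue (configurable polarity for inverted
acquisitions).

**1 — Cornea mask.** Production use assumes a promptable segmenter (the
user clicks include/exclude points). `endovia` deliberately does not bundle
or re-implement such a model: the backend is a plugin — any callable
`(image, prompts) → mask` — and a classical, weight-free fallback is
provided (three-class Otsu separating background / endothelium / sclera,
morphological closing, largest component, hole fill). Every mask from any
source is normalised to the same invariants: exactly one 8-connected
component, no 4-connected interior holes, non-empty. The fallback assumes
the bright scleral rim is present; on images without a rim it will degrade,
which is one reason the promptable path is the primary interface.

**2 — TBPA segmentation** (marker-controlled watershed chain):

1. Luma conversion (Rec.601), CLAHE *only* when the interquartile range of
   intensities inside the cornea is below `clahe_trigger` (default 20/255 —
   an insufficient-contrast image), then a small Gaussian blur. All stage
   boundaries are uint8, so the chain is bit-deterministic.
2. Local-mean adaptive thresholding: a pixel is a candidate when darker
   than the mean of its window by more than `adaptive_offset` (default 5).
   The comparison is done entirely in integer arithmetic (integral-image
   window sums of a symmetrically padded image), so it is exactly
   reproducible and provably identical to a naive sliding-window
   evaluation. Three robustness measures around this rule matter in
   practice and are our own engineering (the published description of each
   step is parameter-free):
   * *Edge margin.* Light bleeding from the bright sclera contaminates the
     outermost cornea pixels; the dark side of that gradient would be
     flagged as stain. Candidates are therefore searched inside the cornea
     eroded by `edge_margin` (default 5 px); the final mask is still
     clipped to the full cornea, and watershed growth reclaims genuine
     stains touching the rim.
   * *Extrapolation fill.* Windows straddling the rim must not see
     background or sclera. A constant or mirrored fill turns the radial
     vignette ramp into a profile whose minimum lies on the rim, biasing
     the local mean upward for every near-rim pixel (measured as a ~5 pp
     false-positive ring on stain-free renders). Outside-region pixels are
     instead filled by linear extrapolation across the nearest boundary
     point, which continues the shading ramp and keeps the mean unbiased.
   * *Two window scales.* The core of a stained area wider than the window
     is invisible to a local-mean rule (its local mean *is* the stain).
     Candidates are the union of a fine window (default 51 px, resolves
     scratches and edges) and a coarse window (default 151 px, flags wide
     stain cores); either scale can be disabled. A final intensity-gated
     hole fill reclaims enclosed cores while refusing healthy tissue
     encircled by thin distinct stains.
   Morphological opening (3 px ellipse, 2 iterations) then removes
   sub-kernel specks.
3. Exact Euclidean distance transform of the candidate mask.
4. Seed threshold: pixels with distance ≥ τ·max (τ = `seed_fraction`,
   default 0.2, against the global maximum; a per-component variant is
   available for images mixing thin and bulky stains). Seeds shrink
   monotonically as τ grows.
5. Marker-controlled watershed on the Sobel gradient magnitude of the
   preprocessed image (the flooding surface is configurable: gradient, raw
   gray, or inverted distance). Markers: each seed component gets its own
   label; everything outside the cornea is one reserved background label
   (suppressing edge artifacts); cornea tissue away from the dilated
   candidate zone is a second reserved label; the remaining "unknown"
   margin (dilated candidates minus seeds) is flooded. No watershed lines
   are kept: ridge pixels are assigned to an adjacent region, so the output
   is a total labelling.
6. Region filter: keep watershed regions with area ≥ `min_region_area`
   (default 25 px) and at least half their area inside the cornea; their
   union clipped to the cornea is the final TBPA mask. By construction
   TBPA ⊆ cornea, and reruns are bit-identical.

**3 — Ring viability.** The cornea centroid comes from the binary image
moments; the outer radius R is the least-squares estimate given by the mean
Euclidean distance from the centroid to every outer-contour pixel; ring
radii are k/5·R (the nominal 2/4/6/8/10-mm rings; the nominal physical
scale 10 mm / R is used only for labelling and Hausdorff reporting, never
for pixel arithmetic). Ring membership uses half-open annuli [r_{k−1}, r_k)
on sub-pixel distances. Because R is a fit and corneas are not perfectly
circular, cornea pixels can lie beyond r_5; they are tracked in an explicit
outside-rings bucket so ring pixel counts always sum *exactly* to
whole-cornea counts (`mortality_identity_check` asserts this integer
identity). Since "ring k" can be read as an annulus or as the enclosing
disc, both readings are always computed and serialised; the annulus reading
is the default report. Rings with no cornea pixels report NaN and are
flagged, never silently zero.

## Validation statistics

* Overlap metrics from confusion counts over an evaluation region
  (precision, recall, balanced accuracy = mean of stained and non-stained
  recall, Dice, IoU); zero denominators yield explicit "undefined" flags.
* Standard and modified (Dubuisson–Jain) Hausdorff distances between
  *boundary* point sets — interiors would understate shape disagreement —
  reported in px, image-diagonal units and mm when a scale is known.
* Continuous agreement: MAE, RMSE, R² (reference-based; undefined for a
  constant reference), with seeded percentile-bootstrap 95% CIs (default
  1000 resamples; pairs are resampled jointly).
* Bland–Altman: differences oriented as automated-estimate minus reference,
  LoA = mean ± 1.96·sample SD, CI ribbons via SE(mean) = SD/√n and
  SE(LoA) = SD·√(3/n). Pearson correlation with the two-sided t-test.
* Rotation homoscedasticity: mortalities per ring are z-scored against the
  grand mean/SD pooled over all tissues and rotations of that ring (the
  pooling is our choice; other poolings are defensible), then classic
  mean-centered Levene's test across the rotation groups
  (`center="median"` gives Brown–Forsythe). Identical groups return
  W = 0, p = 1 rather than a 0/0.

## Synthetic fixtures: what they emulate and what they do not

The generator renders the acquisition geometry — dark background, bright
scleral annulus directly abutting the endothelium disc, quadratic radial
vignetting (default 30% center-to-rim), optional Gaussian glare — and
plants stains in the morphologies seen on damaged tissue: linear scratches,
blobs, peripheral arcs. Stains are binary shapes darkening the local base
shading by `stain_contrast` (default 70/255) with a weaker drop in the blue
channel (trypan blue transmits blue); Gaussian pixel noise is added *after*
shape rendering, so the stored truth masks are exact. A bisection solver
scales shape geometry so the pixel-counted whole-cornea mortality hits a
requested target within 0.5 pp; cohort targets are Beta(2,8)·0.5 draws
(mean ≈ 10%, right-skewed, echoing the spread reported for unsuitable
donor tissue), with per-tissue sub-seeds derived from one master seed.

Three presets ladder the difficulty: `clean` (no noise, no glare),
`standard` (noise σ = 4/255 + vignette), `hard` (compressed contrast that
triggers CLAHE, plus glare and noise). The default cohort size is 19
tissues, matching the scale of a realistic validation batch.

These renders capture geometry and contrast only. They contain no cellular
texture, no chromatic aberration, no specular reflexes beyond the glare
disc, no focus gradients, and their stain boundaries are hard. Passing the
synthetic battery therefore demonstrates algorithmic correctness —
determinism, conservation identities, rotation invariance, recovery of
known planted mortality under the modelled degradations — not clinical
performance on real microscope images.

A separate emulator reproduces the semiautomated reference workflow used
for ground-truth comparison on real images (green channel → CLAHE with
block 127 px / 256 bins / clip 3/256, approximating an ImageJ maximum
slope of 3 → manual global threshold). Its CLAHE output is mapped to
1..255 so threshold 0 keeps the whole region and threshold 255 keeps
nothing.

## Numerical choices and degenerate inputs

* Grayscale: Rec.601 weights, rounded half-up to uint8; 16-bit input is
  rescaled to the 8-bit lattice before thresholding.
* Rotations are restricted to right angles and are exact permutations;
  arbitrary-angle rotation is refused rather than interpolated.
* Connectivity: 8-connected components, 4-connected holes.
* Watershed determinism comes from skimage's ordered flooding; its flood
  order is not exactly rotation-symmetric along ridges, so rotating a
  square image can move individual ridge pixels (measured ≤ 0.1% of
  pixels); mortality percentages agree across rotations to ≤ 0.03 pp on
  the standard preset.
* Empty candidate masks, empty seed sets and stain-free images flow
  through as "no TBPA, 0% mortality", not as errors; an empty *cornea*
  mask is an error everywhere.
* Bootstrap CIs are percentile (not BCa): at n = 50 the 95% CI for a mean
  covers the truth ≈ 93–95% of the time, which the acceptance battery
  checks explicitly.

## Problem sizes in the test battery

The synthetic battery runs at 384×384 px with a 150 px cornea radius — a
scale at which every geometric effect the pipeline must handle (vignette,
limbal bleed, window-size interactions) is present while the full suite
executes in well under a minute per harness: 20 clean fixtures spanning
0–40% planted mortality for recovery, a 19-tissue standard cohort × 4
rotations for the homoscedasticity design, and 500 Monte-Carlo repetitions
for bootstrap coverage.

## Known limitations

* The classical cornea fallback requires the bright-rim geometry; detached
  or decentred rims need the promptable path or a precomputed mask.
* The stain/healthy decision is intensity-based; pigment, dense folds or
  deep shadows darker than `adaptive_offset` below their surroundings will
  be flagged. The region-area and cornea-majority filters remove small
  such artifacts only.
* The nominal mm scale assumes the fitted outer ring is the 10-mm ring;
  absolute mm figures inherit that assumption.
* Cell-level analysis (ECD estimation, cell counting) is out of scope by
  design; the output is area-fraction mortality.
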