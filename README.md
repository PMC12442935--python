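# endovia

Pan-corneal endothelial viability estimation from trypan-blue-stained
donor-cornea images.

Eye banks and corneal surgeons need to know how much of a donor cornea's
endothelium is alive before transplanting it. Endothelial cell density
(ECD) samples only small central fields; staining the endothelium with
trypan blue (TB) instead marks every dead cell and every denuded patch of
Descemet membrane across the whole cornea, so the **stained-area fraction
is a direct pan-corneal mortality estimate**. `endovia` turns a surgical
microscope photograph of a TB-stained cornea into that estimate:

1. **Cornea segmentation** — via a pluggable promptable-segmenter backend
   (click points, get a mask) or a classical weight-free fallback;
2. **TBPA segmentation** — trypan-blue-positive areas found by adaptive
   local-mean thresholding, distance-transform seeding and
   marker-controlled watershed refinement;
3. **Ring viability** — the cornea is split into five concentric rings
   (nominally 2–10 mm): centroid from image moments, outer radius R as the
   least-squares mean distance to the cornea contour, ring radii k/5·R;
   per-ring and whole-cornea mortality are reported as

   mortality = 100 · |TBPA ∩ region| / |cornea ∩ region| (%).

It also ships the full validation battery used to qualify such a pipeline
(Dice/IoU/precision/recall/balanced accuracy, standard and modified
Hausdorff distances, MAE/RMSE/R² with bootstrap CIs, Bland–Altman limits
of agreement, Pearson correlation, per-ring Levene tests of
rotation-invariance) and a seeded synthetic-image generator with exact
ground truth, so everything is testable with no external data.

## Worked example

Generate one synthetic stained cornea with a planted mortality of 15% and
analyze it fully automatically:

```sh
$ endovia simulate --out demo/fixtures --n 1 --preset standard --seed 7 \
      --target-mortality 0.15
wrote 1 fixtures to demo/fixtures

$ endovia analyze demo/fixtures/tissue000_image.png --auto --out demo/report
whole-cornea mortality: 15.0%
  ring 1: 95.2%
  ring 2: 38.0%
  ring 3: 17.8%
  ring 4: 9.0%
  ring 5: 1.7%
```

The planted whole-cornea truth for this fixture is 15.0%, and the
automatic estimate recovers it. The per-ring numbers are the stained
percentage of each annulus: this particular tissue carries a central lesion
(ring 1 almost fully stained — 95.2%) with damage tapering toward the
periphery (ring 5 nearly clear at 1.7%) — the spatial detail a single
whole-cornea number hides. `demo/report/` also receives `report.json`
(full precision, config hash), `report.csv`, the cornea and TBPA masks as
PNGs, and an `overlay.png` with ring circles and stain contours drawn over
the photograph.

Other commands: `endovia rotcheck` (re-analyzes images at 90°/180°/270°
and runs per-ring Levene tests of estimate stability), `endovia validate`
(mask-vs-mask agreement metrics, optionally restricted to the central
ring), `endovia compare` (Bland–Altman + Pearson between two methods'
mortality tables), `endovia simulate` (fixture generation). The same
functionality is importable (`endovia.segment_tbpa`,
`endovia.ring_mortality`, `endovia.metrics`, `endovia.synthetic`, …).

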