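# odcircle

Contrast-based circular optic disc localization and segmentation for
retinal fundus photographs.

The optic disc (OD) — the entry point of the optic nerve and retinal
vessels — appears in fundus images as a bright, roughly circular region
with dark vessels converging on its center. Locating and delineating it is
a core step in retinal image analysis (glaucoma assessment, fovea
localization, vessel tracking). `odcircle` implements a fully classical
pipeline:

1. **Normalization.** The circular field of view (FOV) is detected and the
   image is rescaled with cubic interpolation so the retina diameter equals
   540 px, making every kernel size below resolution-independent.
2. **Vessel evidence.** Vessels are enhanced as
   `V_E = tophat_8(255 − G)` (white top-hat of the complemented green
   channel, disc structuring element of radius 8). Two maps are derived and
   max-normalized: vessel *density* `V_D = Av_{80×40}(V_E) − Av_{80×120}(V_E)`
   and vessel *convergence* `V_C`, the radius-40 circular mean of the count
   of pairwise intersections of Hough lines fitted to the Canny edges of
   `V_E`. Thresholding both at 0.3 and taking their logical AND yields a
   constraint mask `V_DC^b` pointing at the vessel-dense convergence zone.
3. **Localization.** The intensity image `I = R + G + B` is compensated for
   dark vessels (pixels with `V_E` above its 98.5th FOV percentile are set
   to `max I`), then filtered by the disc detector
   `D_OD = Av_{r=40}(I_c) − Av_{80×160}(I_c)`. The argmax of `D_OD` inside
   `V_DC^b` is the estimated OD center.
4. **Segmentation.** A 160-px window is cropped around the estimate. For
   radii `r` on a grid from 25% to 45% of the window side (1% steps) the
   ring contrast `CM(r) = mean I(inner ring) − mean I(outer ring)` is
   evaluated (ring thickness 4% of the side). Four half-plane sectors
   (up/down/left/right) are scanned independently; the final circle center
   is the window center shifted by half the sector-radius differences and
   the radius is the mean of the four sector radii. The window is
   re-centered on the refined estimate and the fit repeated (up to three
   passes) until stable.

Evaluation metrics (normalized center error `D* = |c_exp − c_real| / R`
with `R` the area-equivalent ground-truth radius, success = center inside
the true mask, Jaccard `JC`, Dice `DC = 2JC/(1+JC)`, symmetric mean
boundary distance `MAD`) and a seedable synthetic fundus generator with
exact ground truth round out the package, so the whole pipeline is testable
without external image databases.

## Worked example

Generate a synthetic fundus image and run the pipeline from the shell:

```bash
odcircle synth --n 1 --seed 7 --out demo/
odcircle locate demo/image_000.png
odcircle segment demo/image_000.png --json seg.json
odcircle evaluate --pred seg.json --truth demo/truth_000.png
```

For the seed-7 image (true disc center (341.5, 411.9), radius 61.6 px) this
prints, in order:

```json
{
  "center_col": 412.88, "center_row": 364.49,
  "center_col_normalized": 401, "center_row_normalized": 354,
  "constrained": true, "scale": 0.9712
}
{
  "center_col": 411.85, "center_row": 343.07, "radius": 61.37,
  "sector_radii": {"down": 59.2, "left": 59.2, "right": 59.2, "up": 60.8},
  "window_side": 160
}
{
  "d_star": 0.0263, "dc": 0.9832, "jc": 0.9670,
  "mad": 1.0215, "success": true
}
```

Reading: the brightness detector landed 23 px below the disc center
(`constrained: true` — the vessel mask was used; `D* = 0.026` after the
segmentation refinement), and the fitted circle overlaps the true disc with
Jaccard 0.967 and a mean boundary distance of 1.0 px. All coordinates are
0-based (row, col) in the original image frame; `*_normalized` values are
in the 540-px-retina frame.

`odcircle batch <dir> --truth-dir <dir> --csv rows.csv --json summary.json`
processes a directory (truth masks paired by file stem) and reports
per-image rows plus the aggregate means, success rate and the fraction of
images with `JC ≥ t` for `t ∈ {0.95, 0.90, 0.85, 0.80, 0.75, 0.70}`.

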