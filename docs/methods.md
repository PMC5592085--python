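# Methods

## Appearance model and assumptions

The pipeline assumes the optic disc (OD) is (i) the brightest roughly
circular region of its local neighborhood in the summed-channel intensity
image, and (ii) the convergence point of the retinal vessel tree. Both
assumptions fail gracefully rather than catastrophically: localization
falls back to the FOV-wide brightness argmax when the vessel constraint
mask is empty, and segmentation only needs the estimated center to lie
somewhere inside the disc.

All processing happens in a normalized frame in which the retina (FOV)
diameter is 540 px, so the kernel sizes below are fixed lengths rather
than image-relative fractions. Images from a different capture angle than
the usual 45° field would need the parameters revisited.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `retina_diameter` | 540 px | target FOV diameter after cubic rescaling |
| `tophat_radius` | 8 px | disc structuring element of the vessel top-hat; vessels are thinner, the disc and background are wider |
| `density_kernel_narrow` / `wide` | 80×40 / 80×120 (rows×cols) | vessel-density difference-of-box-means; the differing dimension is horizontal because the vessel bundle at the disc is vertically elongated and its horizontal flanks are vessel-poor |
| `density_threshold`, `convergence_threshold` | 0.3 | binarization of the max-normalized maps (strict `>`) |
| `convergence_avg_radius` | 40 px | circular smoothing of the intersection counts |
| `hough_top_k` | 30 | retained Hough line peaks (≤ 435 candidate intersections) |
| `hough_min_distance`, `hough_min_angle_deg` | 5 px, 5° | minimum accumulator peak separation |
| `hough_peak_floor` | 0.2 | peaks below this fraction of the accumulator maximum are dropped (see below) |
| `intersection_min_angle_deg` | 3° | line pairs closer to parallel are skipped as numerically unstable |
| `canny_sigma` | 1.0 | Gaussian scale of the edge detector |
| `canny_low_pct`, `canny_high_pct` | 70, 90 | hysteresis thresholds as percentiles of the gradient magnitude **inside the FOV**; percentile form keeps the detector robust to resolution and contrast changes |
| `vessel_percentile` | 98.5 | enhancement percentile above which intensity pixels are painted to the FOV maximum before disc detection |
| `detector_circle_radius`, `detector_rect` | 40 px, 80×160 | disc detector difference of means; the wide rectangle samples the horizontally flanking retina |
| `crop_side` | 160 px | segmentation window in the normalized frame |
| `radius_grid_min/max/step` | 0.25 / 0.45 / 0.01 | scanned radii as fractions of the window side (41.6–72 px) |
| `ring_thickness_frac` | 0.04 | ring thickness (6.4 px at side 160) |
| `refine_passes` | 3 | crop-and-fit passes of the flexible circle fit |

### Why crop side 160

The scanned radius grid spans 25–45% of the window side. The synthetic
battery places disc radii at 8–12% of the FOV diameter, i.e. 43.2–64.8 px
in the normalized frame; a side of 160 px puts that whole population
inside the grid (40–72 px) with headroom for center-offset compensation. A
smaller window (e.g. 140 px, grid cap 63 px) cannot represent the largest
discs even under perfect localization.

### Why a Hough peak floor instead of the half-max default

Straight-line Hough peak pickers conventionally discard peaks below half
the accumulator maximum. Curved vessel edges spread their votes over many
(angle, distance) cells, so on realistic images the genuinely useful peaks
sit far below half-max and the default yields only one or two lines — and
no intersections at all. Conversely, with no floor, an image containing a
single straight structure sprouts spurious low-vote lines whose chance
intersections fabricate convergence evidence. A floor of 20% of the
maximum keeps top-30 behavior on vessel images while an isolated straight
edge still contributes only its true (mutually parallel) lines.

### Why the flexible fit iterates

Each half-plane sector ring integrates the disc boundary over its whole
semicircular arc. For a disc whose center is offset by δ from the window
center, the sector-radius difference responds with roughly half of 2δ
rather than 2δ, so a single pass corrects only about half the offset
(measured response ≈ 0.56 per axis on ideal discs). Scaling the shift up
analytically (the thin-ring arc average predicts a 2/π response, i.e. a
π/4-scaled difference) overcorrects in practice because the response
factor varies with offset, radius and noise. Re-cropping the window at the
refined center and repeating the fit sidesteps the calibration entirely:
the iteration converges to the center at which the four sector radii are
symmetric, within the radius-grid resolution, in two to three passes. The
loop stops as soon as the rounded center is stable.

## Numerical choices

* **Border handling.** All box and circular means use reflect
  (symmetric) padding, so the FOV rim does not generate spurious detector
  maxima. Even kernel extents `k` span offsets `-(k//2) .. k//2-1`.
* **Circular means** are computed exactly (per-row run sums on a padded
  integral image), not by FFT, and match a brute-force windowed sum to
  1e-9 in the tests.
* **Clipping.** Negative values of both difference-of-means maps are
  clipped to zero before normalization: only an *excess* of
  density/brightness is evidence.
* **Normalization guard.** An identically zero map stays zero (0/0 → 0)
  instead of raising.
* **Thresholds are strict** (`value > t`), so a map whose maximum equals
  the threshold produces an empty mask.
* **Argmax ties** in localization are broken by smallest row, then
  smallest column; radius-scan ties by smallest radius. Both make the
  pipeline bit-deterministic.
* **Empty constraint mask.** The localization falls back to the FOV-wide
  argmax and flags the result `constrained=false`; a center is always
  produced for the segmentation stage.
* **Degenerate inputs.** An all-dark frame or a bright region covering
  less than 10% of the frame raises `FOVNotFoundError` (CLI exit code 3);
  empty masks and empty boundaries are errors in the metrics rather than
  silent zeros.
* **Coordinates** are 0-based (row, col) everywhere; circles are reported
  in original-image pixels, with the normalized-frame values alongside.

## The synthetic generator

`odcircle.synthetic` renders the cues the method relies on, with exact
geometry: a circular FOV on a dark surround; a reddish background with a
multiplicative illumination ramp in a random direction; a bright yellowish
disc with a sigmoidal rim; quadratic-spline vessels from the FOV rim to
within 0.2 disc radii of the disc center, darker in the green channel;
optional bright exudate blobs at ≥ 2 disc radii from the disc; additive
Gaussian sensor noise. The ground truth is the exact rasterized disc
before noise. The default battery randomizes FOV radius (240–300 px frame
scale, so the rescaling stage is genuinely exercised), disc position in
the nasal half of the FOV, disc radius (8–12% of the FOV diameter, the
scale regime the radius-40 detector kernel targets), 6–12 vessels, noise
σ 4–8 gray levels, illumination gradient up to 25% and 0–2 exudates; the
PCG64 generator makes every image reproducible from one master seed.

What the generator does **not** emulate: peripapillary atrophy, choroidal
vessels, haemorrhages, camera color characteristics, non-circular disc
shapes, and low-contrast pathology. Consequently the synthetic battery
scores (e.g. mean Jaccard ≈ 0.98) are an upper bound driven by the truth
being exactly circular; they demonstrate correctness of the machinery and
graceful degradation under noise, not clinical-grade accuracy. On real
photographs, overlap scores are expected to be materially lower, with
failures concentrated in low-contrast and atrophic cases.

A known behavior worth noting: for discs noticeably larger than the
40-px detector kernel, the brightness detector's response plateaus and its
argmax tends to sit on a ring about `disc_radius − 40` px from the true
center rather than at the center itself (mean normalized center error
≈ 0.23 on the battery). The localization success criterion (center inside
the disc) is unaffected, and the iterative segmentation fit re-centers
almost completely, but center-sensitive downstream uses should prefer the
fitted circle's center over the raw detector argmax.

## Problem sizes

The test suite and the acceptance script use a 50-image battery for the
end-to-end properties, 50 windows for parameter recovery, 20 images per
noise level for the degradation sweep and ≥ 20 small random rasters per
brute-force oracle; these sizes give stable aggregate statistics for a
desk-scale run while keeping a full suite execution in single-digit
minutes.
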