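# Methods

## Problem and model

A paper ECG is a physical plot: voltage is printed at a gain of
10 mm/mV and time advances at a paper speed of 25 mm/s, over graph
paper ruled with 1 mm fine and 5 mm coarse squares. Digitizing a scan
therefore reduces to three measurements:

1. **Geometry calibration.** The only length of known physical size in
   the image is the grid. If a coarse square spans *L* pixels, the
   scale factor is

       SF = 5 / L   [mm per pixel],

   and one pixel column corresponds to `SF/25·1000` ms of signal while
   one pixel row corresponds to `SF/10` mV.

2. **Trace segmentation.** The trace ink is separated from grid and
   background by per-pixel HSV thresholds (closed intervals, channels
   scaled to [0,1]): H ∈ [0, 0.997], S ∈ [0, 0.659], V ∈ [0.647, 1].
   These defaults suit 600 dpi scans whose contrast/sharpness were
   boosted during scanning; they are exposed as configuration because
   any other scanner/ink combination will need retuning. Note the
   window contains pure white — on real scans the background must be
   either saturated or clipped away by the scanner's contrast boost.
   The mask is thinned (default 3 passes of 8-connected morphological
   thinning) to approach a one-pixel curve; thinning only removes
   pixels and never splits a component.

3. **Signal reconstruction.** Each column's foreground pixels collapse
   to their mean row index (median available for outlier-heavy masks);
   empty columns are filled by linear interpolation. The baseline is
   aligned to zero by subtracting the signal mode, computed on
   amplitudes quantized back to integer pixel rows (continuous means
   rarely repeat; ties break toward the value nearest the median).
   Vertical QRS strokes put many pixels in one column, so the mean
   flattens R peaks; this is compensated by adding/subtracting a fixed
   `peak_delta_mm` (default 1 mm) at the k largest-|amplitude| local
   extrema (default k = 5 for a 5 s strip, separated by ≥ 200 ms; an
   optional heart-rate hint resizes k to `duration·HR/60`, since a
   fixed 5 misfires at 30 or 200 bpm). A constant correction is a
   blunt instrument; it is the configurable, documented default rather
   than a claim of optimality.

## Grid detection details

After whitening the trace pixels, grid ink is isolated as mid-gray
pixels (luminance in [100, 220] of 255 — this excludes near-black
marks and the white background), consolidated by morphological closing
with a 16 px square and removal of 8-connected components smaller than
1000 px². Both constants are resolution-bound: they were set for
600 dpi and scale by `dpi/600` (closing) and `(dpi/600)²` (area) when
the scan resolution is supplied.

Square side *L* is measured from the **interiors** of the closed grid:
8-connected background components not touching the crop border.
Interiors map cleanly to `(L − w)²`, where *w* is the grid line width,
measured as the median run length of foreground runs across rows and
columns (runs longer than a quarter of the crop are stretches *along*
a line and are discarded; fallback 1 px). Because trace removal leaves
discontinuities that can fuse two squares into one region (≈2.07×
median area) or split one, interior areas outside [0.6, 1.8]×median
are discarded before averaging; genuine interiors vary by far less
than that, and the looser guards we tried admitted fused pairs, biasing
SF low by several percent at high heart rates. The per-crop SFs of a
page are then averaged.

## Validation methodology

* **Similarity**: the digitized lead is resampled onto the reference's
  500 Hz grid by the rational ratio of two anchor gaps (two R peaks
  identified in both signals) using a polyphase FIR anti-aliasing
  resampler, shifted so the first anchors coincide, and compared over
  the overlap with the Pearson coefficient. `pearson_r` implements the
  covariance formula on mean-centered vectors (algebraically identical
  to the raw-sums definition, numerically stable under offsets).
* **Time parameters**: QRS, QT, PQ, P-wave durations and mean R-R from
  fiducial sample indices; HR = 60000/RR. Fiducials are *inputs*
  (annotation CSV) as they would come from manual identification; the
  bundled `delineate_clean` is a threshold-crossing helper usable only
  on clean synthetic waveforms with a true zero baseline, not a
  clinical delineator. R-R is the mean over all successive peak pairs
  (more noise-robust than a single pair).
* **Repeatability/reproducibility**: per-parameter mean, sample SD
  (n−1 denominator — this convention reproduces recorded measurement
  tables exactly), and range; absolute error aE = |measured − true|,
  with mm equivalents at 25 mm/s (1 mm = 40 ms). 1 mm — the grid
  resolution — is the acceptability bound for the whole chain.

## Synthetic ground truth

`generate_ecg` builds each beat as a sum of five Gaussian bumps
(P, Q, R, S, T) with fixed offsets from QRS onset; at 60 bpm the
template's fiducials give QRS 88 ms, QT 368 ms, PQ 164 ms, P-wave
86 ms, R-R 1000 ms — the instrument settings used as ground truth in
the validation tables. The waveform is normalized so the R peak equals
`amplitude_mV` exactly; beats are placed at RR = 60000/HR ms with
optional uniform jitter, and the template compresses by
`clip(RR/500, 0.4, 1)` at high rates so QT < RR. Fiducial indices are
returned exactly; all randomness flows from one seed.

`render_paper` draws the strip at a configurable true scale factor in
two grid dialects (dot grid; solid lines) with hard-edged strokes, so
ink colors are exact and the default segmentation thresholds apply
verbatim: trace ink (80,80,200) sits inside the HSV window and below
the gray band; grid ink (dots (110,110,110), coarse lines
(160,110,110)) fails the V threshold but sits inside the gray band;
background (255,255,80) and fine 1 mm rules (250,240,60) are saturated
(S > 0.659) and bright (luminance > 220), invisible to both masks.
Dot size scales with resolution so the 1 mm lattice stays unconnected
under closing while the dense dots along 5 mm rules merge into lines.
The baseline sits at 22.5 mm from the top, deliberately off the
ruling, so trace removal never erases a whole grid line.

What the renderer does **not** emulate: skew/rotation, perspective,
JPEG artifacts, thermal-paper fading, anti-aliased or bleeding ink,
overlapping leads, and printed annotations. Passing the closed-loop
tests therefore demonstrates the pipeline's correctness on geometry,
calibration, reconstruction and statistics — not robustness to
degraded real-world scans, which additionally depends on threshold
tuning per scanner.

## Problem sizes and numerical choices

The closed-loop suites run 5 s, 500 Hz single-lead strips rendered at
0.0423 mm/px (the 600 dpi scan scale, ≈950×3200 px), 0.05, and
0.1725 mm/px, at 30–200 bpm in both dialects. Clean renders
closed-loop at r ≈ 0.99 and recover SF within 0.2%; the acceptance
thresholds (r ≥ 0.95, SF within 5%) leave headroom for the quantization
and thinning noise of less benign configurations. Durations recover to
5000 ± 100 ms (the residual is SF error). Inclusive thresholds
everywhere; grayscale band membership uses a 1e-6 tolerance so integer
bounds remain inclusive under float luminance weights. Degenerate
inputs (empty mask, flat signal, constant vector, no enclosed square)
raise typed errors or return empty results as documented per function.

## Known limitations

* The ±1 mm peak correction is static; it can overshoot on leads whose
  R amplitude is small (a 0.5 mV peak is 5 mm, so 1 mm is a 20% bump).
* HSV defaults are scanner-specific; there is no adaptive thresholding.
* No skew correction: the grid must be axis-aligned to a few degrees.
* `delineate_clean` is for synthetic waveforms only.
* Scale recovery on dot grids at very low resolution (≳0.2 mm/px)
  approaches the regime where closing can no longer distinguish the
  1 mm lattice from the 5 mm rules.
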