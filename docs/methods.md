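# Methods

This note documents the models, algorithms and numerical choices behind
`endoheal`: what each stage assumes, which parameters matter, what the
synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Problem setting

An endothelial monolayer lining a simulated coronary artery is wounded
(denuded) along the lumen before stent deployment, then imaged by
epifluorescence time-lapse microscopy while the two wound fronts migrate
back toward each other under flow. The cells carry a membrane dye
(CM-DiI), so covered regions are bright and textured while the denuded
wound band is dark. The quantification task is: per region of interest
(ROI) and per frame, partition the image into wound and endothelium,
measure the wound area, and reduce the per-frame areas to normalized
closure curves and between-condition statistics.

## Segmentation model

Each ROI of each frame is processed independently; no state is shared
between frames except the explicit fallback described below.

1. **Contrast stretch.** Intensities are linearly mapped so that the 1st
   percentile of the crop goes to 0 and the 99th to 65535, clipping
   outside. This standardizes exposure differences between ROIs and
   frames. A constant crop is passed through unchanged with a warning.
   The exact transfer curve of "contrast enhancement" is a declared
   convention here: a linear percentile stretch with configurable
   percentiles, the minimal reading of histogram expansion.
2. **8-bit conversion.** `v8 = floor(v16 / 256)`.
3. **Histogram smoothing.** The 256-bin histogram is smoothed with a
   centred moving average of window 10 (for the even window, one extra
   bin on the high side). Windows are truncated at the histogram ends:
   boundary bins average only the bins actually inside the window, so no
   invented padding values enter the average.
4. **Valley threshold.** A wounded ROI has a bimodal histogram: a dark
   wound mode and a bright cell mode. The two modes are identified as
   the **two most prominent** plateau local maxima of the smoothed
   histogram (topographic prominence, computed exactly; plateaus are
   represented by their lowest gray level; histogram edges may hold a
   peak). The threshold is the gray level of the minimum count strictly
   between the two modes, with ties broken toward the lowest gray level.
   Pixels at or below the threshold are wound (the dark class); the
   boundary-bin assignment (`<=` rather than `<`) is a fixed convention.

   *Why prominence ranking rather than a fixed prominence cutoff.* The
   relative heights of the two modes swing by an order of magnitude as
   the wound closes (the wound mode dominates early, the cell mode
   late), and the percentile stretch deposits a small saturation spike
   at gray 0 whose prominence is of the same order as Poisson ripple
   (a few percent of the modal count). Any fixed prominence fraction
   therefore either admits ripple/spike peaks as false first modes or
   rejects a genuine broad cell mode. Ripple and saturation spikes have
   inherently small topographic prominence (they sit on the flank of a
   larger mode), so ranking by prominence selects the genuine modes
   across the whole closure range. A prominence floor (default 5% of
   the maximum count, configurable) applies only to the second-ranked
   peak and serves as the unimodality test.
5. **Unimodal fallback.** When a wound has (nearly) closed, the dark
   mode vanishes and the histogram becomes unimodal; the module reports
   a segmentation failure with diagnostics. The pipeline then reuses the
   wound/cell intensity boundary of the nearest earlier frame of the
   same ROI — carried in **raw 16-bit intensity space**, because the
   percentile stretch of a wound-free frame spreads the cell mode over
   the whole 8-bit range and an earlier 8-bit valley would re-create a
   phantom wound there. If no earlier threshold exists the ROI-frame is
   marked missing.

Segmentation quality depends on histogram statistics: ROIs below roughly
30 px × 100 px (~3 000 pixels) give unstable valley estimates at default
noise. The default ROI layouts keep ROIs at ≳15 000 pixels.

## Mask refinement

Three filters run in a fixed order on the binary mask; all sizes are in
physical units and converted with the pixel size. The *principal* wound
component — the largest connected wound region — is never removed.

1. **Island fill.** Endothelium-class components entirely surrounded by
   wound (i.e. not touching the crop border) with area below a
   threshold are reassigned to wound. These are isolated migrated cells
   or bright noise inside the wound. Wound area never decreases here.
2. **Speck removal.** Wound-class components other than the principal
   component with area below a threshold are reassigned to endothelium.
   These are small dark gaps or noise in the monolayer. Wound area
   never increases here.
3. **Front-gap removal.** For every remaining non-principal wound
   component, the Euclidean distance transform is computed (distance of
   each component pixel to the nearest non-component pixel); the
   component's maximum EDT value is its inscribed radius. Components
   with inscribed radius below half a typical cell size are reassigned
   to endothelium. This removes narrow crevices hugged by cells near
   the advancing front that survive the area filters because they are
   long but thin.

Defaults: typical cell size 30 µm; both area thresholds default to the
area of a 30 µm disc (~707 µm², ~256 px² at 1.66 µm/pixel); EDT radius
15 µm; 8-connected components. The size thresholds are conventions, not
measured values, and are configurable and logged per stage (the per-stage
area ledger is written to the results so every removal is auditable).
`refine` is idempotent for fixed parameters, which is verified by test.

## Quantification and aggregation

Wound area is wound-pixel count × pixel-size². The aggregation order is:

raw per-ROI areas → mean over the zone's non-excluded ROIs (4 upstream /
8 stented by default; ROIs over collagen imperfections can be flagged
excluded and never enter averages) → normalization of the zone series by
its first-time-point value → mean ± SEM across independent experiments
(SEM = sample SD with n−1 denominator / √n).

Normalizing *after* zone averaging makes the curve less sensitive to a
single noisy ROI at the first time point; the alternative order
(normalize each ROI, then average) is implemented behind a flag and the
two agree on noise-free data, which is pinned by test. Curves are
computed for both zones; the stented zone is the headline.

The "percent faster" effect size at time t is computed on healed
fractions: `100 · [(1−m_b) − (1−m_a)] / (1−m_a)` where `m` is the group
mean normalized area and `a` the reference condition. This is an
interpretation — expressing the difference as a relative excess of
healed (re-covered) area — and it reproduces the expected headline
number from the group means (0.57 vs 0.38 at 48 h → 44%).

## Statistics

At each time point the across-experiment normalized values of the two
conditions are compared with a classical equal-variance unpaired Student
t test (df = n_a + n_b − 2, two-sided p). Welch's variant exists behind
a flag but is not the default. Zero-variance degenerate cases use the
conventions p = 1 (equal means) and p = 0 (unequal means); this also
gives the sensible p = 1 at t = 0 where every normalized value is
exactly 1. No multiple-testing correction is applied across time points
— each test stands alone, and the analysis log says so prominently. The
significance onset is the earliest time from which *all* later time
points are significant, so isolated early crossings do not count.

## Synthetic scenes

The generator renders what the analysis assumes, with known ground
truth:

* **Geometry.** The wound is a straight horizontal band: centerline at
  mid-height, fronts at ± half-width(t). Half-width over time is
  piecewise-linear through control points; since band area is
  proportional to half-width, a normalized-area trajectory maps directly
  onto half-widths. Fronts carry a smooth, zero-mean roughness profile
  (Gaussian-filtered white noise, correlation ~5 cell diameters, RMS
  amplitude `front_roughness`) that is static per experiment, so the
  ragged front keeps its shape as it advances. Zero-mean roughness keeps
  the band area equal to the nominal area up to pixel quantization.
* **Texture.** The monolayer is overlapping soft-edged blobs (Gaussian
  kernels of ~one cell diameter with per-blob intensity jitter) on a
  floor of mean − 2.5 SD; the wound bed is dim Gaussian texture clipped
  at ±2.5 SD. With zero noise the two class-conditional intensity
  ranges are disjoint by construction, which makes the zero-noise
  pipeline-recovery test exact.
* **Artefacts.** Poisson-count bright islands (diameter 0.6 cells)
  inside the wound and dark specks (0.3 cells) in the monolayer, placed
  uniformly; optional opaque strut rectangles and dimmed imperfection
  rectangles. None of these alter the ground-truth mask: they are
  exactly what the refinement filters exist to remove, so truth must not
  move with them.
* **Noise.** Additive Gaussian noise per pixel, applied last, clipped to
  the 16-bit range.

Defaults: 1024×1280 frames, 1.66 µm/pixel, 0.5 h frame interval, 97
frames (48 h), cell diameter 30 µm, cell intensity 22000 ± 5000, wound
3000 ± 800, noise SD 1200, roughness 15 µm, 8 islands and 8 specks per
frame. Intensities were chosen to emulate a well-stained membrane-dye
channel: class modes separated by ~4× the wound-class spread so the raw
valley threshold misclassifies only a few percent of pixels, which is
the regime the original interactive-selection validation describes.
The artefact rates are absolute counts per frame, so they scale in
relative importance as the frame shrinks — on a 512×512 crop the
islands are ~0.6% of the initial wound; on deliberately tiny test frames
they can dominate the pre-refinement error (the refinement recovers
them).

What the generator does **not** emulate: optics (PSF, vignetting),
photobleaching, phase-contrast structure, stage drift or stitching of
the multi-position acquisition grid, cell-scale front protrusions, or
biological variability in closure speed between replicates (replicates
share the trajectory and differ only in texture/noise realizations).
Consequently, passing the parameter-recovery tests shows that the
pipeline measures what the scene model renders without bias, not that it
is robust to every failure mode of real microscopy.

## Scaled study replication

`pipeline.replicate_study_condition` reproduces the study design on
synthetic data: five replicate experiments per condition, ground-truth
trajectories through the printed group means of each stent condition
(bare: 1.0/0.74/0.60/0.57, coated: 1.0/0.65/0.42/0.38 at 0/20/40/48 h),
full pipeline, stented-zone group curve. Scenes are rendered at a
512×512 crop scale with an initial half-width of 200 µm: the full-size
default half-width (500 µm — a free parameter, since the true initial
wound width is not reported) would give a 1000 µm band that cannot fit
a 512 px ≈ 850 µm frame, so the scaled scenes keep the band at the same
~47% fraction of frame height instead. Recovered group means sit within
±0.02 of the generating control fractions at the report times.

## Determinism

All randomness flows from integer seeds through `numpy` `SeedSequence`:
the scene seed fixes the static texture and roughness fields, per-frame
child seeds fix artefact placement and noise, and replicate k of an
experiment set uses seed base + k. Identical configuration and seeds
reproduce stacks bit-for-bit; results CSVs are byte-identical across
reruns apart from the manifest timestamp.

## Flow-condition numbers

The perfusion calculator assumes fully developed Poiseuille flow in a
rigid circular channel: wall shear stress τ_w = 4µQ/(πR³), Reynolds
number Re = 4ρQ/(πDµ) on the channel diameter, Womersley number
α = R·√(2πfρ/µ) on the channel radius and pump roller frequency.
Culture-medium properties at 37 °C (µ = 0.78 mPa·s, ρ = 1000 kg/m³),
Q = 40 mL/min, R = 1.5 mm, D = 3.0 mm, f = 3.5 Hz give τ_w ≈ 0.196 Pa
(reported 0.2), Re ≈ 363 (reported 360 at two significant figures) and
α ≈ 7.96 (reported 8). Reported rounding follows those conventions; raw
values are always also returned. The pulsatile pressure amplitude is
metadata only; no computation consumes it.

## Known limitations

* The valley threshold needs both modes present in the ROI; wounds
  occupying <~5% or >~95% of an ROI give unstable thresholds, mitigated
  but not eliminated by the fallback rule.
* Area thresholds of the refinement filters are conventions around a
  single "typical cell size"; heterogeneous cell sizes are not modeled.
* Zone averaging assumes a common acquisition grid across ROIs and
  experiments; series are not resampled onto a shared grid.
* The t tests are per-timepoint and uncorrected by design; interpreting
  a single early significant point is the user's responsibility (the
  onset rule deliberately ignores them).
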