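# Methods

## Segmentation model

The segmentation assumes the one property of phase-contrast monolayer
images that is robust across illumination settings: cell-covered area is
*textured* (organelle speckle, membrane rims), cell-free medium is *flat*.
The per-pixel statistic is the Euclidean magnitude of the intensity
gradient after Gaussian smoothing,

    g = |∇(G_σ ∗ I)|,   σ = smoothing_sigma (default 1 px),

computed with central differences (one-sided at borders). Thresholding g
directly means cell *edges* — the highest-gradient pixels — are classified
as cell by construction; the subsequent morphology turns edge-delimited
interiors into solid cell regions.

* **Threshold.** Otsu's method on the gradient-magnitude histogram by
  default: parameter-free and invariant to intensity scaling. A fixed
  threshold (`threshold_method="fixed"`) is available to pin a value for
  strict reproducibility across acquisitions. A single-valued gradient
  histogram (blank field) cannot be Otsu-thresholded; such images yield an
  all-black mask with a warning, because media-only fields are legitimate.
* **Cleanup order** is closing (disk, radius 5 px) → hole filling →
  small-object removal (< 64 px²). Closing first bridges the narrow dark
  seams between adjacent cells so that hole filling can convert enclosed
  flat intracellular zones to white before the area filter runs. The
  composite is idempotent, which the suite checks.
* Defaults (σ = 1, disk radius 5, min area 64 px²) are sized for cells of
  ~15–40 px diameter in 1600×1200 fields; for strongly different
  magnifications they scale with cell diameter.

## Column profiles and alignment

For a binarized H×W image, column c has black count b(c) and white count
w(c) with b + w = H. Two per-column statistics are kept:

* `black_fraction = b/H` — bounded in [0, 1], the primary statistic and
  the one that is averaged across replicates;
* `bw_ratio = b/w` — the classical black-to-white pixel ratio, reported
  for continuity with how such profiles are usually plotted. Columns with
  w = 0 get `bw_ratio = +inf`; these are flagged and excluded from ratio
  averaging, since unbounded ratios average badly and the scratch center
  is exactly the w = 0 case. The ratio is finite exactly where
  black_fraction < 1.

The disruption center at 0 h is the midpoint of the longest contiguous run
of all-black columns (lower median for even-length runs; the first run
wins a length tie — a deterministic tie-break). If no all-black column
exists the center falls back, with a warning, to the argmax of a 51-column
moving average of black_fraction; a profile whose maximum black fraction
is below 0.5 raises "no detectable disruption" instead of guessing.

Re-centering is an integer column shift onto a common axis of
`target_width` columns with `target_center = floor(target_width/2)`
(default width: the minimum replicate width). No interpolation: columns
shifted off the axis are dropped, axis columns with no source are marked
missing (NaN) and excluded from averaging — zero-filling would masquerade
as fully cellular area. Averages are per-column means over contributing
replicates with their standard error (defined as 0 where a single
replicate contributes) and an explicit per-column replicate count.

A design fork existed here: average the per-column statistics (done), or
average the binarized images pixel-wise and re-profile. Per-column
averaging keeps the per-replicate dispersion and makes missing-data
handling explicit; the alternative is equivalent for complete, equal-width
replicates.

## Gap metrics

The hour-0 gap region is the maximal contiguous run of columns with
black_fraction ≥ 0.95 containing the detected center. The threshold is
deliberately below 1.0 so isolated white specks cannot fragment the run.
All later-hour endpoints anchor to the replicate's own hour-0 geometry:

* gap width at hour t = width of the thresholded run containing the
  inherited center (0 if that column is below threshold — closed);
* percent closure = 100·(1 − w_t/w_0), 0 at hour 0 by construction;
* cell-to-space ratio = white:black pixel counts restricted to the hour-0
  region's columns (flagged infinite when fully occupied), with
  occupied_fraction = white/(white+black) = ratio/(1+ratio) as the bounded
  companion.

Measuring the ratio inside the *initial* gap region (rather than the whole
image) makes it a pure gap-filling statistic, insensitive to confluence
changes far from the wound; this regioning is this package's documented
choice.

## Fluorescence readouts

Spot counting is multi-scale LoG blob detection (scale range 2–8 px,
10 scales) on the ROI crop, thresholded on the scale-normalized response
(default 0.05 on [0, 1] intensities), followed by distance-based
non-maximum suppression: detections closer than `min_separation` (default
5 px) are merged keeping the stronger response. Defaults suit bright
somata of ~5–15 px diameter. The ROI is a required user input — what
counts as "at the wound" is an experimental definition, not an algorithmic
one. Area-fraction morphometry is plain intensity thresholding; the
per-nucleus normalization (signal pixels / nuclei count) lets conditions
with different cell numbers be compared as fold changes.

## Statistics

Groups are summarized as mean ± SE (sd/√n, ddof = 1). Comparisons: one-way
ANOVA; Tukey's HSD (studentized range, statsmodels implementation,
harmonic-mean n for unbalanced designs) for pairwise p-values with > 2
groups; a two-sample t-test with exactly 2. The t-test is Student's
pooled-variance by default — this preserves the classical identity
F = t² for two balanced groups, which the suite asserts — with Welch as an
option since real designs rarely guarantee equal variances. Unadjusted
pairwise p-values in the multi-group case use the pooled ANOVA residual
(Fisher-LSD form), the same error term Tukey studentizes, so adjusted ≥
unadjusted holds exactly. Significance is declared at p ≤ α, default 0.05.

## Synthetic data generator

`generate_scratch_series` emulates the study conditions the package is
validated under: 1600×1200 px fields, a 200-column vertical gap centered
at column 800, hours 0/24/48 with gap fill fractions 0/0.5/0.9, and
Gaussian pixel noise of sd 0.02 by default.

Rendering: candidate cells are ellipses (semi-axes 14–22 px, random
orientation) on a jittered square grid whose spacing follows
`cell_density` (default 25 cells per 10⁴ px², spacing 20 px), so
neighbouring ellipses overlap and their union covers its region up to
small interstitial holes. Cell interiors get a mid-grey base (0.50 ± 0.06
per-cell shading) plus correlated speckle (texture_contrast, default
0.15); the outer 20 % of each ellipse radius is a bright rim (0.75);
background is flat 0.40. Cells are clipped exactly at the allowed-column
boundary: the hour-0 gap band is cell-free by construction, and at later
hours cells appear in two bands growing inward from the gap edges until
the planted fill fraction is met — emulating migration from the wound
margins. Clip faces are rendered bright like rims, as a membrane edge
would appear. The emitted truth (per-pixel cell mask, gap geometry,
occupied fraction recomputed exactly from the mask) accompanies every
image. One integer seed drives fixed sub-streams (cell field, speckle,
per-hour noise), so identical parameters give bit-identical rasters.

What the simulator does *not* model: phase-contrast halo artifacts, uneven
illumination, debris, cell division and density changes in the bulk
monolayer, sub-pixel gap edges, or biophysically realistic migration
fronts. Passing recovery tests therefore demonstrates the *algorithmic*
correctness of the chain (segmentation → profiling → alignment → metrics)
under controlled texture and noise, not robustness to every real-world
imaging artifact; on real data the segmentation parameters remain the
user's responsibility to sanity-check against a few fields.

`generate_spot_image` sums isotropic Gaussian bumps (sd 3 px, peak 0.8) on
a constant background (0.1), with rejection-sampled centers at ≥ 30 px
separation and ≥ 20 px border margin by default.

## Numerical and interface choices

* Images are float64 in [0, 1] internally regardless of source bit depth;
  RGB collapses via Rec. 709 luminance (0.2126 R + 0.7152 G + 0.0722 B).
  Round-trips through 8/16-bit TIFF/PNG are bit-exact at the stored depth.
* All pipeline CSV numbers are written with 6 significant digits, making
  reruns with identical config and inputs byte-identical across platforms.
* Degenerate inputs are warnings where the input is legitimate (blank
  field → all-black mask; single condition → summary without comparison)
  and errors where analysis would be meaningless (no hour-0 entry, no
  detectable disruption, empty gap region, n < 2 per compared group).

## Problem sizes used in validation

The recovery tests run ten seeded full-size (1600×1200) series at default
noise plus the same ten noiseless for the monotone-closure check; spot
recovery uses ten 512×512 fields of 25 spots; the type-I-error simulation
uses 1000 (tests) / 500 (acceptance script) null tables of 3×5
observations. The acceptance script reports means over three series —
enough to reproduce every headline number while staying fast on one CPU.

## Known limitations

* Alignment is rigid and columnar: slanted or curved scratches violate the
  vertical-gap assumption and would need a rotation step first.
* The disruption center is integer-resolution; sub-pixel refinement is out
  of scope.
* `bw_ratio` is reported but never averaged where infinite; consumers who
  need ratio curves through fully black columns must handle the flags.
* Tukey HSD assumes homoscedasticity; for strongly unequal variances use
  the Welch pairwise option and interpret the omnibus F with care.
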