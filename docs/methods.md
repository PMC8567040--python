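# Methods

## The measurement problem

Blue-autofluorescence cSLO frames of CX3CR1-GFP mouse retinas show bright
myeloid somata on a dark, unevenly illuminated background. Illumination,
saturation and focus drift between imaging sessions, so absolute
intensities are not comparable across frames; what is comparable, after a
contrast-normalization step, is the *set of segmented particles*. The
pipeline therefore (i) flattens and band-limits each frame, (ii) binarizes
it with an adjustable, logged threshold, and (iii) measures the resulting
particles on the original frame, where brightness values are at least
internally consistent.

## Stage 1 — contrast normalization and mask

**Rolling-ball background subtraction** (`preprocess.subtract_background`,
default radius 500 px). The background is the grayscale opening of the
frame with a ball-top structuring element of heights sqrt(r² − d²): the
highest surface a ball of radius r can reach rolling under the intensity
landscape. The subtraction is clipped at zero. Contracts: the opening never
exceeds the image, is idempotent, maps constants to themselves, and
commutes with additive constants (so the subtraction cancels them).

For r ≥ 100 px the opening runs on a downsampled copy (shrink factor
ceil(r/32), capped so the small image keeps at least 8 px per side and the
structuring element fits inside it), and the background is upsampled
bilinearly and clamped below the image. This is the standard large-radius
optimization; on 64×64 test frames the downsampled background agrees with
the exact opening to within a few intensity units (the suite asserts 8 on
a 0–255 scale), and the direct path (r < 100) is exact against a
brute-force oracle.

**FFT bandpass** (`preprocess.bandpass_filter`, defaults 30 px / 3 px).
The transfer function is a difference of Gaussians in radial spatial
frequency f (cycles/px):

    H(f) = exp(−(f·s)²/2) − exp(−(f·L)²/2),   s = 3 px, L = 30 px

H(0) = 0 exactly, so the output is zero-mean; structures much larger than
L (illumination, vignetting, residual background) and much smaller than s
(shot noise) are attenuated, somata (≈4–10 px) pass nearly unchanged. The
length-scale convention — gain exp(−1/2) at wavelength equal to the limit —
is one of several defensible mappings from "structure size" to a Gaussian
scale; it is documented here, tested against sinusoids, and configurable
via the two limits. Frames are mirror-padded to the next fast FFT size
(wrap-around halos around the bright optic disc are the failure mode this
avoids) and cropped back. No post-filter autoscaling or saturation is
applied, keeping the filter linear and deterministic.

Order matters (the opening is nonlinear); the pipeline subtracts
background first, then bandpasses, and records both parameter sets in the
frame's provenance list.

## Stage 1 — threshold and particles

`suggest_threshold` offers three deterministic histogram methods (otsu,
triangle, percentile; 256 bins). **Triangle is the pipeline default**: with
sparse bright particles the preprocessed histogram is a single background
peak with a long bright tail, exactly the regime the triangle construction
was designed for, and in planted-truth experiments it is the method whose
threshold preserves soma areas (Otsu lands mid-blob and halves them).

The protocol additionally enforces a robust noise floor on the *auto*
suggestion: the threshold never drops below 6 robust standard deviations
(1.4826·MAD) of the preprocessed frame. This is the scripted analogue of a
blinded evaluator refusing to place the threshold inside background
speckle, and it is what makes a cell-free frame segment to zero particles
instead of a scatter of noise clusters. Manual thresholds (per-image
overrides in the batch config) are never modified; every threshold,
however produced, is serialized with its origin.

Binarization selects the closed interval [lo, hi]; hi defaults to the
frame maximum (whether the original protocol used an upper cut is
unknowable from its description, so none is applied by default).
Connected components use 8-connectivity by default (the common
particle-analysis convention; 4 is available), are filtered to
[min_area_px, max_area_px], and are relabeled 1..n in raster order of each
component's first pixel so labels are algorithm-independent.
Edge-touching particles are kept unless `exclude_edge` is set. Touching
cells are *not* split: at peak infiltration overlapping somata are not
separable at fundus resolution, and no watershed is attempted.

`min_area_px` defaults to 4 (rejects shot noise, keeps the smallest
plausible somata). The planted-truth benchmarks use 10: the smallest
planted soma (radius 2 px) covers ≈13 px, so a floor of 10 px sits below
every real cell and above residual speckle. This is an analyst's
cell-size-informed choice of the exposed parameter, recorded per run in
the configuration hash.

## Stage 2 — measurement and summaries

Measurements are taken on the **original** frame (a flag switches to the
preprocessed one for sensitivity analyses). Per particle: pixel area,
min/mean/max brightness, equivalent-circle diameter 2·sqrt(A/π), centroid,
and the maximum Feret diameter computed over the pixel-corner point set
(each pixel contributes its four corners; a single pixel has Feret
sqrt(2), a 1×5 bar sqrt(26)). The implementation takes the convex hull
first; the test oracle does the full pairwise scan.

Per image: CC, SuA, MVI, MCB, AvA (definitions in the README). MVI and MCB
are per-image *means* of per-cell statistics by default, making them
comparable across images with different counts; `mcb_mode="global_max"`
switches MCB to the single brightest cell, since the original naming does
not disambiguate the two readings. With zero cells, CC = 0, SuA = 0 and
the intensive readouts are NaN-flagged. AvA·CC = SuA holds exactly.
Areas are in pixels throughout; no µm calibration is assumed (an optional
scale would multiply areas only and affects nothing else).

## Scoring layer

Z-scores use the sample SD (n−1) and are computed **within week strata**
by default: cell counts and areas drift upward with animal age in all
groups, and pooling weeks would let that maturation trend masquerade as a
between-group signal. A constant or single-value stratum is a hard error.
The composite is the unweighted mean of the component Z-scores (CC + SuA
by default); mean vs sum is immaterial for ROC ordering, but cut-off
*values* are on the mean scale.

`roc` sweeps the unique score values (higher = positive, call when score ≥
threshold); the trapezoid AUC then equals the Mann–Whitney pair
probability with ties counted ½. The positive class is the immunized
group; sham and naive animals are pooled as negatives. Each eye-image is a
row — no within-animal aggregation — matching a design in which eye is a
within-subject variable; group-level inference on such data (GEE etc.) is
out of scope, and the cohort table is exported in a long, GEE-ready
format. `choose_cutoff` enumerates midpoints between adjacent scores plus
one candidate below and above the range; *balanced* minimizes
|sens − spec| (ties: larger sens+spec, then lower cutoff), *youden*
maximizes sens+spec−1, and floor strategies optimize one rate subject to a
bound on the other. The full candidate table is exportable. Reported
p-values are flagged against α = 0.025 (Bonferroni-adjusted level).
Confidence intervals for AUC are not produced.

## Synthetic data

`generate_image` renders: background level 12 (8-bit scale) with a gentle
linear illumination gradient and quadratic vignetting (strength 0.3);
Gaussian read noise SD 2; 3 dark vessel-like Bezier streaks (35%
darkening); and n Gaussian-blob somata with peak intensity N(160, 20),
nominal radius uniform in [2, 4] px, rendered with σ = radius/2 and
truncated at 2σ. **The truth mask is the 2σ disc**: a continuous blob has
no canonical area, so the truncation radius defines the planted area, and
the blob is rendered only inside it. Cells are placed by rejection
sampling with a minimum separation (default 20 px; bounded retries, then a
packing error) — overlapping somata defeat per-cell analysis at this
resolution, so no-overlap is the default and the deliberate exception
carries no recovery guarantee. A cell optionally receives 2–5 thin
radiating processes at 25% of its peak intensity; processes are *not* part
of the truth mask. All randomness flows from one explicit seed;
regeneration is bit-identical.

`SynthImageParams.high_snr()` is the documented recovery benchmark: the
same frame without processes (the truth convention covers somata only, so
the soma-area benchmark renders somata only). Peak intensities sit ≈30
noise SDs above background.

`generate_cohort` emulates the longitudinal study design: three groups
(default 34/21/20 animals), two eyes per animal, weeks 0–12, 256×256
frames (nothing downstream depends on frame size; 256 px keeps cohort
simulations cheap at matched cell density). Cell count and soma radius
share a maturation drift; each immunized animal draws a disease-severity
factor ~N(1, 0.35) (floored at 0) that scales a Gaussian-shaped activation
bump (peak week 6, width 2 weeks) on *both* cell count (+40% at peak) and
soma radius (+3%). Baseline noise sources are kept separate on purpose:
between-animal count level (SD 18%), between-animal soma size (SD 13%),
eye-level count noise (SD 8%) — and baseline soma size scales inversely
with baseline density (coupling exponent 1), reflecting microglial tiling:
animals with more cells have smaller ones. This structure reproduces the
qualitative pattern the pipeline is meant to exhibit — CC and SuA both
discriminate immunized from control eyes at the activation peak, and their
composite, which shares the severity signal but averages the independent
noise sources, discriminates at least as well as either alone.

What the generator does **not** emulate: real choroidal background
texture, the instrument's optical point-spread function, eye-motion
artifacts, photobleaching, and genuinely overlapping somata at peak
infiltration. Passing planted-truth benchmarks therefore demonstrates the
correctness and stability of the measurement chain, not field performance
on animal data — on real frames the manual threshold override exists
precisely because auto-suggestions cannot absorb session-to-session
acquisition drift.

## Problem sizes and numerics

The recovery benchmark uses 512×512 frames with 50 somata over 20 seeds
(counts exact on ≥95% of frames, total area within 15% of planted;
measured: 20/20 and ≤3%). Cohort benchmarks use 8/4/4 animals at weeks
{0, 6} over 10 seeds for the composite-vs-single AUC comparison and
automated-vs-truth regression (R² ≥ 0.95 required; ≈0.96–0.99 measured).
These sizes are the package's simulation defaults for its own checks;
`SynthCohortParams` scales to the full study design.

Intermediate arithmetic is float64 throughout; quantization happens only
in the synthetic generator's export (rounding to the declared bit depth)
and when writing masks. Batch runs are deterministic: every cohort-table
row carries the SHA-256 of its input image bytes and of the serialized
run configuration, and rerunning a batch reproduces the CSV byte for
byte. Known limitations: no cell tracking across timepoints, no
morphology classification (ramified vs amoeboid is below fundus-imaging
resolution in heavy infiltration), no reading of proprietary scanner
containers (export to TIFF/PNG first).
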