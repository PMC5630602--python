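# Methods

This note records the model behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Oriented matched filtering and the correlation length

**Stencils.** A kernel of length *L* (µm) and orientation *θ* is an
anti-aliased capsule (straight segment with round caps) of configurable
pixel width, optionally convolved with an isotropic Gaussian of
`blur_px` pixels so the stencil matches the optically blurred profile of
a real imaged fibre (matched filtering). Each stencil is restricted to
its *footprint* — pixels within `width/2 + 0.5 + 2·blur + 1.5` px of the
segment — then zero-meaned and L2-normalised over that footprint.

**Score.** For each placement the score is the ZNCC between the stencil
and the image patch, with the patch mean and norm taken over the
footprint. Normalising over the footprint rather than the stencil's
bounding square matters in dense fields: with a square window, every
unrelated fibre inside the window inflates the patch norm and long
kernels can never score high. With footprint normalisation an isolated
matched structure scores ≈ 1 regardless of what its neighbours do
outside the footprint. Scores are clipped to [−1, 1]; a patch whose
footprint standard deviation is below 1e−5 of the image RMS is treated
as flat and scores 0 (so blank background can never pass a threshold,
whatever the intensity scale).

**Orientation grids.** A thin kernel of length *L* px tolerates an
angular error of only ≈ atan(width/L) before its tip walks off the
structure, so a single global orientation step systematically penalises
long kernels. The bank therefore refines the base grid per length: the
step is halved (at most twice) until half a step of misalignment moves
the kernel tip by at most half the line width. All grids stay closed
under 90° rotation when the base grid is (base steps dividing 90°),
which is what makes the 90°-rotation invariance of the length maps
exact.

**Borders.** The image is padded with its median before correlation.
Without padding, each length *L* has an unevaluable margin of half its
support, and long structures near the frame edge silently read short —
a large bias for cord-scale kernels whose support approaches half the
field of view.

**Length map.** A placement passes when its best-over-θ score ≥ τ. The
per-pixel correlation length is the **largest L for which some passing
placement covers the pixel** (coverage = the placement's own capsule;
`core_width_px` can narrow the attribution stripe, default is the
detection width). Two alternatives were considered and rejected:

* score-argmax over L: inside a long straight structure every shorter
  kernel also scores ≈ 1, so no interior maximum exists; the largest
  passing length is the meaningful statistic;
* centre-only attribution (a pixel gets the largest L whose kernel
  *centred there* passes): the off-axis and tip pixels of every fibre
  then read much shorter than the fibre, which biases pixel-weighted
  length distributions short by a large margin. Coverage attribution
  labels every pixel under a passing placement and removes that bias
  while preserving monotonicity in τ (passing sets shrink as τ grows,
  and dilation and union are monotone).

**Threshold calibration.** `calibrate_tau` scans τ ∈ {0.50, 0.55, …,
0.95}. For each probe length a noise-free single-fibre image is rendered
with the data's fibre width and blur, at an orientation of half the base
grid step — the worst case for orientation quantisation, so the chosen τ
transfers to structures at arbitrary angles rather than being flattered
by grid-aligned probes. The τ minimising the mean |modal recovered
length − truth| wins; ties break toward smaller τ; an empty map counts
as an error of the full probe length (this is what prevents the scan
from running into the regime where almost nothing passes). At the fibre
defaults the scan selects τ = 0.85.

**Mask and rendering.** The mask is (detection term) × (intensity
rescaled between its median and 99th percentile, clipped to [0, 1]); the
detection term is a 0/1 indicator by default, or the pixel's best score
behind `mask_mode="score"`. The HSV rendering maps Lmax linearly from
hue 240° (blue) at the range minimum to 0° (red) at the maximum,
saturation 1, value = mask, so undetected pixels are black.

**Defaults (fibre workflow).** Pixel size 0.5 µm/px, length grid
10–80 µm step 10, base orientation step 5°, kernel width 3 px, kernel
blur 1 px, τ calibrated (0.85). These describe wide-field fluorescence
of fibrillar matrix at a 10–20× objective: ≈ 1.5 µm apparent fibre
width and ≈ 0.5 µm optical blur.

## Phase-contrast pretreatment and cords

Phase-contrast cords are dark bands with bright halos on mid-gray
background — not directly matchable by a bright-line kernel. The local
contrast map is the windowed standard deviation (default 15 px window),
with the *median* of the SD field subtracted before normalising by its
99th percentile and clipping to [0, 1]. The floor subtraction is
essential: the SD field has a nonzero noise floor everywhere, and
dividing without subtracting it maps plain background to a high
constant. After normalisation the map is invariant to affine intensity
changes of the input. If structures are sparser than the normalisation
percentile the peak SD is used as the scale instead (so a
boundary-between-two-flats image still yields a nonzero map).

Cord analysis then reuses the filament machinery at cord scale: pixel
size 2 µm/px, lengths 50–600 µm step 50 (straddling the 300 µm
reporting threshold), base orientation step 10°, kernel width 16 px and
blur 2 px — the apparent ridge width of a ≈ 12 µm cord after the
contrast windowing — and τ = 0.8. Reported statistic:
`fraction_above(dist, 300 µm)` (strictly above), the complement
convention of the fibre workflow's `fraction_below(25 µm)` (strictly
below). Pixel weighting over the detected mask is the default
(per-"structure" weighting would require a segmentation step that is
deliberately out of scope); mask weighting and per-image versus pooled
aggregation are both available, pooled being the default.

## Synthetic data: what it emulates, what it does not

**Fibre fields** render each segment as an additive anti-aliased capsule
(crossings are brighter, as in real matrices), Gaussian-blur the field,
add Gaussian noise and clip at zero. Defaults: 512×512 px at 0.5 µm/px,
amplitude 400 on background 100, blur 0.5 µm, noise SD 10 — a bright,
well-resolved widefield image. The truth label image assigns each core
pixel the covering segment's true length, longest segment winning at
crossings. Draw order per segment: length, orientation, centre x,
centre y (centres constrained so the capsule fits the frame); one seeded
generator per call makes every output bit-reproducible.

**Cord networks** are chains of fixed 25 µm steps with Gaussian heading
jitter and optional side branches, rendered from a per-cord distance
field as a dark core plus bright rim on 0.5-gray background (computing
the band from the whole polyline's distance field avoids bright
artefacts where consecutive segments join). `min_clearance_um > 0`
rejection-samples placements so cords do not cross. The validation
fixtures use straight (`turn_sigma_rad = 0`), non-crossing cords on a
2 × 2 mm field: the correlation length of a cord interrupted by a
crossing, or curving away from any straight line, is *genuinely* shorter
than its contour length — the method measures straight unobstructed
spans — so full-path truth labels are only commensurable with the
measurement when cords are straight and resolvable. The waviness and
branching parameters exist for realistic-looking demonstration data.

**Trajectories** are persistent random walks: constant step
`speed × Δt`, heading increments i.i.d. Gaussian(0, σ²), optional
positional noise added afterwards. The tangent autocorrelation at step
lag k is exactly exp(−k σ²/2), giving a closed-form persistence length
ξ = 2d/σ² against which the estimator is validated. Defaults follow the
study conventions for endothelial migration: 5-min frames, ≈ 20 µm/h,
61 frames (a 5 h window), analysis window 5–10 h, and a warning when
fewer than 100 cells are summarised.

None of the generators simulate a microscope PSF beyond Gaussian blur,
cell bodies, uneven illumination, or photobleaching; passing tests show
the algorithms recover what they claim on clean geometry with realistic
noise, not that any specific instrument is calibrated.

## Motility definitions

Speed is the mean over consecutive steps of |Δposition|/Δt in µm/h —
invariant under rigid motions of the track and exact for noise-free
simulated walks. The directional autocorrelation at step lag k is the
mean cosine between step i and step i+k (zero-length steps skipped);
the contour lag is k × mean step length. The persistence length is
−1/slope of the least-squares line through ln(autocorrelation) versus
contour lag, using only lags with autocorrelation > 0.2 (log of
non-positive values is undefined and the tail is noise-dominated);
fewer than 2 usable lags reports NaN, a non-decaying curve +inf. The
per-condition value is fitted on the track-averaged curve, which is far
more stable than averaging per-track fits.

## Statistics

Distributions are pixel-weighted over the kernel-length support;
`fraction_below`/`fraction_above` use strict inequalities, matching the
"< 25 µm" and "> 300 µm" reporting conventions. Condition comparisons
use the unpaired two-sided Student t-test (equal variances pooled;
Welch behind a flag), with stars \*(p<0.05), \*\*(p<0.01),
\*\*\*(p<0.001) and "ns" otherwise; two identical samples are reported
as t = 0, p = 1 rather than NaN. ΔΔCt: ΔCt = Ct_target − Ct_reference
per condition, ΔΔCt = ΔCt − ΔCt_control, fold change 2^−ΔΔCt (1 when
condition ≡ control). No multiple-testing correction is applied.

## Validation problem sizes

The acceptance checks run on: 20 random 64×64 images for the FFT/direct
oracle; 8 noise-free probes (10–80 µm) for calibration and recovery; a
40-segment 15/60 µm fibre field (512², 0.5 µm/px); a 30-cord 150/450 µm
network (1024², 2 µm/px); and 500 simulated tracks of 61 frames. These
sizes keep a full validation run in the minutes range on a single CPU
while leaving Monte-Carlo error well inside the stated tolerances.

## Known limitations

* Lengths are reported on the kernel grid; resolution is one grid step,
  and structures longer than the largest kernel read as that largest
  length.
* A structure's measured length is its longest straight, unobstructed,
  within-frame span: curvature, crossings and image borders all shorten
  it relative to contour length. This is a property of the estimand,
  not an artefact, but it must be kept in mind when comparing with
  skeleton-based measures.
* The detector quantifies per-pixel length structure only; it does not
  segment fibres into objects, count branch points, or measure mesh
  topology.
* Published per-condition motility values from tracking GUIs cannot be
  matched numerically because their internal persistence definition is
  not public; this package documents its own definition in output
  metadata instead.
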