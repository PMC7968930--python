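# Methods

This note documents the models behind each pipeline stage, the conventions
adopted where the underlying laboratory procedures leave choices open, and
what the synthetic-data generators do and do not emulate.

## Synthetic time-lapse stacks (`synth.gen_timelapse`)

A straightened sporogenic hypha is modelled as a 1-D midline of
`n_positions` pixels (default 200 px at 0.1 µm/px, i.e. a 20 µm hypha —
the field list of the truth object needed an explicit length to be
renderable) observed over `n_frames` frames (default 24 at 10 min/frame,
a 240 min movie). Each planted Z-ring contributes a Gaussian in space
(SD `sigma`, default 0.15 µm — a diffraction-scale ring width) scaled by a
piecewise-linear lifecycle: amplitude rises linearly from 0 at
`t_assemble` to `peak_amplitude` at `t_peak` and falls linearly to 0 at
`t_disassemble`. This is the simplest shape exhibiting the observed
assembly → brightening → constriction → disassembly progression; real
traces plateau and fluctuate, which this model deliberately omits. Noise
is additive i.i.d. Gaussian clipped at 0 — adequate for exercising
thresholding and peak logic, but not a detector model (no Poisson shot
noise, PSF blur, bleaching, or drift). A green recovery test therefore
establishes correctness of the measurement chain, not robustness to
microscope physics.

## Background correction (`zring.background_correct`)

Multi-Otsu thresholds (default 3 classes: background, dim hyphae, bright
rings) are computed once on the histogram of the whole stack, not per
frame — per-frame thresholds would make ring intensity traces
discontinuous. Pixels below the lowest threshold are set to 0 and the
threshold is subtracted from the rest, so the corrected minimum is
exactly 0. Re-thresholding a corrected stack would find a new positive
threshold and keep eroding signal, so the operation defines an explicit
fixed point: when the lowest multi-Otsu class is dominated by exact zeros
(> 50% of its pixels) the stack is considered already corrected and
returned unchanged. This makes correction idempotent on any stack whose
original background class was the zero class after one pass. A side
effect of zeroing sub-threshold pixels is that the flanks of dim or
time-averaged rings are clipped, which biases post-correction FWHM
measurements slightly low (≈ 15% for the default synthetic world); widths
quoted on corrected data inherit this convention.

## Kymographs (`zring.build_kymograph`)

The midline polyline is resampled at 1 px arc-length spacing; at each
sample the intensity is averaged over `line_width` px (default 5)
perpendicular to the local segment, with bilinear interpolation. On
axis-aligned polylines this reduces exactly to row/column averaging,
which the tests exploit as an oracle. Positions are reported in µm from
the polyline start; pixel indices are 0-based.

## Ring detection and widths (`zring.detect_rings`, `zring.ring_width`)

Candidate rings are local maxima of the time-averaged intensity profile,
strictly greater than both neighbours, with plateaus resolved to the
plateau centre (floor of the midpoint — a deterministic tie-break). Peaks
with amplitude below `min_intensity` (default 100) are discarded as false
positives; the filter is applied to the profile the caller provides,
i.e. after background correction when correction is used. FWHM uses a
local baseline — the mean of the two flanking minima — rather than global
zero, because profiles sit on residual hyphal fluorescence; half-maximum
crossings are located by linear interpolation, and a peak whose crossing
runs off the array edge is flagged with an undefined width rather than a
guess. The width is invariant under adding a constant to the profile and
scales linearly with the pixel size.

Ring identity over time uses fixed ROIs (default 10 px along the hypha ×
20 px across it, centred on the ring) with no tracking: rings do not
migrate along sporogenic hyphae, and fixed ROIs match the manual
procedure the automation replaces. With a single ring the aggregate
trace's SEM is reported as 0 and flagged as undefined.

## Spore statistics (`zring.spore_stats`)

Grand mean and SD over pooled lengths; the 95% CI is computed on the
replicate means with a t critical value on n_reps − 1 degrees of freedom
(matching the standard three-replicate, 350-spores-per-replicate design
the generator defaults to). One replicate leaves the CI undefined and
flagged. Synthetic lengths are normal truncated at zero by resampling; at
realistic coefficients of variation (~15%) the truncation shifts the mean
negligibly.

## Windowed ChIP enrichment (`chip`)

Windows are half-open `[start, start+30)` at 0-based starts advancing by
15 bp; depth input is 1-based per the depth-utility convention and
bedgraph output 0-based half-open per that standard (adjacent output
intervals therefore overlap by 15 bp). The background window is truncated
at contig ends without wrapping — the chromosome is linear. Division by a
zero background mean yields a missing value, not 0 or infinity:
zero-coverage regions carry no evidence. Missing values are excluded from
Spearman correlation, replicate means and significance, and are omitted
from bedgraph output (interior gaps are restored as missing on re-read).
Significance is upper-tail by default (enrichment, not depletion), with a
two-sided option and optional Benjamini–Hochberg q-values (off by
default; the per-window z and p are the primary outputs and no peak
merging is performed). The entire statistic is scale-free: multiplying
all depths by a constant leaves every ratio unchanged.

The coverage generator draws negative-binomial counts parameterized by
mean m and dispersion r (variance m + m²/r), the standard overdispersion
model for sequencing coverage, reducing to Poisson as r → ∞; planted
regions multiply the replicate mean only. It does not model read-level
artefacts (GC bias, mappability, fragment-length autocorrelation), so
calibration results certify the statistic under exchangeable
overdispersed noise, not under real library structure.

## Kinetics (`kinetics`)

Absorbance is converted to Pi through a fitted linear standard curve; the
fitted intercept doubles as the assay blank, so inversion is
blank-corrected without a separate per-timepoint subtraction. Quenching
with an equal volume of perchloric acid halves all concentrations; the
constant `QUENCH_DILUTION = 2.0` is applied symmetrically in the
generator (producing absorbances of quenched samples) and the estimator
(scaling back to reaction-tube Pi), and is overridable for assays with a
different quench ratio.

The "linear range" of a saturating progress curve is chosen
automatically and deterministically: among all contiguous windows of at
least three points, maximize r² (rounded to 10 decimals to absorb
floating-point ties), prefer the longest window, then the earliest. A
noiseless linear series selects the full range; a linear-then-flat series
selects exactly the linear prefix. A manual override is available for
curves where the automatic rule is inappropriate. A perfectly flat
window is treated as exactly fitted (r² = 1, slope 0).

The critical concentration uses OLS of rate on concentration with
`Cc = −intercept/slope`, defined only for positive slopes. Its 95% CI is
delta-method propagation of the coefficient covariance with t(n−2)
critical values — closed-form and deterministic, adequate at the small
designs used in practice (four concentrations, duplicate reactions); a
bootstrap would add noise without adding validity at n = 8. The recovery
simulations adopt that design with rate noise SD 0.08 µM Pi/min (~2–8% of
the simulated rates, a realistic technical-duplicate precision); truth
values (Cc 1.43 µM, slope 1.9 µM Pi·min⁻¹ per µM) sit in the regime the
assay is used for. Molar ratios invert each protein's calibration curve
to mass, divide by molecular weight, and report the mole ratio, flagging
signals outside the calibrated range rather than refusing them.

## Determinism and configuration

Every generator is a pure function of (truth, seed) using
`numpy.random.default_rng`; identical inputs give byte-identical outputs.
`RunConfig` carries the pipeline constants (30/15/3000 bp, intensity 100,
ROI 10×20, line width 5, 3 Otsu classes, ρ threshold 0.95, dilution 2.0)
and echoes any override into run reports. CLI exit codes: 0 success,
2 usage error, 3 data error.

## Known limitations

- No 2-D hypha segmentation or straightening: stacks are assumed already
  straightened, as in the manual workflow this package automates.
- The enrichment significance model assumes approximate normality of
  control-subtracted values; at very low coverage the ratio distribution
  is visibly skewed and the calibration degrades.
- The FWHM-after-correction bias described above: widths are best
  measured on uncorrected or locally baselined profiles when absolute
  accuracy matters, and the `ring_width` baseline handles sloping
  backgrounds only to first order.
- Linear-range selection can pick a deceptive window on non-monotone
  noise at very small n; the manual override exists for that case.
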