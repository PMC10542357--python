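# Methods

## Registration

Model: purely rigid, integer-pixel x–y translation per frame. The
estimator maximizes the zero-normalized cross-correlation (Pearson
correlation over the overlap region) between the shifted frame and a
reference image, searched exhaustively on the square
`[-max_shift, max_shift]²` (default `max_shift = 20` px, bounding the
search and covering plausible awake-preparation drift at 512 × 512).
Ties are broken toward the smallest displacement norm, then
lexicographically on `(dx, dy)`, so the estimate is deterministic; the
score is invariant to positive affine rescaling of intensities. Constant
(zero-variance) frames make the correlation undefined: the shift is
reported as `(0, 0)` with a NaN score and a low-confidence flag. Frames
whose peak score falls below `score_floor` (default 0.3) are kept but
flagged rather than dropped. No subpixel interpolation is attempted:
integer shifts leave intensities unresampled, and non-rigid or
within-frame (line-by-line) correction is out of scope.

The reference is the average of the *stable* frames, built in two
passes: pass 1 scores every frame by its peak NCC against the all-frame
mean and estimates its shift; pass 2 retains the frames at or above the
`(1 − stability_quantile)` score quantile (default `stability_quantile =
0.8`, i.e. the best 80%), applies their estimated shifts, and averages
them pixel-wise over their valid support (pixels never covered fall back
to the all-frame mean). Because only *relative* motion is identifiable
against a possibly offset mean image, the reference is anchored in the
first frame's coordinates: frame 0's pass-1 shift is subtracted from all
pass-1 shifts. With a motion path expressed relative to the first frame,
a noiseless movie is then recovered exactly as the negated path, and
re-registering a registered movie yields all-zero shifts.

Pixels exposed at the borders by a shift are marked invalid in the
movie's validity mask. Downstream ROI averages use only valid pixels; a
sample whose ROI is entirely invalid is masked, never imputed.

## Traces and ΔF/F

ROI fluorescence is the mean intensity over the ROI's valid pixels, one
sample per frame. Sample timestamps use the frame-start convention
(frame *k* at `origin_time + k · frame_period`), matching stimulus
marking on the acquisition clock; the default frame period is 33.3 ms
(frame scan) and line-scan tables enter via CSV with a declared sample
period (default 1 ms) through the identical code path.

The per-trial baseline `F₀` is the mean signal over the half-open window
`[onset − 10 000 ms, onset)`. The onset instant is excluded so
stimulus-locked signal can never contaminate the baseline. If the
recording covers less than the full 10 s, the mean is taken over what
exists and a truncation flag is set; an empty window or `F₀ ≤ 0` is an
error (the latter signals broken input, since raw fluorescence is
non-negative). `ΔF/F = (F − F₀)/F₀` is invariant to multiplicative gain;
under an additive offset *b* it transforms to `(F − F₀)/(F₀ + b)`, which
is documented and tested rather than corrected — no neuropil
subtraction, bleaching correction or smoothing is applied.

## Evoked responses

Detection: a trace responds to a trial when ΔF/F is at or above the
threshold (default 0.10, i.e. 10% above baseline) for at least
`min_consecutive` consecutive valid samples within
`(onset, onset + response_window]`. Defaults: window 2 000 ms and
`min_consecutive = 2` at frame-scan resolution, 500 ms and 5 at
line-scan resolution — the windows cover the GCaMP6s rise at each time
scale, and the run-length rule guards against single-sample noise
crossings (with ΔF/F noise σ ≈ 0.02 a lone 5σ excursion is rare, but a
run requirement makes false calls negligible for silent cells). Peak
ΔF/F is always reported; a fully masked window yields an indeterminate
call.

Latency is anchored to the first sample of the first *qualifying* run —
an isolated supra-threshold blip shorter than `min_consecutive` does not
set the latency — and, by default, linearly interpolated between the
preceding sub-threshold sample and that crossing sample, giving
sub-sample accuracy at 33.3 ms frames. The non-interpolated first-sample
rule is retained for audit. Noiseless latency shifts exactly with
transient onset and is invariant to fluorescence rescaling.

Population statistics: an ROI is a responder when it responds in at
least half of its trials (majority rule); fractions are computed per
field of view and summarized as mean ± SEM across fields. Latency modes
come from a Gaussian-kernel density evaluated on a 1-ms grid over
`[0, max latency + 3·bandwidth]` with the kernel standard deviation
equal to the bandwidth (default 5 ms — narrow enough to separate the
40/70 ms structure, wide enough to smooth n ≈ 40–90 samples); modes are
strict interior local maxima with density at least `peak_rel_floor`
(default 0.2) of the global maximum, which suppresses shoulder
artifacts. Percent reduction in latency is computed on population means,
`100·(μ_slow − μ_fast)/μ_slow`. The K–S statistic is the supremum of the
ECDF difference over all step points (computed exactly via sorted
searches); its p-value uses the plain asymptotic Kolmogorov distribution
at `√(n_a n_b/(n_a+n_b))·D`, which at n ≈ 40–90 agrees with the exact
null to a few tens of percent in the far tail — adequate for the
decisive separations this analysis reports. The fold-change readout is
the ratio of post-window to pre-window mean signal.

## Behavior scoring

von Frey: filaments in strictly ascending force; the threshold is the
lowest force with responses on at least `criterion` of `n_trials`
applications (defaults 3 of 5); if none qualifies, the highest filament
is returned with an explicit censored flag (the censoring force is
whatever the record supplies — no canonical ceiling is assumed). The
threshold is monotone non-increasing in every response count. Escape
latency is `first_escape_frame / fps` in exact rational arithmetic
(30 fps default). Cutoff clamping (`Hargreaves 20 s`, `hot plate 30 s`,
`beam 60 s`) is idempotent and records censoring explicitly instead of
dropping trials, so downstream means are reproducible.

## Synthetic data

The generator emulates the statistical structure the analysis must
resolve, not the optics. Transients use a saturating-rise /
exponential-decay surrogate, `A·(1 − e^{−Δ/τ_r})·e^{−Δ/τ_d}` past the
onset, with GCaMP6s-like defaults `τ_r = 20 ms`, `τ_d = 1 500 ms`. The
amplitude parameter is defined as the transient's *peak* ΔF/F: the raw
kernel is rescaled by its closed-form peak factor so the rendered peak
equals `A` exactly. That makes the responder model analytic — with peak
amplitudes drawn `Exponential(mean m)` and detection at threshold θ, the
noiseless responsive fraction is `exp(−θ/m)`: mean 0.072 gives ≈ 24.9%
at θ = 0.10 (layer-5-like) and mean 0.0334 gives ≈ 5.0%
(layer-4-like). Sampling noise at the prescribed 7 fields × 40 ROIs is
about ±2.6 percentage points (binomial), and measurement noise slightly
*inflates* the detected fraction because the exponential density
concentrates just below the threshold, so noise promotes borderline
cells more often than it demotes them — both effects are visible in the
acceptance-scale runs and are properties of the operating point, not of
the estimator.

Traces are `F(t) = F₀·(1 + transient(t)) + ε`, ε Gaussian with σ a
fraction of F₀ (default 0.02), clipped at zero. Latency samples come
from Gaussian mixtures truncated at zero (point masses allowed), e.g.
`0.68·δ(40 ms) + 0.32·δ(70 ms)` versus `δ(70 ms)`, whose mixture mean
49.6 ms yields the 29.1% reduction analytically. Movies render somata as
Gaussian blobs (ROI masks are the half-maximum cores) modulated by their
traces on a zero background, then apply a rigid integer shift path and
noise; the zero background means the extracted ROI ΔF/F equals the
generative ΔF/F exactly in the noiseless case. Behavior tables draw
Binomial(5) filament responses from a logistic force–response curve
(infinite slope = step) and escape frames from a stated latency law at
30 fps. Every generator is a pure function of (config, seed) and emits a
ground-truth record (responder flags, amplitudes, onsets, shift path,
noiseless signals).

What the generator does *not* emulate: optics (PSF, depth attenuation),
shot noise by default, neuropil contamination, non-rigid or rotational
motion, bleaching, and overlapping/irregular somata. Passing tests
therefore certify the estimators against the stated statistical
structure, not robustness to those real-data effects.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to keep the
closed-form structure intact: 64 × 64-pixel scenes with ≤ 6 px shifts for
registration (the estimator is size-agnostic; 512 × 512 changes only run
time), 7 fields × 40 ROIs × 3 trials at 33.3 ms sampling for responder
fractions, 1 kHz noiseless traces for latency closed forms, and
n = 92/39 latency samples mirroring the populations being emulated.
Baseline windows always hold the full 10 s before each trial. Float
comparisons in round-trip I/O use 17-significant-digit formatting with
round-trip parsing, which preserves float64 bit-exactly. Degenerate
inputs fail loudly (empty ROIs, non-positive baselines, constant frames,
sub-minimum mode samples) rather than returning silent defaults.

## Known limitations

Integer-pixel registration leaves up to half a pixel of residual motion;
the absolute anchor of the registered coordinate frame is frame 0 by
convention. The majority rule, response windows, KDE bandwidth/floor and
`min_consecutive` defaults are analysis choices exposed as parameters —
other defensible choices shift responder fractions by a point or two at
the operating point above. The asymptotic K–S p-value is anti-
conservative at very small n; for n < ~20 per group an exact test should
be preferred.
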