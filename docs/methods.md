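# Methods

`wormstate` analyzes recordings of *C. elegans* confined to microfluidic
chambers, where animals spontaneously enter a sleep-like quiescent state.
This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices behind the defaults.

## Behavioral activity and sleep detection

Activity is quantified by frame-by-frame subtraction: for each pair of
consecutive frames, the number of pixels inside an animal's ROI whose grey
value changes by strictly more than `pixel_delta_threshold` (default 30
grey levels, well above CMOS read noise; 400 for the high-dynamic-range
RIS rig). Differences are computed on widened signed integers so unsigned
frames cannot wrap. The raw count series is smoothed with a centered
moving average over `smoothing_window_s` (default 20 s; the window is
truncated at the trace edges, and a zero window disables smoothing for
fine-timescale stimulus analyses) and divided by its
`norm_percentile`-th percentile (default 95, linear interpolation between
order statistics). Normalized activity is approximately in [0, 1]; the
top tail may exceed 1 and is not clipped.

Sleep bouts are maximal runs of normalized activity strictly below a
chamber-geometry threshold (WorMotel 0.15, 500-µm chambers 0.15, 110-µm
0.08, 50-µm 0.06, RIS rig 0.2). Two cleanup rules apply **in this
order**: (1) runs separated by supra-threshold gaps strictly shorter than
`max_twitch_s` (15 s) are merged — brief twitches do not wake the animal;
(2) merged runs shorter than `min_bout_s` (30 s) are discarded. Merging
first is the only order under which a long bout interrupted by a single
twitch survives the minimum-length filter as one unit. Bouts are
half-open `[start, end)` intervals in seconds at frame resolution, so
bout and wake lengths tile the recording exactly; a bout truncated by the
recording end is kept if its observed length passes the minimum.

Bout statistics: total sleep, sleep fraction, onset (start of first
bout), per-bout lengths, wake-bout lengths (gaps between bouts plus the
terminal gap, excluding the period before the first bout), and
homeostasis pairs — each bout after the first paired with the length of
the wake bout immediately preceding it.

### Known bias of the smoothed detector

A 20-s moving average displaces threshold crossings: with typical wake
activity A and threshold θ, each detected bout shrinks by roughly
`2 · (w/2 − w·θ/A)` seconds (w = smoothing window), about 10–14 s per
bout at θ = 0.15. Consequently (i) bouts shorter than ~45 s may fall
below the 30-s minimum and be missed, and (ii) total sleep is slightly
underestimated (≈3% under the default synthetic conditions, where mean
bout length is 270 s). Boundary offsets are bounded by w/2 because the
wake process is bounded away from the threshold (see below). A 20-s
wake-level interruption smears into a ≥15-s supra-threshold gap and
reliably splits a bout, but an interruption whose amplitude barely
exceeds the threshold is invisible to a 20-s-smoothed detector — an
inherent property of the method, not of this implementation.

## Posture and dimensionless curvature

Per frame: background subtraction, contrast stretch, Otsu threshold,
small-object removal, Gaussian smoothing of the mask (σ = 1 px),
skeletonization, and extraction of the maximal-geodesic path between
skeleton endpoints (double BFS sweep; exact on trees). The path is
smoothed with a 7-px moving average — the three-point circle fit is
otherwise dominated by half-pixel skeleton jitter — and resampled to 20
points equally spaced in arclength. A circle is fit through every three
adjacent points (circumradius R = abc/4K; triangle area below 1e-9 px²
counts as collinear, curvature 0), giving 18 local curvatures in 1/px;
their mean times the body length is the dimensionless curvature. The
measure is symmetric under reversing point order, so head and tail are
never assigned.

No tip extension is applied: the rendered (and real) worm body ends in
rounded caps from which skeletonization retreats by about the cap radius,
so raw skeleton arclength tracks the centerline length (within ~4% on
synthetic straight worms). Tip extension was evaluated and rejected — it
broke 90°-rotation invariance of the extracted curvature (0.04% change
without it, ~6% with).

Quality gate: frames whose body length falls below 80% of the animal's
average (self-coiled postures foreshorten the skeleton) are marked
invalid. The reference is the whole-video mean by default; a running-mean
variant is available. State comparison smooths the per-frame value over
20 s (NaN-aware) and averages separately inside and outside sleep bouts.

## Calcium-trace processing

Single-channel: traces are smoothed over 3 s, then
`dF/F(t) = [F(t) − F0(t)] / F0(t)` with `F0(t) = min F over [0, t]`
(running minimum). This makes dF/F ≥ 0, zero at each new minimum, and
invariant under positive rescaling of F; the running minimum also absorbs
monotone photobleaching. Neuron signals come from 8×8 px ROI means;
the RIS soma signal is the mean of the 20 brightest pixels in a 25×25 px
window around the tracked centroid (robust to small centroid error).

Two-color: `R = (dF/F)_GCaMP / (dF/F)_mKate`,
`dR/R = [R − R0]/R0` with R0 the lower 20th-percentile value of R (same
percentile convention as activity normalization). The mKate dF/F is
exactly zero wherever its running minimum is attained, so the denominator
is floored at `denom_floor` (default 0.01, config-exposed and logged in
the trace metadata). The ratio cancels motion and bleaching common to
both channels.

Behavior–fluorescence correlation: both series are split into
non-overlapping 10-min windows; Pearson r is computed per window.
Constant windows have undefined r and are skipped with a warning. The
shuffle control re-pairs behavior windows with uniformly permuted
fluorescence windows (identity permutation allowed; exclusion available
and changes results by at most ~1/n_windows); the pooled mismatched-pair
correlations form the null distribution. Its mean is compared with zero
at the scale of one experiment's standard error, SD/√n_windows; note the
allowed identity pairings contribute a deterministic bias of order
−1/n_windows, which is well inside that scale for ≥10 windows.

The displacement behavior metric for whole-brain recordings is the mean
Euclidean per-frame displacement of the tracked neurons (NaN positions
excluded with a warning), then smoothed and normalized exactly like a
frame-difference trace. Sleep bouts for whole-brain data may be supplied
from a manual annotation in place of the detector.

## Stimulus responses and resampling statistics

Pre-stimulus state is the mean normalized activity over the 10 s before
the stimulus: quiescent < 0.08, low-activity wake in [0.08, 0.35]
(boundaries inclusive, following the printed interval), high-activity
wake above. The response is the mean over `(stim + 2 s, stim + 10 s]` —
the first 2 s are excluded because valve actuation itself displaces the
animal; light-stimulus analyses use a zero artifact window.

Fraction awake: a trial counts awake if its post-stimulus mean exceeds
the sleep threshold (config-exposed; default the 50-µm value 0.06). The
uncertainty is the SD of the fraction over 5000 bootstrap resamples of
trials. Group differences use a permutation test on the difference in
fractions: pooled outcomes, labels reassigned preserving group sizes,
two-sided add-one Monte-Carlo p-value `(1 + #{|Δ*| ≥ |Δ|})/(1 + n_iter)`
(never zero), multiplied by the Bonferroni factor and capped at 1. On
binary outcomes the test is conservative by discreteness; its measured
type-I rate at α = 0.05 is ≈3–4.5%.

## Puncta counting

Per frame: background subtraction (clamped at 0); a 3×3 median filter
and threshold produce the animal-body mask (filled, dilated 2 px).
Inside the mask the image is enhanced by adding its response to a
zero-sum 3×3 high-frequency kernel (center 8/9, neighbors −1/9) — an
unsharp enhancement that roughly doubles the contrast of objects smaller
than the kernel while leaving flat regions unchanged and, crucially,
preserving blob pixel areas. The enhanced image is binarized at a fixed
grey-level threshold (default 100 on the background-subtracted scale; an
adaptive mean + k·SD mode exists but is not the default, because bright
puncta inflate the ROI SD enough to mask themselves), and 8-connected
components with area in [2, 30] px are counted. Per 5-min timepoint,
seven frames are captured and the mean of the three largest counts is
reported, which discounts frames blurred by animal movement.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth, so the full analysis is testable without raw video.

**Bout schedules.** Alternating wake/sleep; wake ~ Exp(240 s); sleep ~
Exp(240 s) truncated below at 30 s (equivalently 30 s + Exp(240 s)), so
every true bout is detectable in principle. No generative model for bout
durations is established for this system; the truncated exponential is a
stand-in chosen for its long tail and closed-form mean (checkable by
Monte Carlo). The defaults describe a sleep-rich constrained-chamber
condition (≈50% sleep, mean bout 4.5 min). Twitches are a Poisson
process (0.5/min) inside sleep intervals, durations U[1, 10] s, with a
30-s refractory separation: twitches are discrete motor events, and the
separation guarantees a cluster cannot smear (under 20-s smoothing) into
a ≥15-s gap that would ambiguously split a bout.

**Activity traces.** Wake activity is a lognormal AR(1) process
(σ = 0.7, correlation time 60 s) around a mean count of 400, clipped to
[0.5, 2.5]× the mean. Real wake traces fluctuate strongly rather than
sitting at a plateau, which is what makes 95th-percentile normalization
meaningful; the clip encodes two physical facts — a swimming animal
never stops flipping pixels, and the count is bounded by the ROI size —
and guarantees that normalized wake activity stays above every sleep
threshold, so a state change is the only route below it. Quiescence
emits 2% of the wake mean (residual pumping/drift); a twitch raises the
trace to 35% of the wake mean — a sub-locomotion amplitude whose
20-s-smoothed excursion stays below a 15-s effective gap.

**Worm videos.** During wake the centerline is a traveling sinusoid
(amplitude 7 px, wavelength 50 px, 0.5 Hz on an 80-px worm) advancing
each frame; during sleep it freezes into a circular arc whose
20-point-discretized dimensionless curvature equals
`sleep_curvature_gain` (default 1.15) times the mean wake value — the
arc's turn angle is solved numerically against the same discrete measure
the analysis uses, so the configured gain is recovered by construction.
Twitches rotate the frozen posture by 4° with alternating sign. The worm
is rasterized as an anti-aliased constant-brightness curve of width 5 px
via a distance transform, plus Gaussian pixel noise. Not emulated:
hydrodynamics, optics (PSF, shot noise), eggs/debris, multi-animal
occlusion — so passing tests demonstrate correctness of the measurement
pipeline, not robustness to real-world segmentation hazards.

**Fluorescence.** Ordinary neurons emit a per-neuron scaled level, ×0.5
during sleep; a `ris_like` channel has the opposite (sleep-active)
pattern; a "red" reference channel is state-independent. All channels
decay as exp(−t/τ_bleach); noise is additive Gaussian. With zero noise
the configured sleep/wake contrast is exact after dividing out the
bleach factor, which the tests exploit.

**Puncta images.** A dim body ellipse plus compact blobs of exact pixel
area (nearest-to-center pixel sets), placed by rejection sampling with a
separation margin so no two touch (infeasible packing raises).
Out-of-range control blobs (e.g. 1 px and 40 px) can be rendered while
excluded from the truth inventory. Puncta brightness (180 over a body
level of 30) is far above the binarization threshold, so on these images
the counter recovers truth exactly; real images with dim or touching
puncta will undercount, as low-magnification imaging does.

All generators draw every random quantity from a single seeded
`numpy.random.default_rng`; identical seed and config give bit-identical
output.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run: 1000 random binary traces
(100–10,000 frames) against the brute-force bout oracle; 50 two-hour
3-fps traces for parameter recovery; one 10-min rendered video
end-to-end; 1000 random traces for dF/F invariants; 100 series for the
R0 percentile oracle; 20 ten-minute windows with 5000 shuffles for the
correlation control; 5000 bootstrap iterations and 1000 null simulations
(5000 permutations each) for the stimulus statistics; 100 puncta images
with 0–20 puncta; and 3 conditions × 10 traces for the minimum-bout
sensitivity harness. These sizes keep every stochastic check several
standard errors away from its tolerance.

## Limitations

- The smoothed detector's boundary bias (above) is inherent; analyses at
  fine timescales should disable smoothing, as the stimulus module does.
- Centerline extraction assumes a single connected animal well separated
  from debris; the 80%-length gate catches coiling but not crossing
  animals.
- The permutation test's conservatism on binary data means its real
  false-positive rate sits below the nominal α.
- The synthetic wake process is stationary; real animals show slow
  drifts (satiety, temperature) that the normalization only partly
  absorbs.
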