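# Methods

This note records the models, algorithms, parameter choices and known
limitations of `saccadekit`, in the order data flows through the package.

## Saccade waveform model

Each simulated saccade is a 1-D displacement profile built from a pair of
shifted soft ramps,

    w(t) = η · [ ρ(t; κ) − ρ(t − τ/η; κ) ],      ρ(t; κ) = κ · ln(1 + e^{t/κ}),

with time `t` in milliseconds. The parameters and their defaults
(uniform sampling ranges):

| parameter | range | units | meaning |
|---|---|---|---|
| τ (tau) | 2–6 | dva | saccade amplitude; the asymptotic displacement is exactly η·(τ/η) = τ |
| η (eta) | 0.45–0.65 | deg/ms | asymptotic main-sequence peak velocity (450–650 deg/s) |
| c | 4.5–7.5 | – | steepness factor; ramp time constant κ = 0.6 ms · c |
| direction | 0–2π | rad | 2-D direction of the straight displacement |

The velocity profile is η·[σ(t/κ) − σ((t−τ/η)/κ)] (σ the logistic
function), a smooth bell whose peak speed has the closed form
**1000·η·tanh(τ/(4ηκ)) deg/s** — increasing and saturating with
amplitude, i.e. the family reproduces the saccadic main sequence. The
single free scale `RAMP_TIME_SCALE = 0.6 ms` was calibrated once against
textbook main-sequence values (a 4-dva saccade at mid-range parameters
peaks near 250 deg/s and lasts ≈ 40 ms between 5 deg/s crossings); over
the full ranges the family spans peak speeds ≈ 110–450 deg/s and
durations ≈ 25–60 ms, inside the physiological 20–100 ms band. A
property test sweeps the parameter box to enforce the duration band.

Numerical details: the ramp is evaluated via `logaddexp` (no overflow);
support is padded on each side until the analytic tail speed falls to
1 deg/s, so splicing into the surrounding fixation introduces a velocity
step below the 5 deg/s ground-truth cutoff; the sampled waveform is
shifted and rescaled so its final sample equals τ exactly (the rescale is
< 0.5% and is the reason sampled peak speeds sit marginally above the
closed form).

## Scanpath generation

A scanpath alternates `n_saccades + 1` fixations (durations uniform in
0.8–1.6 s; positions exactly constant) with `n_saccades = 20` saccades at
uniformly random directions, accumulated as an unbounded random walk
(amplitudes are small, so no screen-boundary handling). The default
sampling rate is 500 Hz. Measurement noise is i.i.d. Gaussian position
noise added independently to x and y, with SD on a 0.0–1.0 dva grid; it
is white by construction (no temporal correlation, no drift, tremor,
post-saccadic oscillations, blinks or pursuit — see Limitations).

Ground-truth events are labelled on the **noise-free** trace: the speed
is computed with the same Savitzky–Golay filter the detector uses, and
for each excursion at/above 5 deg/s the onset is the last sub-cutoff
sample before the peak and the offset the first sub-cutoff sample after
it. Using the same differentiation scheme for truth and detection keeps
timing comparisons free of filter-phase confounds. Intervals are 0-based
half-open `[onset, offset)`; `offset_t` is the time of the exclusive
boundary sample. Generation is bit-reproducible from the config seed and
asserts that exactly `n_saccades` events are found.

## Velocity estimation

Velocities are Savitzky–Golay first derivatives (polynomial order 2,
span 40 ms), scaled by the sample period to deg/s; speed is the Euclidean
norm of (vx, vy). The window is `round(span·fs)` forced odd upward: 21
samples at 500 Hz, 13 at 300 Hz, 7 at 150 Hz. Edges use the filter's
polynomial-fit handling. A useful closed form: white position noise of
SD s passes to per-component velocity noise of SD `s·fs/√(Σ i²)` — 18.0·s
deg/s at 500 Hz with the 21-sample window; this sets the whole
noise-vs-threshold phenomenology below. Recordings can be resampled
(anti-aliased polyphase, rational ratio to 1/1000) for sampling-rate
studies, e.g. 300 → 150 Hz.

## Adaptive threshold iteration

Starting from `theta_init` (default 100 deg/s, the low end of the
admissible 100–300 range — the characteristic failure mode of the
classical path is the threshold *climbing* from its start, which a low
initialization exposes), each update estimates a centre and spread from
all speed samples strictly below the current threshold and sets

    θ ← centre + λ·spread,

stopping when successive thresholds differ by less than 1 deg/s (or
after `max_iter = 100` updates). The estimator is either classical
(mean, SD with ddof = 1) or robust (median, 1.4826·MAD). λ defaults to 6
for the classical presets and 9 for the robust ones (their
best-performing values); both are exposed. The onset/offset base
threshold is `centre + 3·spread` of the final below-threshold set.

Degenerate inputs are handled explicitly:

* an empty below-threshold set ends the iteration at the previous
  threshold (`degenerate` flag);
* a robust spread below 1e-9 deg/s — possible only when most
  below-threshold samples are numerically identical, as on noise-free
  synthetic fixations where the differentiated speed is pure float
  roundoff — carries no scale information, so that update falls back to
  the classical moments (`mad_collapsed` flag). Any noise SD > 0 never
  triggers it.

With `excise = True`, before each estimate k = ⌊min_fixation_dur·fs/6⌋
samples (3 at 500 Hz, 2 at 300 Hz) are removed from both ends of every
below-threshold run — the near-threshold flanks adjacent to putative
saccades — with runs of ≤ 2k samples dropped entirely; the inter-saccadic
intervals are recomputed from the current threshold at every iteration.
On default scanpaths this discards ≈ 1% of the data.

## Event extraction

Maximal runs of speed strictly above the converged θ lasting at least
`min_saccade_dur = 10 ms` are putative saccades (runs separated by even a
single sub-threshold sample are not merged; the duration floor keeps
single-sample noise crossings out and is configurable). For each block
the onset is found by scanning backward to the first sample below the
onset threshold and on to the nearest local velocity minimum; a local
minimum is a sample ≤ both neighbours (ties break toward the block, i.e.
the shortest scan; trace edges count as +∞). The offset scan runs
forward below the mixed offset threshold

    θ_off = 0.7·θ_onset + 0.3·LocalNoise,

where LocalNoise is centre + 3·spread of the speed in the 40 ms
preceding the onset, computed with the same estimator family as the
threshold iteration (mean/SD classical, median/scaled-MAD robust). A
truncated pre-onset window is used as-is and flagged; an absent one
falls back to θ_onset. Events whose refined intervals overlap are
merged. The fixed baseline (θ_PT = 55, θ_ST = 45 deg/s) uses the same
block-finding and walking machinery with constant thresholds and no
LocalNoise term.

## Evaluation

Matching is greedy one-to-one in descending intersection-over-union of
the half-open sample intervals, accepting pairs with IoU strictly above
0.2; ties break by earlier true onset, then earlier detected onset. The
">20% sample overlap" criterion does not name a denominator; IoU was
chosen because it is symmetric (swapping the roles of true and detected
events swaps FP with FN and preserves TP and F1, which is also a
property test). Unmatched true events are FN, unmatched detections FP;
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean
(0 when undefined). Timing lags/jitters are the mean/SD (ddof = 1; a
single pair has jitter 0) of the detected-minus-true boundary
differences within a simulation, in ms — negative lag means the detector
places a boundary earlier than ground truth.

Statistical helpers follow the study design: a paired two-sided t-test
on per-simulation F1 differences with Bonferroni correction
(`min(1, p·n_comparisons)`; zero-variance differences are flagged, not
tested), Spearman rank correlation (average ranks on ties) for
noise-vs-improvement relations, and fixational noise quantified as
RMS-S2S — the RMS of successive sample-to-sample position differences
within fixational intervals, never across their boundaries (positional
RMS would conflate drift; for white noise of SD s, RMS-S2S → s·√2).

`run_benchmark` sweeps noise × λ × algorithm × replicate. Per-replicate
seeds derive from `SeedSequence((master_seed, noise_index, replicate))`,
and all algorithms and λ values within a replicate run on the *same*
trace, so F1 comparisons are paired as the t-test assumes. The default
is 50 replicates per noise level — enough to put the standard error of a
mean F1 difference near 0.005 while keeping the full sweep under a
minute on one CPU.

## What the simulation does and does not show

The generator emulates the one thing the detector is sensitive to — the
ratio between fixation velocity noise and saccadic peak velocities, under
exactly known ground truth — and it does that with white position noise
on perfectly stationary fixations. Real recordings add drift, tremor,
microsaccades, post-saccadic oscillations, pursuit, blinks and
tracker-specific artifacts, all absent here; passing tests therefore
demonstrate the statistical behaviour of the threshold estimators, not
end-to-end performance on any particular eye tracker. Two consequences
observed in the shipped benchmarks are worth stating plainly:

* the fixed 55/45 deg/s baseline only degrades once noise alone can
  cross 55 deg/s (position SD ≳ 0.8 dva given the 18·s amplification
  above); with white noise there is no mechanism for it to fail at
  moderate noise;
* the classical λ = 10 iteration is bistable: depending on the exact
  sub-threshold saccade-flank mass it either descends cleanly or sticks
  near/above its initialization, so its failures are close to
  all-or-nothing. Robust estimation removes this sensitivity, which is
  the point of the method.

## Known limitations

* No glissade/post-saccadic-oscillation classification, no
  acceleration-domain thresholds, no blink or pursuit handling.
* The soft-ramp saccade model has exponential velocity tails; its
  durations at a 5 deg/s cutoff run slightly long for the smallest
  amplitudes.
* `b_mode="percentile"` accepts a user-supplied scale constant
  (1/Q₇₅ of whatever standardized distribution is assumed for the
  outlier-free samples); only the normal constant 1.4826 is built in.
* CSV/JSON interchange only; no vendor eye-tracker formats.
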