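# saccadekit

Adaptive velocity-threshold saccade detection for eye-tracking data, with
**robust (median/MAD) threshold estimation**, a parametric scanpath
simulator with ground-truth labels, and an event-based evaluation
framework.

## The problem

Saccades — ballistic eye movements lasting 20–100 ms — are usually
detected by thresholding eye velocity. Data-driven thresholds of the form

```
θ_PT = μ + λ·σ
```

estimated iteratively from the velocity samples below the current
threshold adapt to each recording's noise level. But the sample mean μ
and standard deviation σ are inflated by the very saccades the threshold
is meant to detect ("masking"): at a given sampling rate saccades are
high-velocity outliers, so a non-robust estimate can drift upward until
low-amplitude saccades are missed. Replacing (μ, σ) with the **median μ′**
and the **scaled median absolute deviation**

```
σ′ = b · median(|x − median(x)|),   b = 1/Φ⁻¹(0.75) ≈ 1.4826
```

gives estimates with a 50% breakdown point: the below-threshold saccade
samples barely move them, the iteration converges lower and faster, and
detection improves markedly at high noise while the experimenter keeps a
meaningful confidence dial (λ).

The package implements four adaptive detector presets — `AT` /
`AT-excise` (classical mean/SD, with or without excision of 3 samples at
each flank of every inter-saccadic interval) and `AT-MAD` /
`AT-MAD-excise` (robust) — plus a fixed 55/45 deg/s baseline (`FIXED`).
Velocities come from Savitzky–Golay differentiation (order 2, 40 ms
span); detected peak blocks are walked out to local velocity minima below
an onset threshold μ + 3σ (backward) and a mixed offset threshold
0.7·θ_onset + 0.3·LocalNoise (forward). Detection quality is scored by
one-to-one event matching (intersection-over-union > 0.2), precision /
recall / F1, and onset/offset lag and jitter.

Because validation needs ground truth, the package ships a simulator:
2-D scanpaths of alternating fixations and parametric soft-ramp saccade
waveforms that reproduce the saccadic main sequence (amplitudes 2–6 dva,
peak speeds ≈ 110–450 deg/s), sampled at 500 Hz with additive white
Gaussian position noise (SD 0–1 dva). Ground-truth boundaries are the
5 deg/s crossings of the noise-free speed.

See `docs/methods.md` for the full model, parameter and design notes.

## Worked example

```bash
$ saccadekit simulate --seed 7 --noise 0.6 -o demo
simulated 20 saccades over 27.2 s at 500 Hz (noise_sd=0.6 dva) -> demo

$ saccadekit detect demo/gaze.csv --preset AT-MAD --lambda 6 -o demo/events_mad.csv
AT-MAD: estimator=robust, lambda=6, iterations=2, converged=True
theta history (deg/s): 100.0, 57.9, 56.9
theta_pt=56.90 deg/s, theta_onset=34.96 deg/s
21 events -> demo/events_mad.csv

$ saccadekit detect demo/gaze.csv --preset AT --lambda 6 -o demo/events_at.csv
AT: estimator=classical, lambda=6, iterations=5, converged=True
theta history (deg/s): 100.0, 78.3, 68.0, 62.9, 61.0, 60.5
theta_pt=60.52 deg/s, theta_onset=37.27 deg/s
21 events -> demo/events_at.csv

$ saccadekit evaluate --true demo/ground_truth.csv --detected demo/events_mad.csv
TP=20 FP=1 FN=0  precision=0.9524 recall=1.0000 F1=0.9756
onset lag=+3.90 ms jitter=3.52 ms; offset lag=-1.80 ms jitter=3.78 ms
```

At this moderate noise level (0.6 dva) the robust iteration stops after
two updates at 56.9 deg/s, while the classical one needs five updates and
settles 3.6 deg/s higher — the masking bias of the mean/SD path. Both
still find all 20 simulated saccades here; the robust advantage grows
with noise, where the classical threshold climbs above the slowest
saccade peaks. Positive onset lag means the detected onsets trail the
ground-truth 5 deg/s crossings by ~2 samples on average.

The same sweep is available from Python:

```python
from saccadekit import run_benchmark
df = run_benchmark(noise_levels=(0.0, 0.5, 1.0), lambdas=(6.0,),
                   algorithms=("AT", "AT-MAD", "FIXED"),
                   n_replicates=10, master_seed=1)
print(df.groupby(["algorithm", "noise_sd"]).f1.mean().unstack().round(3))
```

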