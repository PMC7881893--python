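"""Adaptive peak-velocity threshold saccade detection.

The detector iterates a data-driven velocity threshold: starting from an
initial guess, all speed samples strictly below the current threshold are
used to estimate a centre and spread, and the threshold is updated to
``centre + lambda * spread`` until successive values differ by less than a
convergence tolerance.  Two estimators are available:

* ``classical`` - sample mean and standard deviation.  These moments are
  inflated by the saccades themselves (masking), so the converged
  threshold is biased upward, increasingly so at high noise.
* ``robust`` - median and scaled median absolute deviation (MAD).  With a
  50% breakdown point, the below-threshold saccade samples barely move the
  estimate, yielding a lower, outlier-insensitive threshold.

The MAD underestimates the standard deviation and is rescaled by
``b = 1.4826`` (the reciprocal of the normal distribution's 75th
percentile) under the default normality assumption.

Runs of samples above the converged threshold are putative saccades; each
is walked out to a local velocity minimum below a lower onset threshold
(``centre + 3 * spread``) backward, and below an offset threshold that
mixes the onset threshold with the locally measured pre-saccadic noise
forward.  A fixed-threshold baseline (55 / 45 deg/s) with the same
block-finding and refinement machinery is also provided.

Optionally, a fixed number of samples is excised from the flanks of every
inter-saccadic interval before estimating the threshold, discarding the
near-threshold velocities adjacent to saccades ("excise" variants).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .types import GazeRecording, SaccadeEvent
from .velocity import VelocityTrace, savgol_velocity

__all__ = [
    "EstimatorSpec",
    "DetectorConfig",
    "ThresholdResult",
    "MAD_NORMAL_CONSTANT",
    "PRESETS",
    "preset",
    "estimate_center_spread",
    "excision_count",
    "excise_flanks",
    "iterate_peak_threshold",
    "find_peak_blocks",
    "refine_onset",
    "refine_offset",
    "detect_saccades",
    "fixed_threshold_detect",
]

#: MAD-to-SD scale for a normal underlying distribution, 1 / Phi^{-1}(3/4).
MAD_NORMAL_CONSTANT = 1.4826

FIXED_PEAK_THRESHOLD = 55.0   # deg/s
FIXED_ONSET_THRESHOLD = 45.0  # deg/s

# Robust spreads below this level (deg/s) carry no physical scale
# information: they arise when more than half of the below-threshold
# samples are numerically identical (noise-free synthetic fixations, where
# the differentiated speed is pure float roundoff ~1e-12 deg/s).
_SPREAD_FLOOR = 1e-9


@dataclass(frozen=True)
class EstimatorSpec:
    """Choice of centre/spread estimator for the threshold iteration.

    ``kind`` selects classical (mean/SD) or robust (median/scaled MAD)
    estimation.  ``b_mode='normal_constant'`` fixes the MAD scale at
    1.4826; ``b_mode='percentile'`` lets the caller supply ``b_value`` as
    the reciprocal 75th percentile of whatever standardized distribution
    is assumed for the outlier-free samples.
    """

    kind: str = "classical"
    b_mode: str = "normal_constant"
    b_value: float = MAD_NORMAL_CONSTANT

    def __post_init__(self) -> None:
        if self.kind not in ("classical", "robust"):
            raise ValueError(f"estimator kind must be classical|robust, got {self.kind!r}")
        if self.b_mode not in ("normal_constant", "percentile"):
            raise ValueError(
                f"b_mode must be normal_constant|percentile, got {self.b_mode!r}"
            )
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.b_mode == "normal_constant" and self.b_value != MAD_NORMAL_CONSTANT:
            raise ValueError(
                f"b_mode='normal_constant' requires b_value={MAD_NORMAL_CONSTANT}"
            )


@dataclass(frozen=True)
class DetectorConfig:
    """All knobs of the adaptive threshold algorithm."""

    estimator: EstimatorSpec = field(default_factory=EstimatorSpec)
    lam: float = 6.0                  # threshold multiplier (lambda)
    theta_init: float = 100.0         # deg/s, initial peak threshold
    convergence_tol: float = 1.0      # deg/s
    max_iter: int = 100
    excise: bool = False
    min_fixation_dur: float = 0.040   # seconds
    local_noise_window: float = 0.040  # seconds
    onset_multiplier: float = 3.0
    offset_mix_weight: float = 0.7
    min_saccade_dur: float = 0.010    # seconds

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 100.0 <= self.theta_init <= 300.0:
            raise ValueError("theta_init must lie in [100, 300] deg/s")
        if self.convergence_tol <= 0 or self.max_iter < 1:
            raise ValueError("convergence_tol must be > 0 and max_iter >= 1")
        if not 0.0 <= self.offset_mix_weight <= 1.0:
            raise ValueError("offset_mix_weight must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DetectorConfig":
        data = json.loads(text)
        est = data.pop("estimator", None)
        known = set(cls.__dataclass_fields__) - {"estimator"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown DetectorConfig keys: {sorted(unknown)}")
        kwargs = dict(data)
        if est is not None:
            unknown_est = set(est) - set(EstimatorSpec.__dataclass_fields__)
            if unknown_est:
                raise ValueError(f"unknown EstimatorSpec keys: {sorted(unknown_est)}")
            kwargs["estimator"] = EstimatorSpec(**est)
        return cls(**kwargs)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the adaptive threshold iteration."""

    theta_pt: float                  # converged peak threshold, deg/s
    theta_onset: float               # onset/offset base threshold, deg/s
    center: float                    # mu or mu' of the final sample set
    spread: float                    # sigma or sigma' of the final sample set
    iterations: int
    theta_history: tuple[float, ...]
    converged: bool
    degenerate: bool = False         # below-threshold set became empty
    mad_collapsed: bool = False      # robust spread hit exactly 0; used mean/SD


def _classical(x: np.ndarray) -> tuple[float, float]:
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd


def _robust(x: np.ndarray, b: float) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, b * mad


def estimate_center_spread(
    x: np.ndarray, estimator: EstimatorSpec
) -> tuple[float, float]:
    """Centre and spread of speed samples under the chosen estimator.

    Classical: (mean, SD).  Robust: (median, b * MAD) where
    MAD = median(|x - median(x)|).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate centre/spread of an empty sample set")
    if not np.all(np.isfinite(x)):
        raise ValueError("speed samples must be finite")
    if estimator.kind == "classical":
        return _classical(x)
    return _robust(x, estimator.b_value)


def excision_count(fs: float, min_fixation_dur: float = 0.040) -> int:
    """Samples excised per flank: floor(min_fixation_dur * fs / 6).

    3 samples at 500 Hz, 2 at 300 Hz, 1 at 150 Hz.
    """
    return int(math.floor(min_fixation_dur * fs / 6.0))


def excise_flanks(
    intervals: list[tuple[int, int]], fs: float, min_fixation_dur: float = 0.040
) -> list[tuple[int, int]]:
    """Trim ``k`` samples from each end of each half-open interval.

    Intervals with no more than ``2k`` samples are dropped entirely.
    """
    k = excision_count(fs, min_fixation_dur)
    out = []
    for s, e in intervals:
        if e - s > 2 * k:
            out.append((s + k, e - k))
    return out


def _excised_mask(below: np.ndarray, k: int) -> np.ndarray:
    """Remove k samples at both ends of every True-run of ``below``."""
    if k == 0:
        return below
    mask = below.copy()
    n = len(below)
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i <= 2 * k:
            mask[i:j] = False
        else:
            mask[i : i + k] = False
            mask[j - k : j] = False
        i = j
    return mask


def iterate_peak_threshold(
    speed: np.ndarray, config: DetectorConfig, fs: float
) -> ThresholdResult:
    """Iterate the adaptive peak-velocity threshold to convergence.

    Each update estimates centre/spread from the samples strictly below
    the current threshold (optionally with inter-saccadic flanks excised)
    and sets ``theta = centre + lambda * spread``; the loop stops when the
    change falls below ``convergence_tol`` or after ``max_iter`` updates.

    Degenerate cases: an empty below-threshold set ends the iteration at
    the previous threshold with ``degenerate=True``; a robust spread at
    numerical-roundoff level (below 1e-9 deg/s, possible only when most
    below-threshold samples are numerically identical, as in noise-free
    synthetic fixations - the MAD then carries no scale information)
    falls back to the classical moments for that update and sets
    ``mad_collapsed=True``.
    """
    speed = np.asarray(speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise ValueError("speed trace must be finite")
    est = config.estimator
    k_excise = excision_count(fs, config.min_fixation_dur) if config.excise else 0

    theta = float(config.theta_init)
    history = [theta]
    center = spread = float("nan")
    converged = False
    degenerate = False
    mad_collapsed = False

    for _ in range(config.max_iter):
        below = speed < theta
        if config.excise:
            below = _excised_mask(below, k_excise)
        sel = speed[below]
        if sel.size == 0:
            degenerate = True
            break
        c_, s_ = estimate_center_spread(sel, est)
        if est.kind == "robust" and s_ < _SPREAD_FLOOR:
            c_cl, s_cl = _classical(sel)
            if s_cl > s_:
                c_, s_ = c_cl, s_cl
                mad_collapsed = True
        new_theta = c_ + config.lam * s_
        history.append(new_theta)
        center, spread = c_, s_
        if abs(new_theta - theta) < config.convergence_tol:
            theta = new_theta
            converged = True
            break
        theta = new_theta

    theta_onset = (
        center + config.onset_multiplier * spread
        if np.isfinite(center)
        else float("nan")
    )
    return ThresholdResult(
        theta_pt=theta,
        theta_onset=theta_onset,
        center=center,
        spread=spread,
        iterations=len(history) - 1,
        theta_history=tuple(history),
        converged=converged,
        degenerate=degenerate,
        mad_collapsed=mad_collapsed,
    )


def find_peak_blocks(
    speed: np.ndarray, theta_pt: float, min_saccade_dur: float, fs: float
) -> list[tuple[int, int]]:
    """Maximal runs of ``speed > theta_pt`` lasting at least
    ``min_saccade_dur`` seconds, as half-open index pairs.  Runs separated
    by even a single sub-threshold sample are not merged."""
    if theta_pt <= 0 or not np.isfinite(theta_pt):
        raise ValueError(f"theta_pt must be positive and finite, got {theta_pt}")
    above = np.asarray(speed) > theta_pt
    blocks = []
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if (j - i) / fs >= min_saccade_dur:
            blocks.append((i, j))
        i = j
    return blocks


def _is_local_min(speed: np.ndarray, j: int) -> bool:
    left = speed[j - 1] if j > 0 else np.inf
    right = speed[j + 1] if j + 1 < len(speed) else np.inf
    return speed[j] <= left and speed[j] <= right


def refine_onset(
    speed: np.ndarray, block: tuple[int, int], theta_onset: float
) -> tuple[int, bool]:
    """Walk the saccade onset out from a putative block.

    Scans backward from the block start to the first sample below
    ``theta_onset``, then continues backward to the nearest local velocity
    minimum (ties count as minima, so the scan is shortest).  Returns
    ``(onset_idx, flagged)``; flagged when the trace start is hit before
    the threshold is crossed or a minimum is found.
    """
    i = block[0] - 1
    while i >= 0 and speed[i] >= theta_onset:
        i -= 1
    if i < 0:
        return 0, True
    j = i
    while j >= 0:
        if _is_local_min(speed, j):
            return j, False
        j -= 1
    return 0, True


def local_noise_level(
    speed: np.ndarray,
    onset_idx: int,
    window: float,
    fs: float,
    estimator: EstimatorSpec,
) -> tuple[float, bool]:
    """Centre + 3*spread of the speed in the window preceding the onset.

    Uses the same estimator family as the threshold iteration (mean/SD on
    the classical path, median/scaled MAD on the robust path).  Returns
    ``(value, flagged)``; flagged when fewer samples than the full window
    are available.
    """
    w = int(round(window * fs))
    lo = max(0, onset_idx - w)
    seg = speed[lo:onset_idx]
    flagged = seg.size < w
    if seg.size == 0:
        return float("nan"), True
    c_, s_ = estimate_center_spread(seg, estimator)
    return c_ + 3.0 * s_, flagged


def refine_offset(
    speed: np.ndarray,
    block: tuple[int, int],
    threshold_result: ThresholdResult,
    config: DetectorConfig,
    fs: float,
    onset_idx: int,
) -> tuple[int, bool]:
    """Walk the saccade offset out past the end of a putative block.

    The offset threshold mixes the onset threshold with the local
    pre-saccadic noise level:
    ``theta_off = w * theta_onset + (1 - w) * LocalNoise`` with
    ``w = config.offset_mix_weight``.  The scan runs forward to the first
    sample below ``theta_off`` and on to the nearest local minimum.
    """
    noise, flagged = local_noise_level(
        speed, onset_idx, config.local_noise_window, fs, config.estimator
    )
    theta_onset = threshold_result.theta_onset
    if not np.isfinite(noise):
        theta_off = theta_onset
    else:
        w = config.offset_mix_weight
        theta_off = w * theta_onset + (1.0 - w) * noise
    n = len(speed)
    i = block[1]
    while i < n and speed[i] >= theta_off:
        i += 1
    if i >= n:
        return n - 1, True
    j = i
    while j < n:
        if _is_local_min(speed, j):
            return j, flagged
        j += 1
    return n - 1, True


def _blocks_to_events(
    speed: np.ndarray,
    t: np.ndarray,
    blocks: list[tuple[int, int]],
    onset_fn,
    offset_fn,
) -> list[SaccadeEvent]:
    """Refine blocks to events, merging any that overlap after refinement."""
    raw: list[tuple[int, int]] = []
    for blk in blocks:
        onset, _ = onset_fn(blk)
        offset, _ = offset_fn(blk, onset)
        if offset > onset:
            raw.append((onset, offset))
    merged: list[list[int]] = []
    for s, e in sorted(raw):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        events.append(
            SaccadeEvent(
                onset_idx=s,
                offset_idx=e,
                onset_t=float(t[s]),
                offset_t=float(t[min(e, len(t) - 1)]),
                peak_speed=float(np.max(speed[s:e])),
            )
        )
    return events


def detect_saccades(
    rec: GazeRecording,
    config: DetectorConfig | None = None,
    velocity: VelocityTrace | None = None,
) -> tuple[list[SaccadeEvent], ThresholdResult]:
    """Detect saccades in a recording with the adaptive threshold.

    Composition: Savitzky-Golay velocity -> threshold iteration -> peak
    blocks -> onset/offset refinement.  A precomputed ``velocity`` trace
    may be supplied (it must match the recording).  Returns the ordered,
    disjoint event list and the threshold iteration result.  The function
    is a pure, deterministic map of (recording, config).
    """
    if config is None:
        config = DetectorConfig()
    vel = velocity if velocity is not None else savgol_velocity(rec)
    if vel.n_samples != rec.n_samples:
        raise ValueError("velocity trace does not match recording length")
    speed = vel.speed
    thr = iterate_peak_threshold(speed, config, rec.fs)
    if not np.isfinite(thr.theta_pt) or thr.theta_pt <= 0 or not np.isfinite(thr.theta_onset):
        return [], thr
    blocks = find_peak_blocks(speed, thr.theta_pt, config.min_saccade_dur, rec.fs)
    events = _blocks_to_events(
        speed,
        rec.t,
        blocks,
        onset_fn=lambda blk: refine_onset(speed, blk, thr.theta_onset),
        offset_fn=lambda blk, onset: refine_offset(
            speed, blk, thr, config, rec.fs, onset
        ),
    )
    return events, thr


def fixed_threshold_detect(
    rec: GazeRecording,
    theta_pt: float = FIXED_PEAK_THRESHOLD,
    theta_st: float = FIXED_ONSET_THRESHOLD,
    min_saccade_dur: float = 0.010,
    velocity: VelocityTrace | None = None,
) -> list[SaccadeEvent]:
    """Fixed-threshold baseline detector (defaults 55 / 45 deg/s).

    Identical block-finding and onset/offset walking to the adaptive
    detector, but with constant thresholds and no local-noise term
    (``theta_SToffset == theta_STonset == theta_st``).
    """
    if not theta_pt > theta_st > 0:
        raise ValueError("require theta_pt > theta_st > 0")
    vel = velocity if velocity is not None else savgol_velocity(rec)
    speed = vel.speed
    n = len(speed)
    blocks = find_peak_blocks(speed, theta_pt, min_saccade_dur, rec.fs)

    def offset_fn(blk, onset):
        i = blk[1]
        while i < n and speed[i] >= theta_st:
            i += 1
        if i >= n:
            return n - 1, True
        j = i
        while j < n:
            if _is_local_min(speed, j):
                return j, False
            j += 1
        return n - 1, True

    return _blocks_to_events(
        speed,
        rec.t,
        blocks,
        onset_fn=lambda blk: refine_onset(speed, blk, theta_st),
        offset_fn=offset_fn,
    )


def _make_presets() -> dict[str, DetectorConfig]:
    classical = EstimatorSpec(kind="classical")
    robust = EstimatorSpec(kind="robust")
    return {
        "AT": DetectorConfig(estimator=classical, lam=6.0, excise=False),
        "AT-excise": DetectorConfig(estimator=classical, lam=6.0, excise=True),
        "AT-MAD": DetectorConfig(estimator=robust, lam=9.0, excise=False),
        "AT-MAD-excise": DetectorConfig(estimator=robust, lam=9.0, excise=True),
    }


#: Named adaptive presets; lambdas follow the best-performing values
#: (6 for the classical variants, 9 for the robust ones).  The fixed
#: baseline is exposed through :func:`fixed_threshold_detect` / "FIXED".
PRESETS = _make_presets()


def preset(name: str, lam: float | None = None) -> DetectorConfig:
    """Look up an adaptive preset, optionally overriding lambda."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)} (plus 'FIXED' "
            f"via fixed_threshold_detect)"
        )
    cfg = PRESETS[name]
    return replace(cfg, lam=lam) if lam is not None else cfg
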