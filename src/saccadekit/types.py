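"""Shared containers for gaze traces and saccade events.

Gaze position is expressed in degrees of visual angle (dva), time in
seconds, and all velocities in deg/s.  Event intervals are 0-based and
half-open: ``[onset_idx, offset_idx)``; ``offset_t`` is the time of the
(exclusive) boundary sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GazeRecording", "SaccadeEvent"]

# Relative tolerance on sample-period uniformity, in units of one period.
_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class GazeRecording:
    """A uniformly sampled 2-D gaze position trace.

    Parameters
    ----------
    t : ndarray
        Timestamps in seconds, strictly increasing and uniform.
    x, y : ndarray
        Horizontal / vertical gaze position in dva.
    fs : float
        Sampling rate in Hz.  Must agree with the spacing of ``t``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError(
                f"t, x, y must have equal length; got {len(t)}, {len(x)}, {len(y)}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(t) >= 2:
            dt = np.diff(t)
            period = 1.0 / self.fs
            bad = np.nonzero(np.abs(dt - period) > _UNIFORMITY_RTOL * period)[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"non-uniform sampling at index {i + 1}: "
                    f"dt={dt[i]:.9g} s, expected {period:.9g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SaccadeEvent:
    """One saccade as a half-open sample-index interval.

    ``onset_idx`` is the first sample of the event (the local velocity
    minimum, or the last sub-cutoff sample, preceding the high-velocity
    excursion); ``offset_idx`` is the exclusive boundary sample after it.
    """

    onset_idx: int
    offset_idx: int
    onset_t: float
    offset_t: float
    peak_speed: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not 0 <= self.onset_idx < self.offset_idx:
            raise ValueError(
                f"require 0 <= onset_idx < offset_idx, got "
                f"[{self.onset_idx}, {self.offset_idx})"
            )
        if np.isfinite(self.peak_speed) and self.peak_speed < 0:
            raise ValueError(f"peak_speed must be >= 0, got {self.peak_speed}")

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t
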