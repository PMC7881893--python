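"""CSV / JSON interchange for gaze recordings, events and run configs.

Gaze traces travel as plain CSV with header ``t,x,y`` (seconds, dva, dva)
plus a JSON sidecar carrying ``fs`` (and optionally ``noise_sd``/``seed``);
the method is eye-tracker agnostic, so no vendor formats are supported.
Event tables are CSV with 0-based half-open sample intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectorConfig
from .simulate import SimulationConfig
from .types import GazeRecording, SaccadeEvent

__all__ = [
    "read_gaze_csv",
    "write_gaze_csv",
    "read_events_csv",
    "write_events_csv",
    "EvaluationConfig",
    "RunConfig",
]

_GAZE_COLUMNS = ("t", "x", "y")
_EVENT_COLUMNS = ("onset_idx", "offset_idx", "onset_t", "offset_t", "peak_speed")
_FLOAT_FMT = "%.9g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_gaze_csv(
    rec: GazeRecording,
    path,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> None:
    """Write a recording to ``path`` with its JSON sidecar next to it."""
    path = Path(path)
    df = pd.DataFrame({"t": rec.t, "x": rec.x, "y": rec.y})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"fs": rec.fs}
    if noise_sd is not None:
        meta["noise_sd"] = noise_sd
    if seed is not None:
        meta["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_gaze_csv(path) -> GazeRecording:
    """Read a ``t,x,y`` CSV into a recording.

    The sampling rate comes from the JSON sidecar when present, otherwise
    it is inferred from the median timestamp spacing.  Uniform sampling is
    validated (tolerance 1e-6 of a period); a dropped sample raises with
    the first offending index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"expected header t,x,y")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        fs = float(json.loads(sidecar.read_text())["fs"])
    else:
        dt = np.diff(df["t"].to_numpy())
        if dt.size == 0:
            raise ValueError(f"{path}: need at least 2 samples to infer fs")
        fs = 1.0 / float(np.median(dt))
    return GazeRecording(
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        fs=fs,
    )


def write_events_csv(events: list[SaccadeEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_idx": ev.onset_idx,
                "offset_idx": ev.offset_idx,
                "onset_t": ev.onset_t,
                "offset_t": ev.offset_t,
                "peak_speed": ev.peak_speed,
            }
            for ev in events
        ],
        columns=list(_EVENT_COLUMNS),
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path) -> list[SaccadeEvent]:
    df = pd.read_csv(path)
    missing = [c for c in _EVENT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SaccadeEvent(
                onset_idx=int(row.onset_idx),
                offset_idx=int(row.offset_idx),
                onset_t=float(row.onset_t),
                offset_t=float(row.offset_t),
                peak_speed=float(getattr(row, "peak_speed", np.nan)),
            )
        )
    return events


@dataclass(frozen=True)
class EvaluationConfig:
    """Benchmark grid: overlap criterion, lambda grid, noise grid, replicates."""

    min_overlap: float = 0.2
    lambdas: tuple[float, ...] = (6.0,)
    noise_levels: tuple[float, ...] = tuple(
        float(v) for v in np.round(np.arange(0.0, 1.01, 0.1), 2)
    )
    replicates: int = 50
    algorithms: tuple[str, ...] = (
        "AT",
        "AT-excise",
        "AT-MAD",
        "AT-MAD-excise",
        "FIXED",
    )


@dataclass(frozen=True)
class RunConfig:
    """Full benchmark run description; JSON round-trips losslessly."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detector: str | DetectorConfig = "AT-MAD"
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    output_dir: str = "."
    master_seed: int = 0

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, (SimulationConfig, EvaluationConfig, DetectorConfig)):
                return {k: enc(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if hasattr(obj, "__dict__") and not isinstance(obj, str):
                return {k: enc(v) for k, v in obj.__dict__.items()}
            return obj

        payload = {
            "simulation": enc(self.simulation),
            "detector": (
                self.detector
                if isinstance(self.detector, str)
                else json.loads(self.detector.to_json())
            ),
            "evaluation": enc(self.evaluation),
            "output_dir": self.output_dir,
            "master_seed": self.master_seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")

        def load_dc(dc_cls, payload, tuple_fields=()):
            unknown = set(payload) - set(dc_cls.__dataclass_fields__)
            if unknown:
                raise ValueError(
                    f"unknown {dc_cls.__name__} keys: {sorted(unknown)}"
                )
            kwargs = {
                k: tuple(v) if k in tuple_fields or isinstance(v, list) else v
                for k, v in payload.items()
            }
            return dc_cls(**kwargs)

        kwargs = {}
        if "simulation" in data:
            kwargs["simulation"] = load_dc(SimulationConfig, data["simulation"])
        if "detector" in data:
            det = data["detector"]
            kwargs["detector"] = (
                det if isinstance(det, str) else DetectorConfig.from_json(json.dumps(det))
            )
        if "evaluation" in data:
            kwargs["evaluation"] = load_dc(EvaluationConfig, data["evaluation"])
        for key in ("output_dir", "master_seed"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)
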