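"""File formats and movie preprocessing.

Event tables travel as flat CSV (one row per event, footprints run-length
encoded) with a JSON metadata sidecar carrying the recording geometry; masks,
heatmaps, and stacks are TIFF; behavior and state traces are tidy CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import BehaviorTrace, StateLabels
from .events import REQUIRED_COLUMNS, EventTable

__all__ = [
    "RecordingMeta",
    "read_event_table",
    "write_event_table",
    "read_behavior_csv",
    "write_behavior_csv",
    "read_states_csv",
    "write_states_csv",
    "write_heatmap_tiff",
    "read_heatmap_tiff",
    "preprocess_movie",
]


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition metadata for one imaging session.

    The raw resonant-scanner frame rate (30.9 Hz) is temporally binned by an
    integer factor (3) to the analysis rate (10.3 Hz).
    """

    recording_id: str
    pixel_size_um: float = 94.0 / 512.0
    frame_rate_raw_hz: float = 30.9
    temporal_bin_factor: int = 3
    grid_shape: tuple[int, int] = (512, 512)
    n_frames: int = 0

    def __post_init__(self):
        if self.temporal_bin_factor < 1:
            raise ValueError("temporal_bin_factor must be >= 1")

    @property
    def frame_rate_analysis_hz(self) -> float:
        return self.frame_rate_raw_hz / self.temporal_bin_factor

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_analysis_hz


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_event_table(table: EventTable, path: str | Path) -> Path:
    """Write events as CSV plus a JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    table.df.to_csv(path, index=False)
    meta = {k: (list(v) if isinstance(v, tuple) else v) for k, v in table.meta.items()}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_event_table(path: str | Path) -> EventTable:
    """Read an event CSV with its JSON sidecar; errors name any missing field."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar {side} not found next to {path}")
    meta = json.loads(side.read_text())
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV {path} is missing column(s): {missing}")
    if "footprint" in df.columns:
        df["footprint"] = df.footprint.astype(str)
    return EventTable(df, meta)


def write_behavior_csv(trace: BehaviorTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.frame_times, "speed_cm_s": trace.speed, "touch": trace.touch}
    ).to_csv(path, index=False)
    return path


def read_behavior_csv(path: str | Path, frame_rate: float | None = None) -> BehaviorTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "speed_cm_s", "touch"):
        if col not in df.columns:
            raise ValueError(f"behavior CSV is missing column {col!r}")
    if frame_rate is None:
        dt = np.diff(df.time_s.to_numpy())
        if len(dt) == 0 or dt.min() <= 0:
            raise ValueError("cannot infer frame rate from time_s")
        frame_rate = 1.0 / np.median(dt)
    return BehaviorTrace(df.speed_cm_s.to_numpy(), df.touch.to_numpy(), float(frame_rate))


def write_states_csv(labels: StateLabels, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": np.arange(labels.n_frames) / labels.frame_rate,
            "base_state": labels.base_state,
            "sub_state": labels.sub_state,
        }
    ).to_csv(path, index=False)
    return path


def read_states_csv(path: str | Path, frame_rate: float | None = None) -> StateLabels:
    df = pd.read_csv(path)
    if frame_rate is None:
        dt = np.diff(df.time_s.to_numpy())
        frame_rate = 1.0 / np.median(dt)
    return StateLabels(
        df.base_state.to_numpy(dtype=object), df.sub_state.to_numpy(dtype=object), float(frame_rate)
    )


def write_heatmap_tiff(grid: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))
    return path


def read_heatmap_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def preprocess_movie(movie: np.ndarray, sigma: float = 1.0, bin_factor: int = 3) -> np.ndarray:
    """Smooth and temporally bin a raw 2P movie.

    Applies a 3D Gaussian filter (``sigma`` pixels in x, y, and t) and then
    mean-bins frames in time by ``bin_factor`` (30.9 Hz -> 10.3 Hz at the
    default factor of 3), discarding the trailing remainder frames.
    """
    from scipy.ndimage import gaussian_filter

    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (t, y, x)")
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    if movie.shape[0] < bin_factor:
        raise ValueError("movie has fewer frames than bin_factor")
    smoothed = gaussian_filter(movie, sigma=sigma)
    n_out = movie.shape[0] // bin_factor
    trimmed = smoothed[: n_out * bin_factor]
    return trimmed.reshape(n_out, bin_factor, *movie.shape[1:]).mean(axis=1)
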