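"""Behavioral-state segmentation from treadmill locomotion and vibrissa touch.

The animal's behavior on a cylindrical treadmill is reduced to four states:

* ``rest`` / ``run`` — base states from the rotary-encoder speed trace.  A
  running animal that pauses for less than the gap tolerance (1.5 s) is
  considered to be running continuously; longer pauses are rest.
* ``vibrissa_stimulation`` — the 1.5-s window following a vibrissa-pole touch
  while the animal runs (a substate of run).
* ``vibrissa_exploration`` — vibrissa touch while the animal is at rest
  (a substate of rest).

State transitions (rest-to-run, run-to-rest, touch onset during sustained
running) are extracted only when the flanking states are stable, so that
peri-transition statistics are not contaminated by hesitant behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "REST",
    "RUN",
    "SUB_NONE",
    "STIM",
    "EXPLORE",
    "STATES",
    "WheelGeometry",
    "BehaviorTrace",
    "StateLabels",
    "Transition",
    "speed_from_encoder",
    "segment_run_rest",
    "annotate_touch_states",
    "extract_transitions",
]

REST = "rest"
RUN = "run"
SUB_NONE = "none"
STIM = "vibrissa_stimulation"
EXPLORE = "vibrissa_exploration"
STATES = (REST, RUN, STIM, EXPLORE)

#: encoder speeds at or below this (cm/s) are treated as stationary
MOTION_EPSILON = 0.5


@dataclass(frozen=True)
class WheelGeometry:
    """Cylindrical treadmill with vibrissa-stimulation poles on its circumference."""

    radius_cm: float = 7.4
    n_poles: int = 1
    pole_spacing_cm: float | None = None
    ticks_per_revolution: int = 1024

    def __post_init__(self):
        if self.radius_cm <= 0:
            raise ValueError("radius_cm must be positive")
        if self.n_poles < 0:
            raise ValueError("n_poles must be nonnegative")
        if self.pole_spacing_cm is None:
            spacing = self.circumference_cm / self.n_poles if self.n_poles else np.inf
            object.__setattr__(self, "pole_spacing_cm", spacing)
        elif self.n_poles == 1:
            # a single pole touches once per revolution
            if abs(self.pole_spacing_cm - self.circumference_cm) > 0.01 * self.circumference_cm:
                raise ValueError(
                    "1-pole spacing must equal the wheel circumference "
                    f"({self.circumference_cm:.2f} cm) within 1%"
                )

    @property
    def circumference_cm(self) -> float:
        return 2.0 * np.pi * self.radius_cm


@dataclass
class BehaviorTrace:
    """Per-frame locomotion speed and binary vibrissa touch at the imaging clock."""

    speed: np.ndarray  # cm/s
    touch: np.ndarray  # 0/1
    frame_rate: float  # Hz

    def __post_init__(self):
        self.speed = np.asarray(self.speed, dtype=float)
        self.touch = np.asarray(self.touch).astype(np.int8)
        if self.speed.shape != self.touch.shape:
            raise ValueError("speed and touch must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.speed.size

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class StateLabels:
    """Per-frame behavioral state: base in {rest, run}, substate for touches."""

    base_state: np.ndarray  # array of REST/RUN strings
    sub_state: np.ndarray  # array of SUB_NONE/STIM/EXPLORE strings
    frame_rate: float

    def __post_init__(self):
        self.base_state = np.asarray(self.base_state, dtype=object)
        self.sub_state = np.asarray(self.sub_state, dtype=object)
        if self.base_state.shape != self.sub_state.shape:
            raise ValueError("base_state and sub_state must have equal length")
        bad = ~np.isin(self.base_state, (REST, RUN))
        if bad.any():
            raise ValueError(f"unknown base state {self.base_state[bad][0]!r}")
        if (np.isin(self.sub_state, (STIM,)) & (self.base_state != RUN)).any():
            raise ValueError(f"{STIM} only allowed on run frames")
        if (np.isin(self.sub_state, (EXPLORE,)) & (self.base_state != REST)).any():
            raise ValueError(f"{EXPLORE} only allowed on rest frames")

    @property
    def n_frames(self) -> int:
        return self.base_state.size

    def effective_state(self) -> np.ndarray:
        """Substate where present, base state otherwise — one state per frame."""
        out = self.base_state.copy()
        has_sub = self.sub_state != SUB_NONE
        out[has_sub] = self.sub_state[has_sub]
        return out

    def frames_in_state(self, state: str) -> np.ndarray:
        """Boolean frame mask for a base state or substate name."""
        if state == "all":
            return np.ones(self.n_frames, dtype=bool)
        if state in (REST, RUN):
            return self.base_state == state
        if state in (STIM, EXPLORE):
            return self.sub_state == state
        raise ValueError(f"unknown state {state!r}; expected one of {STATES} or 'all'")

    def seconds_in_state(self, state: str) -> float:
        return float(self.frames_in_state(state).sum()) / self.frame_rate


@dataclass(frozen=True)
class Transition:
    """A stable behavioral-state transition used for peri-event alignment."""

    kind: str  # rest_to_run | run_to_rest | stim_onset
    frame: int
    time_s: float
    pre_ok: bool = True
    post_ok: bool = True


def speed_from_encoder(
    tick_counts: np.ndarray, wheel: WheelGeometry, frame_rate: float
) -> np.ndarray:
    """Convert per-frame rotary-encoder tick counts to a speed trace in cm/s.

    ``speed = ticks/frame / ticks_per_rev * circumference * frame_rate``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    ticks = np.asarray(tick_counts, dtype=float)
    if (ticks < 0).any():
        raise ValueError("tick counts must be nonnegative")
    return ticks / wheel.ticks_per_revolution * wheel.circumference_cm * frame_rate


def segment_run_rest(
    trace: BehaviorTrace,
    gap_tolerance: float = 1.5,
    motion_epsilon: float = MOTION_EPSILON,
) -> StateLabels:
    """Label each frame rest or run, merging sub-tolerance pauses into run bouts.

    A zero-speed gap between two movement epochs is relabeled run when its
    duration is strictly less than ``gap_tolerance`` seconds (a gap of exactly
    the tolerance splits the bout).  Leading and trailing stationary frames
    are always rest.
    """
    if trace.n_frames == 0:
        raise ValueError("empty behavior trace")
    moving = trace.speed > motion_epsilon
    merged = moving.copy()
    # interior stationary gaps flanked by movement
    padded = np.concatenate(([True], moving, [True]))
    gap_edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(gap_edges[::2], gap_edges[1::2]):
        if start == 0 or stop == trace.n_frames:
            continue  # recording edge: stays rest
        if (stop - start) / trace.frame_rate < gap_tolerance:
            merged[start:stop] = True
    base = np.where(merged, RUN, REST).astype(object)
    sub = np.full(trace.n_frames, SUB_NONE, dtype=object)
    return StateLabels(base, sub, trace.frame_rate)


def annotate_touch_states(
    labels: StateLabels, trace: BehaviorTrace, stim_window: float = 1.5
) -> StateLabels:
    """Mark vibrissa substates from the binary touch train.

    Each touch onset on a run frame opens a half-open stimulation window
    ``[t, t + stim_window)`` intersected with run frames; touch frames while
    at rest are marked exploration.
    """
    if labels.n_frames != trace.n_frames:
        raise ValueError("labels and trace are not aligned")
    sub = labels.sub_state.copy()
    touch = trace.touch.astype(bool)
    onsets = np.flatnonzero(touch & ~np.concatenate(([False], touch[:-1])))
    n_win = int(np.ceil(stim_window * labels.frame_rate))
    run = labels.base_state == RUN
    for f in onsets:
        if run[f]:
            stop = min(f + n_win, labels.n_frames)
            window = np.arange(f, stop)
            sub[window[run[window]]] = STIM
    sub[touch & ~run] = EXPLORE
    return StateLabels(labels.base_state.copy(), sub, labels.frame_rate)


def extract_transitions(
    labels: StateLabels,
    pre_stable: float = 3.0,
    post_stable: float = 6.0,
    touch: np.ndarray | None = None,
) -> list[Transition]:
    """Find stable state transitions.

    A rest-to-run transition at frame ``f`` requires at least ``pre_stable``
    seconds of uninterrupted rest before and ``post_stable`` seconds of
    uninterrupted running from ``f`` on; run-to-rest is symmetric.  When a
    binary ``touch`` train is supplied, touch onsets flanked by sustained
    running on both sides are returned as ``stim_onset`` transitions.
    Transitions too close to the recording edges are dropped.
    """
    fr = labels.frame_rate
    n_pre = int(np.ceil(pre_stable * fr))
    n_post = int(np.ceil(post_stable * fr))
    base = labels.base_state
    n = labels.n_frames
    out: list[Transition] = []

    def stable(state: str, start: int, stop: int) -> bool:
        return start >= 0 and stop <= n and bool(np.all(base[start:stop] == state))

    for f in range(1, n):
        if base[f] == base[f - 1]:
            continue
        kind = "rest_to_run" if base[f] == RUN else "run_to_rest"
        before = REST if kind == "rest_to_run" else RUN
        after = RUN if kind == "rest_to_run" else REST
        if stable(before, f - n_pre, f) and stable(after, f, f + n_post):
            out.append(Transition(kind, f, f / fr))

    if touch is not None:
        touch = np.asarray(touch).astype(bool)
        if touch.size != n:
            raise ValueError("touch train and labels are not aligned")
        onsets = np.flatnonzero(touch & ~np.concatenate(([False], touch[:-1])))
        for f in onsets:
            if stable(RUN, f - n_pre, f) and stable(RUN, f, f + n_post):
                out.append(Transition("stim_onset", int(f), f / fr))

    out.sort(key=lambda t: (t.frame, t.kind))
    return out
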