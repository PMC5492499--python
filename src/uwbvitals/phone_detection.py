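"""Four-state dual-mode background-subtraction presence detector.

Runs over the near (phone) sensing region and distinguishes a hand-held
object that *stays and keeps micro-moving* (texting, scrolling, viewing)
from momentary movements and from plain background changes:

* **S1 no detection** -- running clutter tracks the scene.  A frame whose
  background-subtracted peak exceeds threshold 1 freezes the clutter as it
  stood ``k_margin`` frames earlier and moves to S2.
* **S2 transient** -- two residuals are watched: y against the running
  clutter and y-breve against the frozen one.  y-breve falling below
  threshold 1 means the event was momentary (back to S1).  If the running
  residual's peak stays below threshold 2 throughout a trailing window of
  ``t_y`` seconds the object is static: background change (S4).  If
  y-breve has stayed above threshold 1 for ``t_hold`` seconds while the
  windowed running residual still reaches threshold 2, the object is a
  used device: S3, ``phone_start``.
* **S3 phone detected** -- leaves to S1 (``phone_end``) when y-breve drops,
  or to S4 (``background_change``) when the object goes static.
* **S4 background change** -- one-frame absorbing state: the running
  clutter is re-seeded from the current frame and the detector returns to
  S1 on the next step.

The running clutter continues updating in S2/S3 (that is what makes y
distinguish micro-motion from a static object); the frozen copy is never
touched.  The hold timer counts consecutive frames with the y-breve peak
above threshold 1 and resets on any sub-threshold frame.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Deque, Literal

import numpy as np

from .clutter_removal import (
    ClutterState,
    FrozenClutter,
    freeze_clutter,
    subtract_background,
    subtract_frozen,
    update_clutter,
)
from .frames_io import FrameMatrix


class Mode(IntEnum):
    S1_NO_DETECTION = 1
    S2_TRANSIENT = 2
    S3_PHONE = 3
    S4_BACKGROUND_CHANGE = 4


@dataclass(frozen=True)
class DetectorConfig:
    threshold1: float = 3.0  # on max |y-breve|, ADC units
    threshold2: float = 0.8  # on max |y| within the t_y window
    t_hold_s: float = 1.2
    t_y_s: float = 1.0
    alpha: float = 0.8
    k_margin: int = 10

    def __post_init__(self) -> None:
        if not (self.threshold1 > self.threshold2 > 0.0):
            raise ValueError("require threshold1 > threshold2 > 0")
        if self.t_hold_s <= 0 or self.t_y_s <= 0:
            raise ValueError("hold and window times must be positive")

    def t_hold_frames(self, fs: float) -> int:
        return max(1, round(self.t_hold_s * fs))

    def t_y_frames(self, fs: float) -> int:
        return max(1, math.ceil(self.t_y_s * fs))


@dataclass(frozen=True)
class DetectionEvent:
    kind: Literal["phone_start", "phone_end", "background_change"]
    frame_index: int
    time_s: float


@dataclass
class DetectorState:
    state: Mode
    running: ClutterState | None
    frozen: FrozenClutter | None
    hold_frames: int
    y_window: Deque[float]
    frame_count: int
    history: Deque[ClutterState] = field(default_factory=deque)

    @classmethod
    def initial(cls, config: DetectorConfig, fs: float) -> "DetectorState":
        return cls(
            state=Mode.S1_NO_DETECTION,
            running=None,
            frozen=None,
            hold_frames=0,
            y_window=deque(maxlen=config.t_y_frames(fs)),
            frame_count=0,
            history=deque(maxlen=config.k_margin + 1),
        )

    @property
    def windowed_max_y(self) -> float:
        return max(self.y_window) if self.y_window else 0.0


def _absorb(state: DetectorState, frame: np.ndarray) -> None:
    state.running = update_clutter(state.running, frame)
    state.history.append(state.running)


def _freeze_now(state: DetectorState, config: DetectorConfig) -> FrozenClutter:
    k_transient = state.frame_count
    # early transients: clamp the margin to however much history exists
    earliest = state.history[0].frame_index
    margin = min(config.k_margin, k_transient - earliest)
    return freeze_clutter(state.history, k_transient, margin)


def detector_step(
    state: DetectorState,
    frame: np.ndarray,
    config: DetectorConfig,
    fs: float,
) -> tuple[DetectorState, DetectionEvent | None]:
    """Advance the state machine by one frame (mutates and returns state)."""
    frame = np.asarray(frame, dtype=float)
    event: DetectionEvent | None = None
    k = state.frame_count
    t = k / fs

    if state.running is None:  # first frame seeds the clutter
        state.running = ClutterState.from_first_frame(frame, config.alpha)
        state.history.append(state.running)
        state.y_window.append(0.0)
        state.frame_count += 1
        return state, None

    y = subtract_background(frame, state.running)
    max_y = float(np.max(np.abs(y)))
    state.y_window.append(max_y)

    if state.state == Mode.S4_BACKGROUND_CHANGE:
        # absorb the new scene and start over
        state.running = ClutterState.from_first_frame(frame, config.alpha)
        state.history.clear()
        state.history.append(state.running)
        state.frozen = None
        state.hold_frames = 0
        state.y_window.clear()
        state.y_window.append(0.0)
        state.state = Mode.S1_NO_DETECTION
        state.frame_count += 1
        return state, None

    if state.state == Mode.S1_NO_DETECTION:
        if max_y > config.threshold1:
            state.frozen = _freeze_now(state, config)
            state.state = Mode.S2_TRANSIENT
            state.hold_frames = 1  # this frame counts toward the hold
        _absorb(state, frame)
        state.frame_count += 1
        return state, None

    y_breve = subtract_frozen(frame, state.frozen)
    max_yb = float(np.max(np.abs(y_breve)))
    _absorb(state, frame)

    if state.state == Mode.S2_TRANSIENT:
        if max_yb <= config.threshold1:
            state.state = Mode.S1_NO_DETECTION
            state.frozen = None
            state.hold_frames = 0
        elif state.windowed_max_y < config.threshold2:
            state.state = Mode.S4_BACKGROUND_CHANGE
            event = DetectionEvent("background_change", k, t)
        else:
            state.hold_frames += 1
            if state.hold_frames >= config.t_hold_frames(fs):
                state.state = Mode.S3_PHONE
                event = DetectionEvent("phone_start", k, t)
    elif state.state == Mode.S3_PHONE:
        if max_yb <= config.threshold1:
            state.state = Mode.S1_NO_DETECTION
            state.frozen = None
            state.hold_frames = 0
            event = DetectionEvent("phone_end", k, t)
        elif state.windowed_max_y < config.threshold2:
            state.state = Mode.S4_BACKGROUND_CHANGE
            event = DetectionEvent("background_change", k, t)

    state.frame_count += 1
    return state, event


def run_detector(
    frames: FrameMatrix | np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    fs: float | None = None,
) -> list[DetectionEvent]:
    """Fold the detector over a phone-region frame matrix."""
    if isinstance(frames, FrameMatrix):
        data, fs = frames.data, frames.fs_slow
    else:
        data = np.asarray(frames, dtype=float)
        if fs is None:
            raise ValueError("fs required when frames is a bare array")
    if data.size == 0:
        return []
    state = DetectorState.initial(config, fs)
    events: list[DetectionEvent] = []
    for frame in data:
        state, event = detector_step(state, frame, config, fs)
        if event is not None:
            events.append(event)
    return events


def trace_states(
    frames: FrameMatrix | np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    fs: float | None = None,
) -> list[Mode]:
    """Per-frame state trace (state *after* processing each frame)."""
    if isinstance(frames, FrameMatrix):
        data, fs = frames.data, frames.fs_slow
    else:
        data = np.asarray(frames, dtype=float)
        if fs is None:
            raise ValueError("fs required when frames is a bare array")
    state = DetectorState.initial(config, fs)
    trace: list[Mode] = []
    for frame in data:
        state, _ = detector_step(state, frame, config, fs)
        trace.append(state.state)
    return trace
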