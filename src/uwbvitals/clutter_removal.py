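"""Exponential loopback clutter filter and dual-mode background subtraction.

The static background ("clutter") of a radar scene is tracked with a
recursive exponential average over slow time,

    c_k(t) = alpha * c_{k-1}(t) + (1 - alpha) * r_k(t),

and subtracted from each received frame, y_k(t) = r_k(t) - c_k(t).  A large
alpha adapts slowly but is robust to noise (0.97 for vital signs); a small
alpha adapts fast (0.8 for object detection).

For presence detection a second, *frozen* clutter is kept: the running
clutter captured ``k_margin`` frames before a detection transient, so that
an object which has since been absorbed into the running background still
stands out in y-breve_k(t) = r_k(t) - c_stopped(t).

Convention (fixed here, documented): y_k is computed against the clutter
*before* frame k is absorbed, i.e. y_k = r_k - c_{k-1}; the very first
frame seeds the clutter (c_0 := r_0) so y_0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import DimensionError, StateError

ALPHA_VITALS = 0.97
ALPHA_PHONE = 0.8
DEFAULT_K_MARGIN = 10


@dataclass(frozen=True)
class ClutterState:
    """Running clutter estimate.

    ``k`` counts frames absorbed so far; after absorbing frames ``0..j``
    the state holds c_j and ``k == j + 1``.
    """

    c: np.ndarray
    alpha: float
    k: int

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))

    @classmethod
    def from_first_frame(cls, frame: np.ndarray, alpha: float) -> "ClutterState":
        """Seed the filter with the first received frame (c_0 := r_0)."""
        return cls(c=np.array(frame, dtype=float), alpha=alpha, k=1)

    @property
    def frame_index(self) -> int:
        """Slow-time index of the last absorbed frame."""
        return self.k - 1


@dataclass(frozen=True)
class FrozenClutter:
    """Clutter captured ``k_margin`` frames before a detection transient."""

    c_stopped: np.ndarray
    k_transient: int
    k_margin: int

    def __post_init__(self) -> None:
        if self.k_margin < 0:
            raise ValueError("k_margin must be non-negative")
        object.__setattr__(self, "c_stopped", np.asarray(self.c_stopped, dtype=float))


def _check_length(frame: np.ndarray, c: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != c.shape:
        raise DimensionError(
            f"frame length {frame.shape} does not match clutter {c.shape}"
        )
    return frame


def update_clutter(state: ClutterState, frame: np.ndarray) -> ClutterState:
    """Absorb one frame into the running clutter (pure; returns a new state)."""
    if state.k == 0:
        return ClutterState(c=np.array(frame, dtype=float), alpha=state.alpha, k=1)
    frame = _check_length(frame, state.c)
    c_new = state.alpha * state.c + (1.0 - state.alpha) * frame
    return ClutterState(c=c_new, alpha=state.alpha, k=state.k + 1)


def subtract_background(frame: np.ndarray, state: ClutterState) -> np.ndarray:
    """y_k = r_k - c, using the clutter *before* this frame is absorbed."""
    if state.k == 0:
        raise StateError("clutter state not yet seeded with any frame")
    frame = _check_length(frame, state.c)
    return frame - state.c


def subtract_frozen(frame: np.ndarray, frozen: FrozenClutter) -> np.ndarray:
    """y-breve_k = r_k - c_stopped; never updates anything."""
    frame = _check_length(frame, frozen.c_stopped)
    return frame - frozen.c_stopped


def freeze_clutter(
    history: Sequence[ClutterState], k_transient: int, k_margin: int
) -> FrozenClutter:
    """Capture the clutter as it stood ``k_margin`` frames before a transient.

    ``history`` is an ordered buffer of recent running-clutter states; the
    state whose last absorbed frame is ``k_transient - k_margin`` is the
    frozen copy (equivalently alpha*c_{kt-km-1} + (1-alpha)*r_{kt-km}).
    """
    if k_margin < 0 or k_transient < k_margin:
        raise StateError("require k_transient >= k_margin >= 0")
    target = k_transient - k_margin
    for state in history:
        if state.frame_index == target:
            return FrozenClutter(
                c_stopped=state.c.copy(), k_transient=k_transient, k_margin=k_margin
            )
    raise StateError(
        f"clutter history does not reach frame {target}; buffer at least "
        f"k_margin + 1 states"
    )


def remove_clutter(data: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized background subtraction over a whole slow-time block.

    Equivalent to folding :func:`update_clutter`/:func:`subtract_background`
    frame by frame with c_0 seeded by the first frame: row k of the result
    is r_k - c_{k-1} (row 0 is zero).  Implemented with a linear recursion
    filter along slow time.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D slow-time x fast-time block")
    r0 = data[0]
    if data.shape[0] == 1:
        return np.zeros_like(data)
    # c_k for k >= 1 follows c_k = alpha c_{k-1} + (1-alpha) r_k with c_0 = r_0.
    zi = alpha * r0[np.newaxis, :]
    c_tail, _ = lfilter([1.0 - alpha], [1.0, -alpha], data[1:], axis=0, zi=zi)
    c = np.vstack([r0[np.newaxis, :], c_tail])
    y = np.empty_like(data)
    y[0] = 0.0
    y[1:] = data[1:] - c[:-1]
    return y
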