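"""Selection of fast-time bins carrying vital-sign information.

Per-bin sinusoid fits are gated: a fit whose frequency falls outside the
respiration band (0.15-0.5 Hz) or whose amplitude is below a threshold has
its R^2 replaced by zero (non-respiratory motion or noise).  The gated R^2
profile over fast time is then smoothed with a centered moving average and
bins above the 0.3 threshold become the *best-fit signals* handed to the
reconstruction stage.

The selected rows are the raw clutter-removed slow-time series, not the
fitted sinusoids: the reconstruction segments measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames_io import FrameMatrix
from .sinusoid_fitting import FitResult

RESP_BAND_HZ = (0.15, 0.5)
R_SQ_THRESHOLD = 0.3


@dataclass(frozen=True)
class SelectionConfig:
    resp_band_hz: tuple[float, float] = RESP_BAND_HZ
    #: absolute amplitude threshold in ADC units, or "auto" for
    #: ``auto_factor`` x the median fitted amplitude over the region.
    amp_threshold: float | str = "auto"
    auto_factor: float = 3.0
    smooth_window: int = 5
    r_sq_threshold: float = R_SQ_THRESHOLD

    def __post_init__(self) -> None:
        lo, hi = self.resp_band_hz
        if not (0.0 < lo < hi):
            raise ValueError("respiration band must satisfy 0 < lo < hi")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if not (0.0 <= self.r_sq_threshold < 1.0):
            raise ValueError("r_sq_threshold must lie in [0, 1)")
        if isinstance(self.amp_threshold, str) and self.amp_threshold != "auto":
            raise ValueError("amp_threshold is a number or 'auto'")


@dataclass(frozen=True)
class CandidateSet:
    """The k best-fit signals surviving the gates.

    ``best_fit_matrix`` is k x m: row j is the clutter-removed slow-time
    signal at fast-time bin ``indices[j]``.  k may be zero (whole-body
    motion: nothing fits a respiration sinusoid).
    """

    indices: np.ndarray
    best_fit_matrix: np.ndarray
    profile: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(
            self, "best_fit_matrix", np.atleast_2d(np.asarray(self.best_fit_matrix, dtype=float))
        )

    @property
    def k(self) -> int:
        return len(self.indices)

    @property
    def is_empty(self) -> bool:
        return self.k == 0


def resolve_amp_threshold(fits: Sequence[FitResult], config: SelectionConfig) -> float:
    """Turn an "auto" amplitude threshold into an absolute one."""
    if not isinstance(config.amp_threshold, str):
        return float(config.amp_threshold)
    amps = np.array([f.model.amplitude for f in fits])
    return config.auto_factor * float(np.median(amps))


def gate_fit(
    fit: FitResult,
    config: SelectionConfig,
    fs_slow: float,
    amp_threshold: float | None = None,
) -> float:
    """R^2 of the fit, or 0 if it fails the band or amplitude gate.

    Negative R^2 (fit worse than the mean) is clamped to 0.
    """
    if amp_threshold is None:
        if isinstance(config.amp_threshold, str):
            raise ValueError("'auto' amp_threshold needs resolve_amp_threshold first")
        amp_threshold = float(config.amp_threshold)
    lo, hi = config.resp_band_hz
    f_hz = fit.model.frequency_hz(fs_slow)
    if not (lo <= f_hz <= hi):
        return 0.0
    if fit.model.amplitude < amp_threshold:
        return 0.0
    return max(fit.r_square, 0.0)


def smooth_profile(rsq: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over fast time; edge windows shrink."""
    rsq = np.asarray(rsq, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return rsq.copy()
    num = np.convolve(rsq, np.ones(window), mode="same")
    den = np.convolve(np.ones_like(rsq), np.ones(window), mode="same")
    return num / den


def select_candidates(
    frames: FrameMatrix | np.ndarray,
    fits: Sequence[FitResult],
    config: SelectionConfig,
    fs_slow: float | None = None,
) -> CandidateSet:
    """Gate, smooth, and threshold the per-bin fits of one sensing region.

    ``frames`` holds the clutter-removed (and mean-removed) region; one fit
    per fast-time bin.  An empty result is valid and means "motion too
    large for vital-sign extraction".
    """
    if isinstance(frames, FrameMatrix):
        data = frames.data
        fs = frames.fs_slow if fs_slow is None else fs_slow
    else:
        data = np.asarray(frames, dtype=float)
        if fs_slow is None:
            raise ValueError("fs_slow required when frames is a bare array")
        fs = fs_slow
    if len(fits) != data.shape[1]:
        raise ValueError("need exactly one fit per fast-time bin")
    amp_thr = resolve_amp_threshold(fits, config)
    gated = np.array([gate_fit(f, config, fs, amp_thr) for f in fits])
    profile = smooth_profile(gated, config.smooth_window)
    indices = np.flatnonzero(profile >= config.r_sq_threshold)
    return CandidateSet(
        indices=indices,
        best_fit_matrix=data.T[indices] if len(indices) else np.empty((0, data.shape[0])),
        profile=profile,
    )
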