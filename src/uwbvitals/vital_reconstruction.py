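"""Greedy reconstruction of the vital signal from best-fit segments.

Each best-fit signal is cut into *sub-signals* at its zero crossings.  The
vital signal is assembled recursively: initialisation takes, from the
candidate whose FIRST zero crossing is furthest out, everything up to that
crossing; every later iteration tentatively appends, from each candidate,
the samples between the current end and that candidate's next crossing,
scores each concatenation by its autocorrelation *width* (the number of
contiguous lags over which the normalized autocorrelation stays above a
level, default 0.5 -- wide means the continuation is phase-consistent with
what was already built), and keeps the widest.  The procedure is greedy
and deterministic: all ties break toward the lowest candidate index.

Indices are 0-based half-open internally; reporting helpers convert to the
1-based inclusive convention used in field descriptions of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .candidate_selection import CandidateSet
from .errors import ReconstructionError


@dataclass(frozen=True)
class WidthConfig:
    """Definition of the autocorrelation width used as the greedy score.

    ``hysteresis_frac`` controls the Schmitt-trigger band (as a fraction
    of each candidate's RMS) used when segmenting candidates at zero
    crossings: sampled noise flickers the sign near every true crossing,
    and without a band the segments fragment into meaningless scraps.
    Zero disables it (strict sign-change crossings).  ``min_segment``
    additionally drops crossings closer than that many slow-time samples
    to the previous kept one (default 33 ~ 0.3 s at 110 frames/s, well
    below any breathing half-period).

    ``score_context`` bounds how much trailing context of the already
    constructed signal enters the width score when a tentative segment is
    appended (default 220 samples ~ 2 s at 110 frames/s, about one
    breathing half-period).  On long recordings the width of the whole
    concatenation is insensitive to a single segment -- candidates differ
    by less than 0.1 lag -- so the score must be local to discriminate
    phase-consistent continuations.  ``None`` scores the full
    concatenation.
    """

    level: float = 0.5
    max_lag: int | None = None
    hysteresis_frac: float = 0.2
    min_segment: int = 33
    score_context: int | None = 220

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.hysteresis_frac < 0.0:
            raise ValueError("hysteresis_frac must be non-negative")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.score_context is not None and self.score_context < 8:
            raise ValueError("score_context must be >= 8 samples")


@dataclass(frozen=True)
class SubSignal:
    """Provenance of one appended segment (0-based half-open)."""

    source: int
    start: int
    end: int

    @property
    def report_1based(self) -> tuple[int, int, int]:
        """(source, start, end) in 1-based inclusive convention."""
        return (self.source + 1, self.start + 1, self.end)


@dataclass
class ReconstructionState:
    constructed: np.ndarray
    end_index: int
    iteration: int
    provenance: list[SubSignal] = field(default_factory=list)


@dataclass(frozen=True)
class VitalSignal:
    samples: np.ndarray
    provenance: tuple[SubSignal, ...]

    def provenance_rows(self) -> list[tuple[int, int, int, int]]:
        """(segment_id, source_bin, start, end) rows for CSV export."""
        return [(i, s.source, s.start, s.end) for i, s in enumerate(self.provenance)]


def zero_crossings(signal: np.ndarray, hysteresis: float = 0.0) -> np.ndarray:
    """Indices of the first sample after each sign change.

    Zero samples inherit the previous nonzero sign (leading zeros the
    following one), so a touch of zero without a sign flip is not a
    crossing.  A constant-sign signal has no crossings.

    With ``hysteresis`` > 0 a crossing only registers once the signal
    reaches beyond the +/-``hysteresis`` band on the far side (Schmitt
    trigger), so noise flicker around a slow oscillation's true zeros
    does not fragment the segmentation.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("need at least 2 samples")
    if hysteresis > 0.0:
        return _hysteresis_crossings(signal, hysteresis)
    s = np.sign(signal)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.array([], dtype=int)
    # forward-fill zeros with the previous nonzero sign; backfill the head
    filled = s.copy()
    idx = np.maximum.accumulate(np.where(s != 0, np.arange(len(s)), -1))
    head = idx < 0
    filled[~head] = s[idx[~head]]
    filled[head] = s[nz[0]]
    return np.flatnonzero(filled[:-1] != filled[1:]) + 1


def _hysteresis_crossings(signal: np.ndarray, h: float) -> np.ndarray:
    """Schmitt-trigger crossings: flip state on reaching the opposite band."""
    beyond = np.flatnonzero(np.abs(signal) >= h)
    if beyond.size == 0:
        return np.array([], dtype=int)
    signs = np.sign(signal[beyond])
    flips = np.flatnonzero(signs[1:] != signs[:-1]) + 1
    return beyond[flips].astype(int)


def correlation_width(signal: np.ndarray, config: WidthConfig = WidthConfig()) -> float:
    """Autocorrelation width: total lag extent over which the normalized
    biased autocorrelation (r[0] = 1) stays at or above ``level``.

    Every above-level run of lags contributes its length, with the exit
    of each run linearly interpolated, so the width is fractional.  A
    phase-consistent periodic signal keeps r near 1 at every multiple of
    its period and scores wide; noise scores about one lag; a signal with
    a phase break loses long-lag coherence and its width collapses even
    though the short-lag shape is untouched.

    The signal mean is removed first (i.e. this is the normalized
    autocovariance): any net offset would otherwise hold the
    autocorrelation above the level at every lag and the width would
    stop measuring periodicity.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    x = x - x.mean()
    energy = float(x @ x)
    if energy == 0.0:
        raise ValueError("degenerate autocorrelation of an all-zero signal")
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / energy
    max_lag = n if config.max_lag is None else min(config.max_lag + 1, n)
    r = r[:max_lag]
    above = r >= config.level
    total = 0.0
    i = 0
    while i < max_lag:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < max_lag and above[j + 1]:
            j += 1
        if j + 1 < max_lag:  # interpolate the run's exit below the level
            total += (j - i) + (r[j] - config.level) / (r[j] - r[j + 1])
        else:
            total += (j - i) + 1.0
        i = j + 1
    return total


def select_initial_segment(first_crossings: Sequence[int]) -> tuple[int, int]:
    """Initialisation rule: the candidate with the furthest first crossing.

    Returns (source index 0-based, end index).  Ties break toward the
    lowest source index.
    """
    arr = np.asarray(first_crossings)
    if arr.size == 0:
        raise ReconstructionError("no segmentable candidates")
    src = int(np.argmax(arr))
    return src, int(arr[src])


def select_append_segment(
    widths: Sequence[float], next_crossings: Sequence[int]
) -> tuple[int, int]:
    """Append rule: the candidate whose concatenation is widest.

    Returns (source index 0-based, new end index = that candidate's next
    crossing).  Ties break toward the lowest source index.
    """
    w = np.asarray(widths, dtype=float)
    if w.size == 0:
        raise ReconstructionError("reconstruction complete: no candidate extends")
    src = int(np.argmax(w))
    return src, int(np.asarray(next_crossings)[src])


def _candidate_crossings(
    candidates: CandidateSet, config: WidthConfig = WidthConfig()
) -> list[np.ndarray]:
    out = []
    for row in candidates.best_fit_matrix:
        rms = float(np.sqrt(np.mean(row**2)))
        c = zero_crossings(row, hysteresis=config.hysteresis_frac * rms)
        if config.min_segment > 1 and c.size:
            keep = [int(c[0])]
            for i in c[1:]:
                if int(i) - keep[-1] >= config.min_segment:
                    keep.append(int(i))
            c = np.asarray(keep, dtype=int)
        out.append(c)
    return out


def init_reconstruction(
    candidates: CandidateSet, config: WidthConfig = WidthConfig()
) -> ReconstructionState:
    """First iteration: seed the vital signal from the best-fit matrix.

    Candidates with no zero crossing at all are skipped; if every candidate
    is constant-sign the reconstruction cannot start.
    """
    if candidates.is_empty:
        raise ReconstructionError("no vital signal under current motion")
    crossings = _candidate_crossings(candidates, config)
    firsts = [(j, int(c[0])) for j, c in enumerate(crossings) if c.size]
    if not firsts:
        raise ReconstructionError("no segmentable candidates")
    rel_src, end = select_initial_segment([f for _, f in firsts])
    src = firsts[rel_src][0]
    return ReconstructionState(
        constructed=candidates.best_fit_matrix[src, :end].copy(),
        end_index=end,
        iteration=1,
        provenance=[SubSignal(source=src, start=0, end=end)],
    )


def append_segment(
    state: ReconstructionState,
    candidates: CandidateSet,
    config: WidthConfig = WidthConfig(),
) -> ReconstructionState:
    """One greedy iteration: append the width-maximising sub-signal.

    Raises :class:`ReconstructionError` ("reconstruction complete") when no
    candidate has a crossing beyond the current end.
    """
    crossings = _candidate_crossings(candidates, config)
    options: list[tuple[int, int]] = []  # (source, next_crossing)
    for j, c in enumerate(crossings):
        beyond = c[c > state.end_index]
        if beyond.size:
            options.append((j, int(beyond[0])))
    if not options:
        raise ReconstructionError("reconstruction complete")
    context = (
        state.constructed
        if config.score_context is None
        else state.constructed[-config.score_context:]
    )
    widths = []
    for src, nxt in options:
        tentative = np.concatenate(
            [context, candidates.best_fit_matrix[src, state.end_index:nxt]]
        )
        widths.append(correlation_width(tentative, config))
    rel_src, _ = select_append_segment(widths, [n for _, n in options])
    src, nxt = options[rel_src]
    return ReconstructionState(
        constructed=np.concatenate(
            [state.constructed, candidates.best_fit_matrix[src, state.end_index:nxt]]
        ),
        end_index=nxt,
        iteration=state.iteration + 1,
        provenance=state.provenance + [SubSignal(source=src, start=state.end_index, end=nxt)],
    )


def reconstruct(
    candidates: CandidateSet, config: WidthConfig = WidthConfig()
) -> VitalSignal:
    """Run initialisation + greedy appends until no candidate extends."""
    state = init_reconstruction(candidates, config)
    while True:
        try:
            state = append_segment(state, candidates, config)
        except ReconstructionError:
            break
    return VitalSignal(samples=state.constructed, provenance=tuple(state.provenance))
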