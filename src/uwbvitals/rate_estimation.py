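"""Frequency-domain readout of respiration and heart rate.

The reconstructed vital signal is zero-padded to a 2^15-point FFT
(0.2014 cycles/min resolution at 110 frames/s) and each rate is the
frequency of the maximum-magnitude bin inside its band: respiration
0.15-0.5 Hz (9-30 cycles/min), heart 0.8-2.0 Hz (48-120 beats/min).
Because respiration dominates the chest displacement, the heart peak is
the globally second-highest peak, exactly as read off a spectrum plot.

The signal mean is removed before the FFT so DC leakage does not swamp
the respiration band.  Integer reporting rounds half up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_NFFT = 2**15


@dataclass(frozen=True)
class SpectrumConfig:
    nfft: int = DEFAULT_NFFT
    resp_band_hz: tuple[float, float] = (0.15, 0.5)
    heart_band_hz: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        if self.nfft < 2 or self.nfft & (self.nfft - 1):
            raise ValueError("nfft must be a power of two")
        if self.resp_band_hz[1] > self.heart_band_hz[0]:
            raise ValueError("respiration and heart bands must be disjoint")

    def resolution_cpm(self, fs_slow: float) -> float:
        return fs_slow / self.nfft * 60.0


@dataclass(frozen=True)
class RateEstimate:
    respiration_cpm: float
    heart_bpm: float
    resp_peak_amp: float
    heart_peak_amp: float
    resolution_cpm: float

    @property
    def respiration_int(self) -> int:
        return round_half_up(self.respiration_cpm)

    @property
    def heart_int(self) -> int:
        return round_half_up(self.heart_bpm)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def amplitude_spectrum(
    signal: np.ndarray, fs_slow: float, config: SpectrumConfig = SpectrumConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded magnitude spectrum on a grid of spacing fs/nfft Hz."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size > config.nfft:
        raise ValueError(f"signal length {x.size} exceeds nfft {config.nfft}")
    mags = np.abs(np.fft.rfft(x - x.mean(), config.nfft))
    freqs = np.fft.rfftfreq(config.nfft, 1.0 / fs_slow)
    return freqs, mags


def _band_peak(
    freqs: np.ndarray, mags: np.ndarray, band: tuple[float, float], what: str
) -> tuple[float, float]:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any() or not np.any(mags[mask] > 0.0):
        raise ValueError(f"no {what} peak: spectrum is zero in {band} Hz")
    sub = np.flatnonzero(mask)
    j = sub[int(np.argmax(mags[sub]))]  # ties -> lowest frequency
    return float(freqs[j]), float(mags[j])


def estimate_respiration(
    freqs: np.ndarray, mags: np.ndarray, config: SpectrumConfig = SpectrumConfig()
) -> tuple[float, float]:
    """(respiration in cycles/min, peak magnitude) from the band argmax."""
    f, a = _band_peak(freqs, mags, config.resp_band_hz, "respiration")
    return f * 60.0, a


def estimate_heart(
    freqs: np.ndarray, mags: np.ndarray, config: SpectrumConfig = SpectrumConfig()
) -> tuple[float, float]:
    """(heart rate in beats/min, peak magnitude) from the band argmax."""
    f, a = _band_peak(freqs, mags, config.heart_band_hz, "heart")
    return f * 60.0, a


def estimate_rates(
    signal: np.ndarray, fs_slow: float, config: SpectrumConfig = SpectrumConfig()
) -> RateEstimate:
    """Full readout: FFT then both band peaks."""
    freqs, mags = amplitude_spectrum(signal, fs_slow, config)
    resp_cpm, resp_amp = estimate_respiration(freqs, mags, config)
    heart_bpm, heart_amp = estimate_heart(freqs, mags, config)
    return RateEstimate(
        respiration_cpm=resp_cpm,
        heart_bpm=heart_bpm,
        resp_peak_amp=resp_amp,
        heart_peak_amp=heart_amp,
        resolution_cpm=config.resolution_cpm(fs_slow),
    )
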