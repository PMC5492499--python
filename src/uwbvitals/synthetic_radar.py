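"""Synthetic IR-UWB frame generator standing in for the radar hardware.

Generates slow-time x fast-time matrices with the statistical structure the
pipeline assumes: a static clutter profile, a multi-bin torso whose range
displacement is a breathing sinusoid plus a ten-times-smaller heartbeat
sinusoid, optional broadband motion-artifact episodes, additive white
noise, and -- for the near region -- object entry/dwell/removal scenarios
with or without sustained micro-motion.

Chest displacement is rendered by shifting an analytic band-limited pulse
template along fast time, so at small displacement every torso bin carries
a slow-time sinusoid proportional to the displacement -- which is exactly
the signal model the fitting stage assumes.  Each torso
bin gets a small random phase jitter so candidates are similar but not
identical.

Everything is driven by one integer seed: same scenario + seed gives a
bit-identical matrix.  Ground truth (true rates, artifact windows, the
intended detector verdict) is returned as a separate sidecar dict so tests
never read truth from the waveforms themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .frames_io import (
    DEFAULT_BIN_SPACING_M,
    DEFAULT_FS_SLOW_HZ,
    DEFAULT_N_BINS,
    DEFAULT_PHONE_REGION,
    DEFAULT_VITALS_REGION,
    FrameMatrix,
)

C_LIGHT = 299792458.0
DEFAULT_CENTER_FREQ_HZ = 6.8e9
DEFAULT_BANDWIDTH_HZ = 2.3e9

PHONE_KINDS = (
    "texting",
    "scrolling",
    "viewing",
    "moving_hand",
    "moving_bottle",
    "moving_phone",
    "background_appear",
    "background_disappear",
)
_SUSTAINED = ("texting", "scrolling", "viewing")
_MOMENTARY = ("moving_hand", "moving_bottle", "moving_phone")


@dataclass(frozen=True)
class PulseTemplate:
    """Unit-energy band-limited pulse over fast-time bins.

    ``waveform`` is the pulse sampled at integer bin offsets; rendering at
    fractional offsets evaluates the same analytic Hann-windowed carrier
    (see :func:`make_pulse_template`) so that sub-bin displacement maps
    smoothly -- a piecewise-linear lookup would put interpolation kinks
    exactly at the integer offsets where small chest motion dithers, and
    rectify it.
    """

    waveform: np.ndarray
    center_freq_hz: float
    bandwidth_hz: float
    bin_spacing_m: float
    norm: float  # energy normalization shared by sampled and analytic forms

    @property
    def support_bins(self) -> int:
        return int(np.count_nonzero(self.waveform))

    def evaluate(self, offsets_bins: np.ndarray) -> np.ndarray:
        """Analytic pulse value at (possibly fractional) bin offsets."""
        u = np.asarray(offsets_bins, dtype=float)
        support = len(self.waveform)
        half = support // 2
        window = 0.5 - 0.5 * np.cos(2.0 * np.pi * (u + half + 1) / (support + 1))
        carrier = np.cos(4.0 * np.pi * self.center_freq_hz * u * self.bin_spacing_m / C_LIGHT)
        out = window * carrier / self.norm
        # the Hann factor reaches zero with zero slope at |u| = half + 1,
        # so clipping there keeps the rendered pulse C^1 in the offset
        return np.where(np.abs(u) <= half + 1, out, 0.0)


def make_pulse_template(
    center_freq_hz: float = DEFAULT_CENTER_FREQ_HZ,
    bandwidth_hz: float = DEFAULT_BANDWIDTH_HZ,
    bin_spacing_m: float = DEFAULT_BIN_SPACING_M,
) -> PulseTemplate:
    """Modulated-envelope pulse whose support equals the range resolution.

    Range resolution is c/(2B); the waveform is a Hann-windowed carrier at
    the two-way spatial frequency 2 f_c / c, normalized to unit energy.
    """
    if center_freq_hz <= 0 or bandwidth_hz <= 0 or bin_spacing_m <= 0:
        raise ValueError("nonphysical pulse parameters")
    if bandwidth_hz >= 2.0 * center_freq_hz:
        raise ValueError("bandwidth must be below twice the center frequency")
    range_res_m = C_LIGHT / (2.0 * bandwidth_hz)
    support = max(3, round(range_res_m / bin_spacing_m))
    if support % 2 == 0:
        support += 1
    half = support // 2
    r = (np.arange(support) - half) * bin_spacing_m
    window = np.hanning(support + 2)[1:-1]  # nonzero over the full support
    w = window * np.cos(4.0 * np.pi * center_freq_hz * r / C_LIGHT)
    norm = float(np.sqrt(np.sum(w**2)))
    return PulseTemplate(
        waveform=w / norm,
        center_freq_hz=center_freq_hz,
        bandwidth_hz=bandwidth_hz,
        bin_spacing_m=bin_spacing_m,
        norm=norm,
    )


def _smooth_clutter(rng: np.random.Generator, n_bins: int, amp: float) -> np.ndarray:
    return amp * gaussian_filter1d(rng.normal(0.0, 1.0, n_bins), 6.0) + amp


# ---------------------------------------------------------------------------
# Vitals scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VitalsScenario:
    """Seated-subject recording: breathing + heartbeat + optional artifacts.

    Displacements are peak-to-peak chest excursions in millimeters
    (defaults: 4 mm breathing, 0.4 mm heartbeat -- quiet-breathing chest
    physiology).  The peak-to-peak convention keeps the two-way carrier
    phase modulation moderate, so breathing harmonics in the heart band
    stay below the heartbeat line -- the spectral structure the pipeline's
    second-peak readout presumes.  ``artifacts`` are (start_s, dur_s,
    (bin_lo, bin_hi), amplitude_sd) broadband episodes.  ``drift_mm`` adds
    a slow (0.05 Hz) global torso drift, also peak-to-peak.
    """

    breathing_cpm: float = 18.0
    heart_bpm: float = 72.0
    breathing_disp_mm: float = 4.0
    heart_disp_mm: float = 0.4
    torso_bins: tuple[int, int] = (84, 124)
    artifacts: tuple[tuple[float, float, tuple[int, int], float], ...] = ()
    clutter_profile: np.ndarray | None = None
    noise_sd: float = 0.05
    duration_s: float = 60.0
    drift_mm: float = 0.0
    torso_amp: float = 10.0
    fs_slow: float = DEFAULT_FS_SLOW_HZ
    n_bins: int = DEFAULT_N_BINS
    bin_spacing_m: float = DEFAULT_BIN_SPACING_M
    vitals_region: tuple[int, int] = DEFAULT_VITALS_REGION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heart_disp_mm >= self.breathing_disp_mm:
            raise ValueError("heart displacement must be below breathing displacement")
        lo, hi = self.torso_bins
        rlo, rhi = self.vitals_region
        if not (rlo <= lo < hi <= rhi):
            raise ValueError("torso span must lie inside the vitals region")


def simulate_vitals(scenario: VitalsScenario) -> tuple[FrameMatrix, dict]:
    """Render a vitals recording; returns (frames, ground-truth sidecar)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    m = round(sc.duration_s * sc.fs_slow)
    t = np.arange(m) / sc.fs_slow
    tmpl = make_pulse_template(bin_spacing_m=sc.bin_spacing_m)
    half = len(tmpl.waveform) // 2

    clutter = (
        np.asarray(sc.clutter_profile, dtype=float)
        if sc.clutter_profile is not None
        else _smooth_clutter(rng, sc.n_bins, 3.0)
    )
    W = np.tile(clutter, (m, 1))

    f_b = sc.breathing_cpm / 60.0
    f_h = sc.heart_bpm / 60.0
    phase_b0 = rng.uniform(0.0, 2.0 * np.pi)
    phase_h0 = rng.uniform(0.0, 2.0 * np.pi)
    mm_per_bin = sc.bin_spacing_m * 1000.0

    drift_bins = np.zeros(m)
    if sc.drift_mm > 0.0:
        drift_bins = (
            0.5 * sc.drift_mm / mm_per_bin
            * np.sin(2.0 * np.pi * 0.05 * t + rng.uniform(0.0, 2.0 * np.pi))
        )

    lo, hi = sc.torso_bins
    for b in range(lo, hi):
        refl = sc.torso_amp * rng.uniform(0.7, 1.3)
        jit_b = rng.uniform(-0.3, 0.3)
        jit_h = rng.uniform(-0.3, 0.3)
        disp_mm = 0.5 * sc.breathing_disp_mm * np.sin(2.0 * np.pi * f_b * t + phase_b0 + jit_b)
        disp_mm += 0.5 * sc.heart_disp_mm * np.sin(2.0 * np.pi * f_h * t + phase_h0 + jit_h)
        shift = disp_mm / mm_per_bin + drift_bins
        j0, j1 = max(0, b - half - 2), min(sc.n_bins, b + half + 3)
        cols = np.arange(j0, j1)
        offsets = cols[None, :] - b - shift[:, None]
        W[:, j0:j1] += refl * tmpl.evaluate(offsets)

    artifact_truth = []
    for start_s, dur_s, (alo, ahi), amp in sc.artifacts:
        k0 = round(start_s * sc.fs_slow)
        k1 = min(m, round((start_s + dur_s) * sc.fs_slow))
        W[k0:k1, alo:ahi] += rng.normal(0.0, amp, (max(0, k1 - k0), ahi - alo))
        artifact_truth.append(
            {"start_s": start_s, "dur_s": dur_s, "bins": [alo, ahi], "amp": amp}
        )

    W += rng.normal(0.0, sc.noise_sd, W.shape)
    frames = FrameMatrix(
        data=W, fs_slow=sc.fs_slow, bin_spacing=sc.bin_spacing_m, origin_m=0.0
    )
    truth = {
        "breathing_cpm": sc.breathing_cpm,
        "heart_bpm": sc.heart_bpm,
        "torso_bins": list(sc.torso_bins),
        "artifacts": artifact_truth,
        "drift_mm": sc.drift_mm,
        "seed": sc.seed,
    }
    return frames, truth


def transient_artifact_scenario(seed: int) -> VitalsScenario:
    """60 s recording with a 5 s broadband artifact over the upper half of
    the 40-bin torso -- the brief-head-movement condition."""
    lo, hi = 84, 124
    mid = (lo + hi) // 2
    return VitalsScenario(
        breathing_cpm=18.0,
        heart_bpm=72.0,
        torso_bins=(lo, hi),
        artifacts=(((20.0, 5.0, (mid, hi), 20.0)),),
        seed=seed,
    )


def slow_drift_scenario(seed: int) -> VitalsScenario:
    """60 s recording with a 1 mm slow global drift across all torso bins --
    the smooth-acceleration condition."""
    return VitalsScenario(
        breathing_cpm=18.0, heart_bpm=72.0, drift_mm=1.0, seed=seed
    )


# ---------------------------------------------------------------------------
# Phone scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhoneScenario:
    """Near-region object scenario.

    ``object_amp`` is the peak received amplitude of the object in ADC
    units (the template is peak-normalized here); ``micro_motion_amp`` the
    peak amplitude of the short re-excitation bursts a handled device
    produces (threshold 2 < burst < threshold 1 territory).
    """

    kind: str = "texting"
    entry_s: float = 0.7
    dwell_s: float = 5.0
    micro_motion_amp: float = 2.0
    object_amp: float = 8.0
    noise_sd: float = 0.05
    duration_s: float = 8.0
    object_bin: int = 30
    fs_slow: float = DEFAULT_FS_SLOW_HZ
    n_bins: int = DEFAULT_N_BINS
    bin_spacing_m: float = DEFAULT_BIN_SPACING_M
    phone_region: tuple[int, int] = DEFAULT_PHONE_REGION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHONE_KINDS:
            raise ValueError(f"unknown phone scenario kind {self.kind!r}")
        if self.micro_motion_amp < 0 or self.object_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        lo, hi = self.phone_region
        if not (lo <= self.object_bin < hi):
            raise ValueError("object_bin must lie inside the phone region")


def _micro_motion_bursts(
    rng: np.random.Generator, m: int, fs: float, k_on: int, k_off: int, amp: float
) -> np.ndarray:
    """Short amplitude bursts every <= 0.5 s while the object is handled."""
    a = np.zeros(m)
    burst_len = max(1, round(0.1 * fs))
    k = k_on + round(0.25 * fs)
    while k < k_off:
        sign = rng.choice((-1.0, 1.0))
        mag = amp * rng.uniform(0.8, 1.0)
        a[k:min(k + burst_len, k_off)] = sign * mag
        k += round(fs * rng.uniform(0.3, 0.45))
    return a


def simulate_phone(scenario: PhoneScenario) -> tuple[FrameMatrix, dict]:
    """Render a near-region scenario; returns (frames, verdict sidecar)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    m = round(sc.duration_s * sc.fs_slow)
    tmpl = make_pulse_template(bin_spacing_m=sc.bin_spacing_m)
    shape = tmpl.waveform / np.max(np.abs(tmpl.waveform))  # peak-normalized
    half = len(shape) // 2

    clutter = _smooth_clutter(rng, sc.n_bins, 2.0)
    W = np.tile(clutter, (m, 1))

    k_entry = round(sc.entry_s * sc.fs_slow)
    if sc.kind in _SUSTAINED:
        k_leave = min(m, k_entry + round(sc.dwell_s * sc.fs_slow))
    elif sc.kind in _MOMENTARY:
        k_leave = min(m, k_entry + round(0.5 * sc.fs_slow))
    else:  # background change: a step that never reverts
        k_leave = m

    amp = np.zeros(m)
    if sc.kind == "background_disappear":
        amp[:k_entry] = sc.object_amp  # present from the start, then removed
    else:
        amp[k_entry:k_leave] = sc.object_amp
    if sc.kind in _SUSTAINED:
        amp += _micro_motion_bursts(rng, m, sc.fs_slow, k_entry, k_leave, sc.micro_motion_amp)
    j0 = max(0, sc.object_bin - half)
    j1 = min(sc.n_bins, sc.object_bin + half + 1)
    seg = shape[j0 - (sc.object_bin - half):j1 - (sc.object_bin - half)]
    W[:, j0:j1] += amp[:, None] * seg[None, :]

    W += rng.normal(0.0, sc.noise_sd, W.shape)
    frames = FrameMatrix(
        data=W, fs_slow=sc.fs_slow, bin_spacing=sc.bin_spacing_m, origin_m=0.0
    )
    verdict = {
        "kind": sc.kind,
        "expect_phone": sc.kind in _SUSTAINED,
        "expect_background_change": sc.kind in ("background_appear", "background_disappear"),
        "entry_s": sc.entry_s,
        "seed": sc.seed,
    }
    return frames, verdict
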