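"""End-to-end vitals pipeline: clutter removal -> per-bin sinusoid fits ->
candidate selection -> greedy reconstruction -> spectral rate readout.

One call processes one analysis window of the vitals region; a sliding
driver (default 30 s windows, 5 s hop) covers long recordings.  A window
in which no fast-time bin survives the R^2 gates yields no estimate: the
whole-body-motion ("motion too large") condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidate_selection import CandidateSet, SelectionConfig, select_candidates
from .clutter_removal import remove_clutter
from .config import DEFAULTS
from .errors import ReconstructionError
from .frames_io import FrameMatrix, RegionSpec, slice_region
from .rate_estimation import RateEstimate, SpectrumConfig, estimate_rates
from .sinusoid_fitting import FitConfig, fit_matrix
from .vital_reconstruction import WidthConfig, reconstruct


@dataclass(frozen=True)
class WindowReport:
    """Result of one analysis window (rates are None under large motion)."""

    start_s: float
    end_s: float
    n_candidates: int
    estimate: RateEstimate | None

    @property
    def motion_too_large(self) -> bool:
        return self.estimate is None


def _configs(config: dict | None):
    cfg = DEFAULTS if config is None else config
    fit = FitConfig(
        omega_min_hz=cfg["fit"]["omega_min_hz"],
        omega_max_hz=cfg["fit"]["omega_max_hz"],
        grid_points=cfg["fit"]["grid_points"],
        refine_iters=cfg["fit"]["refine_iters"],
        include_offset=cfg["fit"]["include_offset"],
    )
    sel = SelectionConfig(
        resp_band_hz=tuple(cfg["select"]["resp_band_hz"]),
        amp_threshold=cfg["select"]["amp_threshold"],
        auto_factor=cfg["select"]["auto_factor"],
        smooth_window=cfg["select"]["smooth_window"],
        r_sq_threshold=cfg["select"]["r_sq_threshold"],
    )
    width = WidthConfig(
        level=cfg["recon"]["width_level"],
        max_lag=cfg["recon"]["max_lag"],
        hysteresis_frac=cfg["recon"]["hysteresis_frac"],
        min_segment=cfg["recon"]["min_segment"],
        score_context=cfg["recon"]["score_context"],
    )
    spect = SpectrumConfig(
        nfft=cfg["spect"]["nfft"],
        resp_band_hz=tuple(cfg["spect"]["resp_band_hz"]),
        heart_band_hz=tuple(cfg["spect"]["heart_band_hz"]),
    )
    alpha = cfg["clutter"]["alpha_vitals"]
    return fit, sel, width, spect, alpha


def _trim_candidates(candidates: CandidateSet, max_candidates: int | None) -> CandidateSet:
    """Keep the ``max_candidates`` bins with the best smoothed profile.

    The method is designed around a handful of best-fit columns
    (typically about nine); feeding the greedy every bin that
    clears the threshold dilutes it with low-amplitude edge bins whose
    segments are noisier than the torso core.  Ties break toward the
    lower fast-time bin.
    """
    if max_candidates is None or candidates.k <= max_candidates:
        return candidates
    scores = candidates.profile[candidates.indices]
    order = np.lexsort((candidates.indices, -scores))[:max_candidates]
    order = np.sort(order)  # restore ascending bin order
    return CandidateSet(
        indices=candidates.indices[order],
        best_fit_matrix=candidates.best_fit_matrix[order],
        profile=candidates.profile,
    )


def vitals_candidates(
    region_frames: FrameMatrix, config: dict | None = None
) -> CandidateSet:
    """Clutter-remove, mean-remove, fit every bin, and gate/select."""
    cfg = DEFAULTS if config is None else config
    fit_cfg, sel_cfg, _, _, alpha = _configs(cfg)
    y = remove_clutter(region_frames.data, alpha)
    y = y - y.mean(axis=0, keepdims=True)
    fits = fit_matrix(y.T, fit_cfg, region_frames.fs_slow)
    selected = select_candidates(y, fits, sel_cfg, fs_slow=region_frames.fs_slow)
    return _trim_candidates(selected, cfg["select"].get("max_candidates"))


def process_vitals_window(
    region_frames: FrameMatrix, config: dict | None = None
) -> tuple[RateEstimate | None, CandidateSet]:
    """Full pipeline on one window of the (raw) vitals region."""
    _, _, width_cfg, spect_cfg, _ = _configs(config)
    candidates = vitals_candidates(region_frames, config)
    if candidates.is_empty:
        return None, candidates
    try:
        vital = reconstruct(candidates, width_cfg)
    except ReconstructionError:
        return None, candidates
    estimate = estimate_rates(vital.samples, region_frames.fs_slow, spect_cfg)
    return estimate, candidates


def run_vitals(
    frames: FrameMatrix,
    config: dict | None = None,
    region: RegionSpec | None = None,
) -> list[WindowReport]:
    """Sliding-window vitals estimation over a full-width recording."""
    cfg = DEFAULTS if config is None else config
    if region is None:
        v0, v1 = cfg["regions"]["vitals"]
        region = RegionSpec("vitals", v0, min(v1, frames.n_bins))
    sliced = slice_region(frames, region)
    fs = frames.fs_slow
    win = round(cfg["vitals_window"]["window_s"] * fs)
    hop = max(1, round(cfg["vitals_window"]["hop_s"] * fs))
    m = sliced.n_frames
    starts = [0] if m <= win else list(range(0, m - win + 1, hop))
    reports = []
    for k0 in starts:
        k1 = min(m, k0 + win)
        window = FrameMatrix(
            data=sliced.data[k0:k1],
            fs_slow=fs,
            bin_spacing=sliced.bin_spacing,
            origin_m=sliced.origin_m,
        )
        estimate, candidates = process_vitals_window(window, cfg)
        reports.append(
            WindowReport(
                start_s=k0 / fs,
                end_s=k1 / fs,
                n_candidates=candidates.k,
                estimate=estimate,
            )
        )
    return reports
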