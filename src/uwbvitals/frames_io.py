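"""Radar frame-matrix data model, on-disk formats, and region slicing.

An IR-UWB radar produces one *frame* (a sampled echo over *fast time*,
i.e. range) per pulse-repetition interval; stacking frames row-wise over
*slow time* yields the m x n amplitude matrix that every downstream stage
consumes.  The default geometry is 256 fast-time bins spanning 1 m
(~3.9 mm/bin) sampled at 110 frames/s.

Two fixed sub-ranges of the fast-time axis are used: a near *phone* region
(hand-held-object sensing, 25 cm) and a *vitals* region behind it
(~50 cm covering the torso).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import ConfigError, FrameParseError

DEFAULT_N_BINS = 256
DEFAULT_BIN_SPACING_M = 1.0 / DEFAULT_N_BINS  # 256 bins over 1 m
DEFAULT_FS_SLOW_HZ = 110.0

#: Default fast-time extents of the two sensing zones (0-based, half-open).
#: The near 25 cm belongs to the phone region, the next ~50 cm to vitals.
DEFAULT_PHONE_REGION = (0, 64)
DEFAULT_VITALS_REGION = (64, 192)


@dataclass(frozen=True)
class FrameMatrix:
    """Slow-time x fast-time amplitude matrix with sampling metadata.

    Parameters
    ----------
    data
        Real amplitudes, shape ``(m, n)``: m slow-time frames, n fast-time
        bins, in raw ADC units.
    fs_slow
        Slow-time sampling frequency in Hz (frames per second).
    bin_spacing
        Meters of range per fast-time bin.
    origin_m
        Range of bin 0 in meters.
    """

    data: np.ndarray
    fs_slow: float = DEFAULT_FS_SLOW_HZ
    bin_spacing: float = DEFAULT_BIN_SPACING_M
    origin_m: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("frame matrix must be 2-D with m >= 1, n >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("frame matrix contains non-finite amplitudes")
        if not self.fs_slow > 0:
            raise ValueError("fs_slow must be positive")
        if not self.bin_spacing > 0:
            raise ValueError("bin_spacing must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_slow

    def slow_time(self) -> np.ndarray:
        """Slow-time axis in seconds (one value per frame)."""
        return np.arange(self.n_frames) / self.fs_slow

    def ranges_m(self) -> np.ndarray:
        """Range of each fast-time bin in meters."""
        return self.origin_m + np.arange(self.n_bins) * self.bin_spacing


@dataclass(frozen=True)
class RegionSpec:
    """Half-open fast-time span assigned to one sensing role."""

    role: Literal["phone", "vitals"]
    start_bin: int
    end_bin: int

    def __post_init__(self) -> None:
        if self.role not in ("phone", "vitals"):
            raise ValueError(f"unknown region role {self.role!r}")
        if not (0 <= self.start_bin < self.end_bin):
            raise ValueError("require 0 <= start_bin < end_bin")

    @property
    def width(self) -> int:
        return self.end_bin - self.start_bin


def default_regions(n_bins: int = DEFAULT_N_BINS) -> dict[str, RegionSpec]:
    """Default phone/vitals regions, clipped to the matrix width."""
    phone = RegionSpec("phone", *DEFAULT_PHONE_REGION)
    v0, v1 = DEFAULT_VITALS_REGION
    vitals = RegionSpec("vitals", v0, min(v1, n_bins))
    if phone.end_bin > n_bins or vitals.start_bin >= n_bins:
        raise ValueError(f"matrix with {n_bins} bins cannot host default regions")
    return {"phone": phone, "vitals": vitals}


def slice_region(frames: FrameMatrix, region: RegionSpec) -> FrameMatrix:
    """Extract the fast-time columns of one sensing zone.

    The slow-time axis is untouched; ``origin_m`` shifts so bin 0 of the
    result is the range of ``region.start_bin`` in the input.
    """
    if region.end_bin > frames.n_bins:
        raise IndexError(
            f"region [{region.start_bin}, {region.end_bin}) exceeds "
            f"matrix width {frames.n_bins}"
        )
    return replace(
        frames,
        data=frames.data[:, region.start_bin:region.end_bin],
        origin_m=frames.origin_m + region.start_bin * frames.bin_spacing,
    )


# ---------------------------------------------------------------------------
# On-disk formats: CSV matrix + JSON sidecar, or an HDF5 container.
# ---------------------------------------------------------------------------

SIDECAR_KEYS = ("fs_slow_hz", "bin_spacing_m", "origin_m")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_frames(
    frames: FrameMatrix,
    path: str | Path,
    created_by: str = "uwbvitals",
    seed: int | None = None,
) -> None:
    """Write a frame matrix.

    ``.h5``/``.hdf5`` suffixes select the binary container; anything else is
    written as a comma-separated text matrix (one frame per row, ``%.17g`` so
    doubles round-trip exactly) plus a JSON metadata sidecar next to it.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=frames.data)
            ds.attrs["fs_slow_hz"] = frames.fs_slow
            ds.attrs["bin_spacing_m"] = frames.bin_spacing
            ds.attrs["origin_m"] = frames.origin_m
            ds.attrs["created_by"] = created_by
            if seed is not None:
                ds.attrs["seed"] = int(seed)
        return
    np.savetxt(path, frames.data, fmt="%.17g", delimiter=",")
    meta = {
        "fs_slow_hz": frames.fs_slow,
        "bin_spacing_m": frames.bin_spacing,
        "origin_m": frames.origin_m,
        "created_by": created_by,
        "seed": seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                row = [float(v) for v in line.split(",")]
            except ValueError as exc:
                raise FrameParseError(f"non-numeric cell in row {i} of {path}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FrameParseError(
                    f"row {i} of {path} has {len(row)} cells, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise FrameParseError(f"{path} contains no frames")
    return np.asarray(rows, dtype=float)


def read_frames(path: str | Path, meta: dict | None = None) -> FrameMatrix:
    """Read a frame matrix written by :func:`write_frames`.

    For the text dialect, metadata comes from the JSON sidecar unless an
    explicit ``meta`` mapping (keys ``fs_slow_hz``, ``bin_spacing_m``,
    optional ``origin_m``) is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh["frames"]
            return FrameMatrix(
                data=ds[()],
                fs_slow=float(ds.attrs["fs_slow_hz"]),
                bin_spacing=float(ds.attrs["bin_spacing_m"]),
                origin_m=float(ds.attrs.get("origin_m", 0.0)),
            )
    data = _read_csv_matrix(path)
    if meta is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ConfigError(
                f"no metadata: {sidecar} missing and no meta mapping given"
            )
        meta = json.loads(sidecar.read_text())
    try:
        fs = float(meta["fs_slow_hz"])
        spacing = float(meta["bin_spacing_m"])
    except KeyError as exc:
        raise ConfigError(f"metadata missing required key {exc}") from exc
    return FrameMatrix(
        data=data,
        fs_slow=fs,
        bin_spacing=spacing,
        origin_m=float(meta.get("origin_m", 0.0) or 0.0),
    )
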