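"""Maximum-likelihood single-sinusoid fitting via the concentrated objective.

Each fast-time bin's slow-time series x[n] is modelled as a single sinusoid
in white Gaussian noise,

    x[n] = A cos(omega n) + B sin(omega n) [+ C] + w[n],   n = 1..N.

For fixed omega the ML estimate of theta = [A B (C)] is ordinary least
squares against the design matrix H(omega), and the likelihood concentrates
to

    g(omega) = x^T H (H^T H)^{-1} H^T x,

the energy of the projection of x onto the column space of H.  The
frequency estimate is the maximiser of g; here a dense deterministic grid
over the physiological band (default 0.05-3.0 Hz) followed by a few
parabolic refinement steps.  Fit quality is scored with the coefficient of
determination R^2 = 1 - SS_res/SS_tot.

Sample indexing starts at n = 1, and the residual-variance estimate divides
by N (the ML estimator, not an unbiased one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SingularityError

_COND_EPS = 1e-12


@dataclass(frozen=True)
class SinusoidModel:
    """Fitted single-sinusoid parameters (quadrature form)."""

    omega: float  # radians per slow-time sample
    A: float
    B: float
    C: float = 0.0

    @property
    def amplitude(self) -> float:
        return math.hypot(self.A, self.B)

    @property
    def phase(self) -> float:
        """Initial phase of the a*sin(omega n + phi) form."""
        return math.atan2(self.A, self.B)

    def frequency_hz(self, fs_slow: float) -> float:
        return self.omega * fs_slow / (2.0 * math.pi)

    def evaluate(self, N: int) -> np.ndarray:
        n = np.arange(1, N + 1)
        return self.A * np.cos(self.omega * n) + self.B * np.sin(self.omega * n) + self.C


@dataclass(frozen=True)
class FitResult:
    model: SinusoidModel
    r_square: float
    g_value: float
    sigma_sq_hat: float
    note: str = ""


@dataclass(frozen=True)
class FitConfig:
    """Frequency-search configuration (Hz bounds converted via fs_slow)."""

    omega_min_hz: float = 0.05
    omega_max_hz: float = 3.0
    grid_points: int = 1024
    refine_iters: int = 3
    include_offset: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.omega_min_hz < self.omega_max_hz):
            raise ValueError("require 0 < omega_min_hz < omega_max_hz")
        if self.grid_points < 2:
            raise ValueError("grid needs at least 2 points")

    def omega_grid(self, fs_slow: float) -> np.ndarray:
        if self.omega_max_hz >= fs_slow / 2.0:
            raise ValueError("omega_max_hz must be below Nyquist")
        return np.linspace(
            2.0 * math.pi * self.omega_min_hz / fs_slow,
            2.0 * math.pi * self.omega_max_hz / fs_slow,
            self.grid_points,
        )


def build_design_matrix(omega: float, N: int, include_offset: bool = False) -> np.ndarray:
    """Design matrix H(omega): row n is [cos(n omega), sin(n omega) (, 1)], n=1..N."""
    if N < 3:
        raise ValueError("need at least 3 samples")
    if not (0.0 <= omega < math.pi):
        raise ValueError("omega must lie in [0, pi)")
    n = np.arange(1, N + 1)
    cols = [np.cos(omega * n), np.sin(omega * n)]
    if include_offset:
        cols.append(np.ones(N))
    return np.column_stack(cols)


def least_squares_theta(H: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares amplitude estimate theta-hat = (H^T H)^{-1} H^T x."""
    theta, _, rank, _ = np.linalg.lstsq(H, np.asarray(x, dtype=float), rcond=None)
    if rank < H.shape[1]:
        raise SingularityError("design matrix is rank deficient at this frequency")
    return theta


def concentrated_objective(
    omega: float, x: np.ndarray, include_offset: bool = False
) -> float:
    """Projection energy g(omega) = x^T H (H^T H)^{-1} H^T x.

    Rank-deficient frequencies (e.g. omega = 0 without offset) return 0 with
    a warning so a search simply skips them.
    """
    x = np.asarray(x, dtype=float)
    H = build_design_matrix(omega, len(x), include_offset)
    try:
        theta = least_squares_theta(H, x)
    except SingularityError:
        warnings.warn(f"singular design matrix at omega={omega:g}; g set to 0")
        return 0.0
    return float(x @ (H @ theta))


def r_square(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero total variance: R^2 undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Vectorized grid evaluation.  The trig matrices depend only on (grid, N),
# so they are cached across the many bins/seeds of a run.
# ---------------------------------------------------------------------------

_trig_cache: dict[tuple, tuple] = {}
_TRIG_CACHE_MAX = 2


def _grid_tables(omegas: np.ndarray, N: int):
    key = (N, len(omegas), float(omegas[0]), float(omegas[-1]))
    if key in _trig_cache:
        return _trig_cache[key]
    n = np.arange(1, N + 1)
    arg = omegas[:, None] * n[None, :]
    C = np.cos(arg)
    S = np.sin(arg)
    a = np.einsum("ij,ij->i", C, C)
    b = np.einsum("ij,ij->i", C, S)
    d = np.einsum("ij,ij->i", S, S)
    if len(_trig_cache) >= _TRIG_CACHE_MAX:
        _trig_cache.pop(next(iter(_trig_cache)))
    _trig_cache[key] = (C, S, a, b, d)
    return _trig_cache[key]


def grid_objective(X: np.ndarray, omegas: np.ndarray, include_offset: bool = False) -> np.ndarray:
    """g(omega) for every signal: shape (len(omegas), n_signals).

    ``X`` has one signal per row.  The offset-free case uses the closed-form
    2x2 inverse of H^T H; the offset case solves the 3x3 systems per grid
    point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[1]
    if not include_offset:
        C, S, a, b, d = _grid_tables(omegas, N)
        P = C @ X.T  # (G, K)
        Q = S @ X.T
        det = a * d - b * b
        good = det > _COND_EPS * (a + d) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (d[:, None] * P**2 - 2.0 * b[:, None] * P * Q + a[:, None] * Q**2) / det[:, None]
        g[~good, :] = 0.0
        return g
    g = np.empty((len(omegas), X.shape[0]))
    for i, w in enumerate(omegas):
        H = build_design_matrix(float(w), N, include_offset=True)
        HtH = H.T @ H
        HtX = H.T @ X.T
        try:
            theta = np.linalg.solve(HtH, HtX)
        except np.linalg.LinAlgError:
            g[i] = 0.0
            continue
        g[i] = np.einsum("ij,ij->j", HtX, theta)
    return g


def _parabolic_refine(
    x: np.ndarray,
    omegas: np.ndarray,
    gvals: np.ndarray,
    idx: int,
    iters: int,
    include_offset: bool,
) -> tuple[float, float]:
    """Local parabolic interpolation around a grid argmax.

    Keeps a three-point bracket and repeatedly evaluates the parabola
    vertex; returns (omega, g) of the best point seen.
    """
    pts = [(float(omegas[j]), float(gvals[j])) for j in
           range(max(idx - 1, 0), min(idx + 2, len(omegas)))]
    if len(pts) < 3:
        best = max(pts, key=lambda p: p[1])
        return best
    for _ in range(iters):
        pts.sort(key=lambda p: p[0])
        (w0, g0), (w1, g1), (w2, g2) = pts
        denom = (w1 - w0) * (g1 - g2) - (w1 - w2) * (g1 - g0)
        if abs(denom) < 1e-30:
            break
        wv = w1 - 0.5 * ((w1 - w0) ** 2 * (g1 - g2) - (w1 - w2) ** 2 * (g1 - g0)) / denom
        if not (w0 < wv < w2) or not np.isfinite(wv):
            break
        gv = concentrated_objective(wv, x, include_offset)
        allpts = pts + [(wv, gv)]
        allpts.sort(key=lambda p: p[0])
        j = int(np.argmax([p[1] for p in allpts]))
        lo = min(max(j - 1, 0), len(allpts) - 3)
        pts = allpts[lo:lo + 3]
    return max(pts, key=lambda p: p[1])


def _result_at(x: np.ndarray, omega: float, g_val: float, include_offset: bool) -> FitResult:
    H = build_design_matrix(omega, len(x), include_offset)
    theta = least_squares_theta(H, x)
    y_hat = H @ theta
    rsq = r_square(x, y_hat)
    ss_res = float(np.sum((x - y_hat) ** 2))
    C = float(theta[2]) if include_offset else 0.0
    model = SinusoidModel(omega=omega, A=float(theta[0]), B=float(theta[1]), C=C)
    return FitResult(
        model=model,
        r_square=rsq,
        g_value=g_val,
        sigma_sq_hat=ss_res / len(x),
    )


def fit_matrix(X: np.ndarray, config: FitConfig, fs_slow: float) -> list[FitResult]:
    """Fit every row of ``X`` (one slow-time signal per row).

    Shares one grid evaluation across all rows, then refines each row's
    argmax locally.  Grid ties break toward the lowest frequency.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 8:
        raise ValueError("signals must have at least 8 samples")
    omegas = config.omega_grid(fs_slow)
    g = grid_objective(X, omegas, config.include_offset)
    results: list[FitResult] = []
    for j in range(X.shape[0]):
        x = X[j]
        if np.ptp(x) == 0.0:
            results.append(
                FitResult(
                    model=SinusoidModel(omega=float(omegas[0]), A=0.0, B=0.0),
                    r_square=0.0,
                    g_value=0.0,
                    sigma_sq_hat=0.0,
                    note="no sinusoidal content",
                )
            )
            continue
        idx = int(np.argmax(g[:, j]))  # first max -> lowest frequency on ties
        w_best, g_best = float(omegas[idx]), float(g[idx, j])
        if config.refine_iters > 0 and 0 < idx < len(omegas) - 1:
            w_best, g_best = _parabolic_refine(
                x, omegas, g[:, j], idx, config.refine_iters, config.include_offset
            )
        results.append(_result_at(x, w_best, g_best, config.include_offset))
    return results


def fit_sinusoid(x: np.ndarray, config: FitConfig, fs_slow: float) -> FitResult:
    """Fit a single slow-time signal (see :func:`fit_matrix`)."""
    return fit_matrix(np.asarray(x, dtype=float)[None, :], config, fs_slow)[0]
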