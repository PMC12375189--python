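"""Sum-of-sines rhythm fitting and the period/intensity metrics.

Behavioural timelines (feeding rate, interaction rate) are fit with the
model

    y(x) = sum_{i=1..j} a_i * sin(b_i * x + c_i)

by bound-constrained nonlinear least squares (trust-region reflective),
after removing the series mean so the fit is invariant under a constant
offset.  For the single-term model the quantities of interest are the
waveform displacement d = a_1, the curve intensity (peak-to-trough
amplitude) A = 2 d, the angular frequency omega = b_1 (rad/hour) and the
period T = 1/f = 2*pi/omega hours.

Initialisation is deterministic: a Lomb-Scargle periodogram of the centered
series is scanned inside the period bounds, the optimiser is started from
each of the top three peaks (amplitude and phase from a linear fit at fixed
frequency), and the best resulting fit by residual sum of squares is kept —
never worse than its own starting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError

__all__ = ["SineFit", "fit_sum_of_sines", "sine_metrics"]

_TWO_PI = 2.0 * np.pi


@dataclass
class SineFit:
    """Fitted sum-of-sines coefficients and goodness of fit.

    ``a`` (amplitudes, signal units, >= 0), ``b`` (angular frequencies,
    rad/hour) and ``c`` (phases, [0, 2 pi)) each have ``j`` entries.
    ``r2 = 1 − SS_res / SS_tot`` about the series mean (<= 1, can be
    negative for a fit worse than the mean).  ``offset`` is the removed
    series mean.  For ``j == 1`` the derived metrics are exact identities:
    ``A = 2 d`` and ``T * b[0] = 2 pi``.
    """

    j: int
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    r2: float
    offset: float = 0.0
    degenerate: bool = False

    @property
    def d(self) -> float:
        """Waveform displacement (single-term amplitude)."""
        self._require_single()
        return float(self.a[0])

    @property
    def intensity(self) -> float:
        """Curve intensity A = 2 d (peak-to-trough)."""
        return 2.0 * self.d

    @property
    def omega(self) -> float:
        self._require_single()
        return float(self.b[0])

    @property
    def period_h(self) -> float:
        """Period T = 2 pi / omega, hours."""
        return _TWO_PI / self.omega

    @property
    def frequency(self) -> float:
        """f = 1 / T, cycles per hour."""
        return 1.0 / self.period_h

    def _require_single(self) -> None:
        if self.j != 1:
            raise ConfigError(
                f"metric defined for single-term fits only (j={self.j})")

    def predict(self, x_hours: np.ndarray) -> np.ndarray:
        x = np.asarray(x_hours, dtype=float)
        y = np.full_like(x, self.offset)
        for ai, bi, ci in zip(self.a, self.b, self.c):
            y = y + ai * np.sin(bi * x + ci)
        return y


def _model(params: np.ndarray, x: np.ndarray, j: int) -> np.ndarray:
    a = params[:j]
    b = params[j:2 * j]
    c = params[2 * j:]
    return (a[:, None] * np.sin(b[:, None] * x[None, :] + c[:, None])).sum(axis=0)


def _linear_amp_phase(x: np.ndarray, y: np.ndarray, omega: float,
                      ) -> tuple[float, float]:
    """Least-squares amplitude and phase at a fixed angular frequency."""
    s, cth = np.sin(omega * x), np.cos(omega * x)
    design = np.column_stack([s, cth])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha, beta = coef
    return float(np.hypot(alpha, beta)), float(np.arctan2(beta, alpha))


def _lomb_power(x: np.ndarray, y: np.ndarray, omegas: np.ndarray,
                chunk: int = 256) -> np.ndarray:
    """Classic Lomb-Scargle power, vectorised over frequency chunks."""
    power = np.empty(len(omegas))
    for i0 in range(0, len(omegas), chunk):
        w = omegas[i0:i0 + chunk][:, None]
        wt = w * x[None, :]
        tau_arg = np.arctan2(np.sin(2 * wt).sum(axis=1),
                             np.cos(2 * wt).sum(axis=1)) / 2.0
        arg = wt - tau_arg[:, None]
        c = np.cos(arg)
        s = np.sin(arg)
        yc = (y[None, :] * c).sum(axis=1)
        ys = (y[None, :] * s).sum(axis=1)
        power[i0:i0 + chunk] = 0.5 * (yc ** 2 / (c ** 2).sum(axis=1)
                                      + ys ** 2 / (s ** 2).sum(axis=1))
    return power


def _decimate(x: np.ndarray, y: np.ndarray, target: int = 1500,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Block-average a dense series before the periodogram scan (init only;
    the nonlinear fit always sees the full-resolution data)."""
    n = len(x)
    if n <= target:
        return x, y
    k = int(np.ceil(n / target))
    m = (n // k) * k
    return (x[:m].reshape(-1, k).mean(axis=1),
            y[:m].reshape(-1, k).mean(axis=1))


def _periodogram_peaks(x: np.ndarray, y: np.ndarray, omega_lo: float,
                       omega_hi: float, n_freq: int = 1500,
                       n_peaks: int = 3) -> list[float]:
    xd, yd = _decimate(x, y)
    omegas = np.linspace(omega_lo, omega_hi, n_freq)
    power = _lomb_power(xd, yd, omegas)
    interior = (power[1:-1] >= power[:-2]) & (power[1:-1] >= power[2:])
    idx = np.flatnonzero(interior) + 1
    if len(idx) == 0:
        idx = np.array([int(np.argmax(power))])
    idx = idx[np.argsort(power[idx])[::-1][:n_peaks]]
    return [float(omegas[i]) for i in idx]


def _normalize(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force a >= 0 and c in [0, 2 pi) via sin(x + c + pi) = -sin(x + c)."""
    a = a.copy()
    c = c.copy()
    neg = a < 0
    a[neg] = -a[neg]
    c[neg] += np.pi
    c = np.mod(c, _TWO_PI)
    return a, b, c


def fit_sum_of_sines(x_hours: np.ndarray, y: np.ndarray, j: int = 1,
                     period_bounds_h: tuple[float, float] = (4.0, 48.0),
                     ) -> SineFit:
    """Fit ``y(x) = sum a_i sin(b_i x + c_i)`` to a timeline in hours.

    Needs at least ``4 j + 2`` points.  A flat series returns a fit flagged
    degenerate (a ≈ 0) rather than raising.  The frequency of every term is
    bounded inside ``period_bounds_h`` (hours).
    """
    x = np.asarray(x_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    if j < 1:
        raise ConfigError("j must be >= 1")
    if len(x) < 4 * j + 2:
        raise ConfigError(
            f"need at least {4 * j + 2} points for a {j}-term fit, got {len(x)}")
    p_lo, p_hi = period_bounds_h
    if not 0 < p_lo < p_hi:
        raise ConfigError("period bounds must satisfy 0 < lo < hi")
    omega_lo, omega_hi = _TWO_PI / p_hi, _TWO_PI / p_lo

    mean = float(np.mean(y))
    yc = y - mean
    scale = float(np.std(yc))
    if scale < 1e-12 * max(1.0, abs(mean)) or scale == 0.0:
        mid = np.sqrt(omega_lo * omega_hi)
        return SineFit(j=j, a=np.zeros(j), b=np.full(j, mid), c=np.zeros(j),
                       r2=0.0, offset=mean, degenerate=True)
    ss_tot = float(np.sum(yc ** 2))

    peaks = _periodogram_peaks(x, yc, omega_lo, omega_hi)
    lb = np.concatenate([np.zeros(j), np.full(j, omega_lo), np.full(j, -_TWO_PI)])
    ub = np.concatenate([np.full(j, np.inf), np.full(j, omega_hi),
                         np.full(j, 2 * _TWO_PI)])

    best: tuple[float, np.ndarray] | None = None
    for peak in peaks:
        # greedy peel: init each term from the strongest residual peak
        a0 = np.empty(j)
        b0 = np.empty(j)
        c0 = np.empty(j)
        resid = yc.copy()
        omega = peak
        for term in range(j):
            amp, phase = _linear_amp_phase(x, resid, omega)
            a0[term], b0[term], c0[term] = max(amp, 1e-6 * scale), omega, phase
            resid = resid - a0[term] * np.sin(b0[term] * x + c0[term])
            if term + 1 < j:
                omega = _periodogram_peaks(x, resid, omega_lo, omega_hi,
                                           n_peaks=1)[0]
        p0 = np.concatenate([a0, b0, np.mod(c0, _TWO_PI)])
        p0 = np.clip(p0, lb, ub)
        sse0 = float(np.sum((_model(p0, x, j) - yc) ** 2))
        sol = least_squares(lambda p: _model(p, x, j) - yc, p0,
                            bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        sse = float(np.sum(sol.fun ** 2))
        params, cost = (sol.x, sse) if sse <= sse0 else (p0, sse0)
        if best is None or cost < best[0]:
            best = (cost, params)

    assert best is not None
    sse, params = best
    a, b, c = _normalize(params[:j], params[j:2 * j], params[2 * j:])
    r2 = 1.0 - sse / ss_tot
    degenerate = bool(np.max(a) < 1e-8 * scale)
    return SineFit(j=j, a=a, b=b, c=c, r2=float(r2), offset=mean,
                   degenerate=degenerate)


def sine_metrics(fit: SineFit) -> dict:
    """Intensity, period and goodness of a single-term fit.

    A = 2 a_1 (signal units, peak-to-trough), T = 2 pi / b_1 (hours).
    Raises for multi-term fits, whose metrics are not defined here.
    """
    if fit.j != 1:
        raise ConfigError(f"sine metrics defined for j=1 fits only (j={fit.j})")
    return {"A": fit.intensity, "T": fit.period_h, "r2": fit.r2}
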