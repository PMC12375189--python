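"""Cumulative food intake, interaction-bout detection and rate outputs.

Intake is the mass difference readout: the amount eaten by time *t* is the
initially calibrated mass minus the filtered plateau at *t* (the "lesser
value"), clipped at zero.  Interactions are the activity proxy: any
bidirectional fluctuation of the raw trace about the current plateau that
exceeds a predefined threshold, with crossings inside a refractory window
of a prior event merged into a single bout.  The primary outputs of the
pipeline are the time derivatives of cumulative intake and cumulative
interactions — the feeding rate and activity rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ConfigError
from .filtering import PlateauSeries

__all__ = [
    "IntakeSeries",
    "EventSeries",
    "RateSeries",
    "cumulative_intake",
    "detect_interactions",
    "rates",
    "phase_totals",
]


@dataclass
class IntakeSeries:
    """Cumulative intake in grams: starts at 0, non-decreasing."""

    times: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self) else 0.0

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.cumulative, prepend=0.0)


@dataclass
class EventSeries:
    """Interaction bout times plus the cumulative count on the sample grid."""

    event_times: np.ndarray
    times: np.ndarray
    cumulative: np.ndarray

    def __len__(self) -> int:
        return len(self.event_times)

    @property
    def count(self) -> int:
        return len(self.event_times)

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.cumulative, prepend=0.0)


@dataclass
class RateSeries:
    """Per-hour rate (g/h or events/h) on the sample grid."""

    times: np.ndarray
    rate: np.ndarray
    units: str = "g/h"


def cumulative_intake(plateaus: PlateauSeries, calibration_mass: float,
                      buffer: float = 0.1) -> IntakeSeries:
    """Intake(t) = calibration mass − plateau(t), clipped at 0.

    A plateau exceeding the calibration mass by more than ``buffer`` means
    the device was calibrated against the wrong mass and raises
    :class:`CalibrationError`.
    """
    if calibration_mass <= 0:
        raise CalibrationError("calibration mass must be positive")
    mass = plateaus.mass
    if len(mass) and float(mass.max()) > calibration_mass + buffer:
        raise CalibrationError(
            f"plateau {mass.max():.3f} g exceeds calibration mass "
            f"{calibration_mass:.3f} g + buffer {buffer:.3f} g")
    intake = np.clip(calibration_mass - mass, 0.0, None)
    intake = np.maximum.accumulate(intake)  # guard against numerical residue
    return IntakeSeries(times=plateaus.times.copy(), cumulative=intake)


def detect_interactions(t: np.ndarray, raw_mass: np.ndarray,
                        plateaus: PlateauSeries, threshold: float = 0.1,
                        refractory: float = 10.0,
                        dead_band: float | None = None,
                        recenter_window: float = 60.0) -> EventSeries:
    """Count animal-device interaction bouts.

    An event is registered whenever ``|raw − plateau|`` crosses ``threshold``
    in either direction; crossings within ``refractory`` seconds of the
    previous event's start merge into that bout.  Returns the bout start
    times and the cumulative count sampled on the input grid.

    The plateau staircase sits up to one filter dead-band above the true
    mass while sub-threshold feeding accumulates, which would register as
    spurious slow "fluctuations".  Before thresholding, the reference level
    is therefore re-centered by the rolling median (``recenter_window``
    seconds, robust to genuine short excursions) of the residual, clipped
    to at most ``dead_band`` grams downward (default: the threshold, i.e.
    the band-pass buffer in the standard configuration).
    """
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    if dead_band is None:
        dead_band = threshold
    t = np.asarray(t, dtype=float)
    raw = np.asarray(raw_mass, dtype=float)
    resid = raw - plateaus.mass
    if dead_band > 0 and len(t) > 2 and recenter_window > 0:
        from scipy.ndimage import median_filter as _medf
        dt = float(np.median(np.diff(t)))
        w = max(1, int(round(recenter_window / max(dt, 1e-9))) | 1)
        offset = np.clip(_medf(resid, size=min(w, len(resid)), mode="nearest"),
                         -dead_band, 0.0)
    else:
        offset = 0.0
    dev = np.abs(resid - offset)
    crossing = np.flatnonzero(dev > threshold)
    events: list[float] = []
    last = -np.inf
    for i in crossing:
        if t[i] - last > refractory:
            events.append(float(t[i]))
            last = t[i]
    ev = np.asarray(events, dtype=float)
    cumulative = np.searchsorted(ev, t, side="right").astype(float)
    return EventSeries(event_times=ev, times=t.copy(), cumulative=cumulative)


def rates(t: np.ndarray, cumulative: np.ndarray, window: float = 3600.0,
          units: str = "g/h") -> RateSeries:
    """Centered finite-difference rate of a cumulative series, per hour.

    rate(t) = [C(t + w/2) − C(t − w/2)] / w × 3600, with the window clamped
    one-sided at the ends of the recording.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(cumulative, dtype=float)
    if len(t) < 2:
        raise ConfigError("rates need at least 2 samples")
    if window < 2 * float(np.median(np.diff(t))):
        raise ConfigError("window must span at least 2 samples")
    half = window / 2.0
    hi = np.minimum(t + half, t[-1])
    lo = np.maximum(t - half, t[0])
    span = hi - lo
    rate = (np.interp(hi, t, c) - np.interp(lo, t, c)) / span * 3600.0
    return RateSeries(times=t.copy(), rate=rate, units=units)


def phase_totals(t: np.ndarray, increments: np.ndarray, segments,
                 day_length_s: float = 86400.0) -> dict:
    """Partition per-sample increments into light/dark totals per day.

    ``segments`` is a :class:`~cagescale.light.LightSegments`; ON samples
    count as light, OFF as dark, RAMP is excluded from the phase split but
    included in the daily total.  Days are successive ``day_length_s``
    windows from the first sample.  Returns per-day arrays plus means and
    the standard error of the mean (sample SD / sqrt(n days)).
    """
    t = np.asarray(t, dtype=float)
    inc = np.asarray(increments, dtype=float)
    if segments is None or len(segments.segments) == 0:
        raise ConfigError("phase totals need a light segmentation")
    labels = segments.label_at(t)
    day = ((t - t[0]) / day_length_s).astype(int)
    n_days = int(day.max()) + 1
    light = np.zeros(n_days)
    dark = np.zeros(n_days)
    total = np.zeros(n_days)
    for d in range(n_days):
        sel = day == d
        total[d] = inc[sel].sum()
        light[d] = inc[sel & (labels == "ON")].sum()
        dark[d] = inc[sel & (labels == "OFF")].sum()

    def _sem(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    return {
        "light_per_day": light,
        "dark_per_day": dark,
        "total_per_day": total,
        "light_total": float(light.sum()),
        "dark_total": float(dark.sum()),
        "day_total": float(total.sum()),
        "mean_per_day": float(total.mean()),
        "sem_per_day": _sem(total),
        "n_days": n_days,
    }
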