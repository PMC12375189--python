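"""The mass/light filtering steps of the processing pipeline.

The raw load-cell trace mixes four signals: the true food mass (a staircase
that only ever steps down as the animal removes pieces), zero-net push/pull
transients from animal-device interaction, sensor noise, and occasional
"chip" artifacts (debris on the holder: a sharp upward spike followed by a
steep dip below the pre-spike level).  The filters here unmix them:

``mass_filter``
    Persistence-gated band-pass.  The output holds the last accepted level
    until the input departs from it by more than ``buffer`` grams for at
    least ``plateau_min_duration`` seconds.  Implemented in two passes:
    change-points are found online, then each inter-change segment level is
    re-estimated as the median of the input samples it spans, so long stable
    plateaus are recovered to well below the noise floor.

``plateau_filter``
    Turns the band-passed series into a non-increasing staircase of
    plateaus: upward excursions (pushes) are removed outright, and downward
    excursions that recover to the running level within ``pull_window``
    seconds (pulls) are removed as transients.  Optionally re-anchors the
    final plateau on the trailing median of the raw trace — the intake
    readout is calibrated mass minus the final *stable* value, so the
    terminal level should not inherit the band-pass dead-band.

``chip_filter``
    Detects spike-then-dip chip artifacts and attenuates them so the net
    mass drop across the chip interval is zero, logging every attenuation.

``ldr_smooth``, ``crop_trace``, ``fold_daily``, ``compress`` are the light
smoothing, cropping, daily-alignment and binning steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import median_filter as _median_filter

from .errors import ConfigError
from .log_io import RawLog

__all__ = [
    "FilterConfig",
    "PlateauSeries",
    "ChipEvent",
    "ChipReport",
    "recommended_buffer",
    "crop_trace",
    "mass_filter",
    "plateau_filter",
    "chip_filter",
    "ldr_smooth",
    "fold_daily",
    "compress",
]


def recommended_buffer(drift_fluctuation_g: float, decimals: int = 1) -> float:
    """Band-pass buffer recommended from a measured drift fluctuation.

    The buffer is set to twice the peak random fluctuation observed in a
    static drift test, rounded to the resolution a user would configure
    (0.1 g steps by default): ``2 × 0.045 g ≈ 0.1 g``.
    """
    if drift_fluctuation_g < 0:
        raise ValueError("fluctuation must be non-negative")
    return round(2.0 * drift_fluctuation_g, decimals)


@dataclass
class FilterConfig:
    """All tunable pipeline parameters.

    buffer : g — band-pass tolerance; fluctuations below it are noise.
    plateau_min_duration : s — a level change must persist this long.
    pull_window : s — a drop recovering within this window is a transient pull.
    chip_spike_min / chip_dip_min : g — chip detection thresholds.
    chip_window : s — max spike-to-settled-dip span of a chip.
    ldr_smooth_window : samples — moving-median width for the light trace.
    bin_width : s — compression bin width.
    crop : (t0, t1) seconds since start, or None for the full recording.
    fold_mode : 'ZT' | 'CT' | 'none' — daily alignment of the output timeline.
    interaction_threshold : g — bidirectional event threshold (None → buffer).
    refractory : s — events within this window of a prior event merge.
    rate_window : s — centered-difference window for rate outputs.
    settle_window : s — trailing window for the final-plateau re-anchor.
    """

    buffer: float = recommended_buffer(0.045)
    plateau_min_duration: float = 5.0
    pull_window: float = 120.0
    chip_spike_min: float = 0.5
    chip_dip_min: float = 0.3
    chip_window: float = 300.0
    ldr_smooth_window: int = 5
    bin_width: float = 60.0
    crop: tuple[float, float] | None = None
    fold_mode: Literal["ZT", "CT", "none"] = "none"
    interaction_threshold: float | None = None
    refractory: float = 10.0
    rate_window: float = 3600.0
    settle_window: float = 120.0

    def __post_init__(self) -> None:
        if self.buffer <= 0:
            raise ConfigError("buffer must be > 0")
        for name in ("plateau_min_duration", "pull_window", "chip_window",
                     "bin_width", "refractory", "rate_window", "settle_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.ldr_smooth_window < 1:
            raise ConfigError("ldr_smooth_window must be >= 1")
        if self.crop is not None and not self.crop[0] < self.crop[1]:
            raise ConfigError("crop requires t0 < t1")
        if self.fold_mode not in ("ZT", "CT", "none"):
            raise ConfigError(f"unknown fold_mode {self.fold_mode!r}")

    @property
    def threshold(self) -> float:
        """Effective interaction threshold (defaults to the buffer)."""
        return self.buffer if self.interaction_threshold is None \
            else self.interaction_threshold

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        if d.get("crop") is not None:
            d["crop"] = tuple(d["crop"])
        return cls(**d)


@dataclass
class PlateauSeries:
    """Piecewise-constant, non-increasing filtered mass."""

    times: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.times.shape != self.mass.shape:
            raise ValueError("times and mass must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.mass) <= 1e-12))


@dataclass(frozen=True)
class ChipEvent:
    start: float
    end: float
    spike_height: float
    attenuated_mass: float
    manual: bool


@dataclass
class ChipReport:
    """Log of every chip attenuation applied (intervals disjoint)."""

    events: list[ChipEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_attenuated(self) -> float:
        return float(sum(e.attenuated_mass for e in self.events))


def crop_trace(log: RawLog, t0: float, t1: float,
               rezero: bool = False) -> RawLog:
    """Restrict a recording to ``t0 <= t < t1`` (seconds since start).

    Raises :class:`ConfigError` if the window misses the recording.
    """
    if not t0 < t1:
        raise ConfigError("crop requires t0 < t1")
    t = log.t
    mask = (t >= t0) & (t < t1)
    if not mask.any():
        raise ConfigError(
            f"crop window [{t0}, {t1}) does not overlap recording "
            f"[{t[0]}, {t[-1]}]")
    rec = log.records.loc[mask].reset_index(drop=True).copy()
    start = log.start_time
    if rezero:
        offset = float(rec["t"].iloc[0])
        rec["t"] = rec["t"] - offset
        from datetime import timedelta
        start = log.start_time + timedelta(seconds=offset)
    return RawLog(records=rec, calibration_mass=log.calibration_mass,
                  start_time=start, source_id=log.source_id,
                  n_dropped=log.n_dropped)


def _min_samples(t: np.ndarray, min_duration: float) -> int:
    if len(t) < 2:
        return 1
    dt = float(np.median(np.diff(t)))
    return max(1, int(np.ceil(min_duration / max(dt, 1e-9))))


def _change_points(x: np.ndarray, buffer: float, min_n: int) -> list[int]:
    """Online pass: indices where a persistent departure from the held level
    began.  A departure run resets whenever a sample returns within buffer."""
    n = len(x)
    level = float(np.median(x[:min_n])) if n >= min_n else float(x[0])
    breaks = [0]
    run_start = -1
    i = 0
    while i < n:
        if abs(x[i] - level) > buffer:
            if run_start < 0:
                run_start = i
            if i - run_start + 1 >= min_n:
                breaks.append(run_start)
                level = float(np.median(x[run_start:i + 1]))
                run_start = -1
        else:
            run_start = -1
        i += 1
    return breaks


def mass_filter(t: np.ndarray, mass: np.ndarray, buffer: float = 0.1,
                min_duration: float = 5.0) -> np.ndarray:
    """Persistence-gated band-pass of the raw mass channel.

    Sub-``buffer`` jitter is flattened to the held level; a departure that
    persists for at least ``min_duration`` seconds commits a new level.
    Each level is the median of the raw samples in its segment.  Empty input
    returns an empty array.
    """
    if buffer <= 0:
        raise ConfigError("buffer must be > 0")
    t = np.asarray(t, dtype=float)
    x = np.asarray(mass, dtype=float)
    if len(x) == 0:
        return x.copy()
    min_n = _min_samples(t, min_duration)
    breaks = _change_points(x, buffer, min_n)
    out = np.empty_like(x)
    bounds = breaks + [len(x)]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        out[b0:b1] = np.median(x[b0:b1])
    return out


def _segments(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Runs of constant value as (start, end_exclusive, value)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return [(int(s), int(e), float(values[s])) for s, e in zip(starts, ends)]


def plateau_filter(t: np.ndarray, filtered: np.ndarray, config: FilterConfig,
                   raw: np.ndarray | None = None) -> PlateauSeries:
    """Reduce a band-passed mass series to a non-increasing staircase.

    Pushes (levels at or above the running plateau) are dropped; a candidate
    drop whose level recovers to within ``buffer`` of the running plateau
    inside ``pull_window`` seconds — and stays there — is a transient pull
    and is dropped too.  Retained drops persist at least
    ``plateau_min_duration`` seconds by construction of the band-pass.

    When ``raw`` (the pre-band-pass mass) is supplied, the final plateau is
    re-anchored on the median of the trailing ``settle_window`` seconds if
    that trailing stretch is quiet (median absolute deviation below half the
    buffer) and sits below the last plateau: daily intake is defined as the
    calibrated mass minus the final *stable* reading, which the band-pass
    dead-band would otherwise bias by up to one buffer.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(filtered, dtype=float)
    if len(x) == 0:
        return PlateauSeries(times=t.copy(), mass=x.copy())
    segs = _segments(x)
    buffer = config.buffer
    out = np.empty_like(x)
    level = segs[0][2]
    for k, (s, e, v) in enumerate(segs):
        if v >= level - buffer:
            out[s:e] = level
            continue
        # candidate drop: a transient pull spends most of the following
        # pull_window back at the running level; a genuine feeding step
        # stays down.  The window median separates the two robustly even
        # when several transients cluster.
        j_end = int(np.searchsorted(t, t[s] + config.pull_window, side="right"))
        med = float(np.median(x[s:max(j_end, e)]))
        if med - v > (level - v) / 2.0:
            out[s:e] = level          # pull: hold the running plateau
        else:
            level = v
            out[s:e] = level

    if raw is not None and len(raw) == len(x):
        n_tail = _min_samples(t, config.settle_window)
        if 3 <= n_tail < len(x):
            tail = np.asarray(raw, dtype=float)[-n_tail:]
            med = float(np.median(tail))
            mad = float(np.median(np.abs(tail - med)))
            if mad < buffer / 2:
                # re-anchor in either direction: downward absorbs the
                # band-pass dead-band; upward undoes an end-truncated pull
                # that the window-median test could not classify.  Never
                # rise above the preceding plateau.
                out[-n_tail:] = min(med, out[-n_tail - 1])
    # enforce exact monotonicity against numerical residue
    out = np.minimum.accumulate(out)
    return PlateauSeries(times=t.copy(), mass=out)


def chip_filter(plateaus: PlateauSeries, config: FilterConfig,
                manual_intervals: Sequence[tuple[float, float]] = (),
                reference: np.ndarray | None = None,
                ) -> tuple[PlateauSeries, ChipReport]:
    """Attenuate spike-then-dip chip artifacts.

    Automatic detection needs ``reference`` — the band-passed mass series on
    the same time base — because the non-increasing plateau series cannot
    retain the upward spike.  A chip is an excursion of ``reference`` at
    least ``chip_spike_min`` above the current plateau, followed within
    ``chip_window`` seconds by the plateau settling at least ``chip_dip_min``
    below its pre-spike value.  Attenuation raises every level from the end
    of the chip interval so the net drop across the interval is zero; the
    interval itself is held at the pre-chip level.  ``manual_intervals``
    force attenuation regardless of detection (overlapping manual intervals
    are an error).
    """
    t = plateaus.times
    mass = plateaus.mass.copy()
    report = ChipReport()

    manual = sorted((float(a), float(b)) for a, b in manual_intervals)
    for (a0, a1), (b0, b1) in zip(manual, manual[1:]):
        if b0 < a1:
            raise ConfigError(f"manual chip intervals overlap: "
                              f"({a0},{a1}) and ({b0},{b1})")
    for a, b in manual:
        if not a < b:
            raise ConfigError("manual chip interval requires t0 < t1")

    intervals: list[tuple[float, float, float, bool]] = [
        (a, b, 0.0, True) for a, b in manual]

    if reference is not None and len(reference) == len(mass):
        ref = np.asarray(reference, dtype=float)
        above = ref - mass > config.chip_spike_min
        idx = np.flatnonzero(above)
        # group contiguous spike samples into candidate spikes
        if len(idx):
            splits = np.flatnonzero(np.diff(idx) > 1) + 1
            groups = np.split(idx, splits)
            for g in groups:
                ts = t[g[0]]
                pre = mass[g[0] - 1] if g[0] > 0 else mass[0]
                t_end = ts + config.chip_window
                sel = (t > ts) & (t <= t_end)
                if not sel.any():
                    continue
                post = mass[np.flatnonzero(sel)[-1]]
                if pre - post >= config.chip_dip_min:
                    spike = float(ref[g].max() - pre)
                    if not any(a <= ts < b for a, b, *_ in intervals):
                        intervals.append((float(ts), float(t_end), spike, False))

    intervals.sort()
    for t0, t1, spike, is_manual in intervals:
        i0 = int(np.searchsorted(t, t0, side="left"))
        i1 = int(np.searchsorted(t, t1, side="right"))
        if i0 >= len(t):
            continue
        pre = mass[i0 - 1] if i0 > 0 else mass[0]
        post = mass[min(i1, len(mass)) - 1] if i1 > 0 else mass[-1]
        delta = float(pre - post)
        if delta <= 0:
            continue
        mass[i0:i1] = pre
        mass[i1:] += delta
        report.events.append(ChipEvent(start=t0, end=t1, spike_height=spike,
                                       attenuated_mass=delta, manual=is_manual))
    mass = np.minimum.accumulate(mass)
    return PlateauSeries(times=t.copy(), mass=mass), report


def ldr_smooth(ldr: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-median smoothing of the light-sensor trace.

    Length-preserving; a window of 1 is the identity.  Median smoothing
    removes single-sample glitches (window >= 3) and preserves monotone
    ramps, and the output range is a subset of the input range.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    x = np.asarray(ldr, dtype=float)
    if window == 1 or len(x) == 0:
        return x.copy()
    return _median_filter(x, size=min(window, len(x)), mode="nearest")


def fold_daily(t: np.ndarray, values: np.ndarray, anchor_s: float,
               mode: Literal["ZT", "CT"] = "ZT", bin_width_h: float = 0.5,
               period_h: float = 24.0,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold a timeline onto a 24 h axis anchored at lights-on.

    ``anchor_s`` is the recording time (seconds) of lights-on (ZT0) under a
    light-dark cycle, or of the projected previous lights-on (CT0) in
    constant darkness.  Multiple days are combined by per-bin mean; the
    per-bin sample count is returned alongside.

    Returns ``(bin_centers_h, mean, n)`` with centers in [0, 24).
    """
    if mode not in ("ZT", "CT"):
        raise ConfigError(f"unknown fold mode {mode!r}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(t) == 0:
        raise ConfigError("cannot fold an empty series")
    phase = ((t - anchor_s) / 3600.0) % period_h
    n_bins = int(np.ceil(period_h / bin_width_h))
    idx = np.minimum((phase / bin_width_h).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    centers = (np.arange(n_bins) + 0.5) * bin_width_h
    return centers, mean, counts


def compress(t: np.ndarray, values: np.ndarray, bin_width: float,
             how: Literal["mean", "sum"] = "mean",
             ) -> tuple[np.ndarray, np.ndarray]:
    """Bin a series to ``bin_width`` seconds.

    ``mean`` for level-like channels (mass, LDR), ``sum`` for increment-like
    channels (intake increments, event counts) so totals are conserved
    exactly.  Output length is ``ceil(span / bin_width)``; bin times are the
    bin start times.
    """
    if how not in ("mean", "sum"):
        raise ConfigError(f"unknown aggregation {how!r}")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(t) == 0:
        return t.copy(), values.copy()
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    t0 = t[0]
    idx = ((t - t0) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    if how == "sum":
        agg = sums
    else:
        counts = np.bincount(idx, minlength=n_bins)
        agg = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                        where=counts > 0)
    times = t0 + np.arange(n_bins) * bin_width
    return times, agg
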