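"""Light-sensor trace segmentation and light-schedule inference.

The light-dependent resistor reports relative cage illumination in arbitrary
units — there is no absolute calibration — so classification is threshold
based: samples at or above ``hi`` are lights-ON, at or below ``lo`` are
lights-OFF, and sustained stretches in between are RAMP (dimming).  When
thresholds are not supplied they are auto-set at 25% / 75% of the observed
range, which splits any reasonably bimodal trace.  Segments feed Zeitgeber-
time alignment (ZT0 = lights-on) and the light/dark phase split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .errors import ConfigError

__all__ = ["LightSegments", "LightSchedule", "classify_light", "infer_schedule"]

_EPS = 1e-9


@dataclass
class LightSegments:
    """Contiguous, non-overlapping (start_s, end_s, label) covering the span.

    ``ambiguous`` is set when auto-thresholding saw an (effectively)
    constant trace, where ON vs OFF cannot be resolved in arbitrary units.
    """

    segments: list[tuple[float, float, str]]
    ambiguous: bool = False

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def span(self) -> float:
        return self.segments[-1][1] - self.segments[0][0] if self.segments else 0.0

    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e, _ in self.segments])

    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.segments]

    def label_at(self, t: np.ndarray) -> np.ndarray:
        """Label of the segment containing each time (end-exclusive)."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s for s, _, _ in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        labs = np.array(self.labels())
        return labs[idx]

    def total_on(self) -> float:
        return float(sum(e - s for s, e, lab in self.segments if lab == "ON"))


@dataclass
class LightSchedule:
    """Inferred lighting regime.

    mode: 'LD' (alternating ~24 h light-dark), 'DD' (constant dark),
    'LL' (constant light) or 'irregular'.  ``lights_on_s`` is the recording
    time of the first lights-on; ``lights_on_clock`` a clock time when the
    recording start time is known; ``photoperiod_h`` the median ON duration.
    """

    mode: str
    lights_on_s: float | None = None
    lights_on_clock: str | None = None
    photoperiod_h: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "LD" and self.photoperiod_h is not None:
            if not 0.0 < self.photoperiod_h < 24.0:
                raise ConfigError("LD photoperiod must be in (0, 24) h")


def classify_light(t: np.ndarray, ldr: np.ndarray, lo: float | None = None,
                   hi: float | None = None, debounce: int = 5) -> LightSegments:
    """Segment an LDR trace into ON / OFF / RAMP stretches.

    ``lo``/``hi`` default to the 25% / 75% points of the observed range.
    Between-threshold excursions shorter than ``debounce`` samples are
    absorbed into the preceding segment; longer ones become RAMP.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(ldr, dtype=float)
    if len(x) == 0:
        return LightSegments(segments=[], ambiguous=True)
    rng = float(x.max() - x.min())
    ambiguous = False
    if lo is None or hi is None:
        if rng < _EPS:
            # constant trace: unresolvable in arbitrary units
            end = t[-1] + (t[-1] - t[0]) / max(len(t) - 1, 1)
            return LightSegments(segments=[(float(t[0]), float(end), "OFF")],
                                 ambiguous=True)
        lo = x.min() + 0.25 * rng if lo is None else lo
        hi = x.min() + 0.75 * rng if hi is None else hi
        # a unimodal (noise-only) trace puts most samples between the
        # quarter-range thresholds; a genuinely bimodal on/off trace puts
        # almost none there.  Treat the former as constant: ON vs OFF is
        # unresolvable in arbitrary units.
        mid_fraction = float(np.mean((x > lo) & (x < hi)))
        if mid_fraction > 0.5:
            end = t[-1] + (t[-1] - t[0]) / max(len(t) - 1, 1)
            return LightSegments(segments=[(float(t[0]), float(end), "OFF")],
                                 ambiguous=True)
    if not lo < hi:
        raise ConfigError("classify_light requires lo < hi")

    state = np.where(x >= hi, 1, np.where(x <= lo, -1, 0))
    # collapse short mid-band runs into the preceding state
    segs: list[list] = []  # [start_idx, end_idx, state]
    for i, s in enumerate(state):
        if segs and segs[-1][2] == s:
            segs[-1][1] = i + 1
        else:
            segs.append([i, i + 1, int(s)])
    cleaned: list[list] = []
    for seg in segs:
        if seg[2] == 0 and (seg[1] - seg[0]) <= debounce and cleaned:
            cleaned[-1][1] = seg[1]
        elif cleaned and cleaned[-1][2] == seg[2]:
            cleaned[-1][1] = seg[1]
        else:
            cleaned.append(seg)
    if cleaned and cleaned[0][2] == 0 and (cleaned[0][1] - cleaned[0][0]) <= debounce \
            and len(cleaned) > 1:
        cleaned[1][0] = cleaned[0][0]
        cleaned = cleaned[1:]

    dt = (t[-1] - t[0]) / max(len(t) - 1, 1)
    names = {1: "ON", -1: "OFF", 0: "RAMP"}
    out: list[tuple[float, float, str]] = []
    for i0, i1, s in cleaned:
        start = float(t[i0])
        end = float(t[i1]) if i1 < len(t) else float(t[-1] + dt)
        lab = names[s]
        if out and out[-1][2] == lab:
            out[-1] = (out[-1][0], end, lab)
        else:
            out.append((start, end, lab))
    return LightSegments(segments=out, ambiguous=ambiguous)


def infer_schedule(segments: LightSegments, start_time: datetime | None = None,
                   period_tol_h: float = 1.0) -> LightSchedule:
    """Infer the lighting regime from a segmentation.

    LD requires alternating ON onsets with a stable period of 24 ± 1 h;
    lights-on is the first full ON onset and the photoperiod the median ON
    duration.  No ON segment → DD; no OFF segment → LL; anything else is
    labelled irregular.
    """
    labels = segments.labels()
    if not labels:
        return LightSchedule(mode="irregular")
    has_on = "ON" in labels
    has_off = "OFF" in labels
    if not has_on:
        return LightSchedule(mode="DD")
    if not has_off:
        return LightSchedule(mode="LL")

    on = [(s, e) for s, e, lab in segments.segments if lab == "ON"]
    span_start = segments.segments[0][0]
    span_end = segments.segments[-1][1]
    # drop ON segments truncated by the recording boundary from duration stats
    full_on = [(s, e) for s, e in on if s > span_start and e < span_end]
    onsets = [s for s, _ in on if s > span_start]
    if full_on:
        photoperiod_h = float(np.median([e - s for s, e in full_on])) / 3600.0
    else:
        # every ON segment is boundary-truncated; truncation only shortens,
        # so the longest one is the best available photoperiod estimate
        photoperiod_h = float(max(e - s for s, e in on)) / 3600.0
    if not 0.0 < photoperiod_h < 24.0:
        return LightSchedule(mode="irregular")

    if len(onsets) >= 2:
        periods = np.diff(onsets) / 3600.0
        if np.any(np.abs(periods - 24.0) > period_tol_h):
            return LightSchedule(mode="irregular")
    if not onsets:
        # recording starts inside the only ON phase; still a plausible LD day
        onsets = [on[0][0]]

    lights_on_s = float(onsets[0] % 86400.0) if onsets else None
    clock = None
    if start_time is not None and onsets:
        sod = (start_time.hour * 3600 + start_time.minute * 60
               + start_time.second + onsets[0]) % 86400.0
        clock = f"{int(sod // 3600):02d}:{int(sod % 3600 // 60):02d}"
    return LightSchedule(mode="LD", lights_on_s=float(onsets[0]),
                         lights_on_clock=clock, photoperiod_h=photoperiod_h)
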