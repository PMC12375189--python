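"""Processed-recording container and run metadata.

:class:`ProcessedTrace` is the column store behind the processed output
CSV: the raw and filtered mass channels, the plateau staircase, cumulative
intake and interactions, their per-hour rates, and the smoothed/classified
light channel, all on the (possibly cropped) sample grid.
:class:`RunMetadata` is the two-column key,value sidecar: descriptive
labels, every filter parameter that touched the data (each exactly once),
the chip-attenuation log, and summary totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .filtering import ChipReport, FilterConfig, compress

__all__ = ["ProcessedTrace", "RunMetadata"]


@dataclass
class ProcessedTrace:
    times: np.ndarray
    mass_raw: np.ndarray
    mass_filtered: np.ndarray
    plateau: np.ndarray
    intake: np.ndarray
    interactions: np.ndarray
    feeding_rate: np.ndarray
    interaction_rate: np.ndarray
    ldr_raw: np.ndarray
    ldr_smooth: np.ndarray
    light_label: np.ndarray
    switch1: np.ndarray
    switch2: np.ndarray
    config: FilterConfig
    calibration_mass: float
    start_time: datetime
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "mass_raw": self.mass_raw,
            "mass_filtered": self.mass_filtered,
            "plateau_g": self.plateau,
            "intake_g": self.intake,
            "interactions": self.interactions,
            "feeding_rate_g_per_h": self.feeding_rate,
            "interaction_rate_per_h": self.interaction_rate,
            "ldr_raw": self.ldr_raw,
            "ldr_smooth": self.ldr_smooth,
            "light": self.light_label,
            "switch1": self.switch1.astype(int),
            "switch2": self.switch2.astype(int),
        })

    def compressed_frame(self, bin_width: float | None = None) -> pd.DataFrame:
        """Bin the trace to the configured compression width.

        Level channels (mass, plateau, LDR, rates) are bin means; intake
        and interactions are binned as summed increments so column sums
        reproduce the totals exactly.
        """
        w = bin_width if bin_width is not None else self.config.bin_width
        t = self.times
        tb, mass = compress(t, self.mass_filtered, w, "mean")
        _, plateau = compress(t, self.plateau, w, "mean")
        _, intake_inc = compress(t, np.diff(self.intake, prepend=0.0), w, "sum")
        _, inter_inc = compress(t, np.diff(self.interactions, prepend=0.0), w, "sum")
        _, frate = compress(t, self.feeding_rate, w, "mean")
        _, irate = compress(t, self.interaction_rate, w, "mean")
        _, ldr = compress(t, self.ldr_smooth, w, "mean")
        return pd.DataFrame({
            "t": tb,
            "mass_filtered": mass,
            "plateau_g": plateau,
            "intake_increment_g": intake_inc,
            "intake_g": np.cumsum(intake_inc),
            "interaction_increment": inter_inc,
            "interactions": np.cumsum(inter_inc),
            "feeding_rate_g_per_h": frate,
            "interaction_rate_per_h": irate,
            "ldr_smooth": ldr,
        })


@dataclass
class RunMetadata:
    descriptive: dict
    config: FilterConfig
    chip_report: ChipReport | None = None
    crop: tuple[float, float] | None = None
    totals: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, str]] = []

        def emit(prefix: str, value) -> None:
            if isinstance(value, float):
                rows.append((prefix, f"{value:.6g}"))
            elif isinstance(value, (list, tuple, np.ndarray)):
                rows.append((prefix, ";".join(f"{v:.6g}" if isinstance(v, float)
                                              else str(v) for v in value)))
            else:
                rows.append((prefix, str(value)))

        for k, v in self.descriptive.items():
            emit(f"descriptive.{k}", v)
        for k, v in self.config.to_dict().items():
            emit(f"filter.{k}", v)
        emit("crop", self.crop if self.crop is not None else "none")
        if self.chip_report is not None:
            emit("chips.count", len(self.chip_report))
            emit("chips.total_attenuated_g", self.chip_report.total_attenuated)
            for i, ev in enumerate(self.chip_report.events, start=1):
                emit(f"chips.{i}",
                     [ev.start, ev.end, ev.attenuated_mass,
                      "manual" if ev.manual else "auto"])
        for k, v in self.totals.items():
            emit(f"summary.{k}", v)
        for k, v in self.extras.items():
            emit(f"{k}", v)
        return pd.DataFrame(rows, columns=["key", "value"])
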