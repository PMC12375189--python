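"""Reading and writing the device-log dialect and the pipeline's output files.

A recording is a plain CSV written by the logger firmware at a nominal 1 Hz:
one row per sample with a real-time-clock timestamp, the amplified load-cell
mass in grams, the light-sensor (LDR) reading in arbitrary units and two
binary toggle-switch states.  The column layout is not fixed by hardware, so
it is described by a pluggable :class:`LogDialect`; the default dialect is
self-describing (explicit header row) and carries the calibration mass and
source id in ``#``-prefixed comment lines above the header::

    # calibration_mass_g: 55.000
    # source_id: sim-0
    timestamp,mass_g,ldr,switch1,switch2
    2024-01-01T07:00:00,54.998,912,0,0
    ...

On ingest timestamps are converted to seconds since the first sample, rows
are stably sorted, exact duplicate timestamps are collapsed keep-first (the
count is retained on the returned :class:`RawLog`), and a backwards clock
jump larger than the dialect's ``max_clock_skew_s`` raises
:class:`~cagescale.errors.ClockFaultError`.  No values are imputed at I/O
time: gaps in the 1 Hz grid are passed through to the filters untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ClockFaultError, LogParseError

logger = logging.getLogger(__name__)

__all__ = [
    "LogDialect",
    "DEFAULT_DIALECT",
    "Sample",
    "RawLog",
    "read_log",
    "write_log",
    "write_outputs",
]


class Sample(NamedTuple):
    """One logger row: time (s since start), mass (g), LDR, two switch flags."""

    t: float
    mass: float
    ldr: float
    switch1: int
    switch2: int


@dataclass(frozen=True)
class LogDialect:
    """Column layout and conventions of a device-log CSV."""

    columns: tuple[str, ...] = ("timestamp", "mass_g", "ldr", "switch1", "switch2")
    timestamp_format: str = "%Y-%m-%dT%H:%M:%S"
    comment_prefix: str = "#"
    mass_decimals: int = 3
    max_clock_skew_s: float = 5.0


DEFAULT_DIALECT = LogDialect()

_REQUIRED_META = ("calibration_mass_g",)


@dataclass
class RawLog:
    """An ingested recording.

    ``records`` has columns ``t`` (seconds since first sample, float),
    ``mass`` (g), ``ldr``, ``switch1``, ``switch2``; timestamps are strictly
    increasing after ingest.  ``n_dropped`` counts duplicate-timestamp rows
    collapsed on read (0 for in-memory logs).
    """

    records: pd.DataFrame
    calibration_mass: float
    start_time: datetime
    source_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.calibration_mass <= 0:
            raise ValueError("calibration_mass must be positive")
        missing = {"t", "mass", "ldr", "switch1", "switch2"} - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t(self) -> np.ndarray:
        return self.records["t"].to_numpy(dtype=float)

    @property
    def mass(self) -> np.ndarray:
        return self.records["mass"].to_numpy(dtype=float)

    @property
    def ldr(self) -> np.ndarray:
        return self.records["ldr"].to_numpy(dtype=float)

    @property
    def duration_s(self) -> float:
        t = self.t
        return float(t[-1] - t[0]) if len(t) else 0.0

    def sample(self, i: int) -> Sample:
        row = self.records.iloc[i]
        return Sample(float(row["t"]), float(row["mass"]), float(row["ldr"]),
                      int(row["switch1"]), int(row["switch2"]))


def _parse_meta(path: Path, dialect: LogDialect) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line.startswith(dialect.comment_prefix):
                break
            body = line.lstrip(dialect.comment_prefix).strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_log(path: str | Path, dialect: LogDialect = DEFAULT_DIALECT) -> RawLog:
    """Read a device-log CSV into a :class:`RawLog`.

    Raises :class:`LogParseError` for a malformed row (naming the 1-based
    file line), a bad header or an empty body, and :class:`ClockFaultError`
    when the clock runs backwards by more than ``dialect.max_clock_skew_s``.
    Duplicate timestamps are collapsed keep-first with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_meta(path, dialect)
    for key in _REQUIRED_META:
        if key not in meta:
            raise LogParseError(f"missing '{key}' in log header comments")

    df = pd.read_csv(path, comment=dialect.comment_prefix, dtype=str,
                     skip_blank_lines=True)
    if tuple(df.columns) != dialect.columns:
        raise LogParseError(
            f"header {tuple(df.columns)} does not match dialect {dialect.columns}")
    if len(df) == 0:
        raise LogParseError("log has a header but no data rows")

    n_comment = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.strip().startswith(dialect.comment_prefix):
                n_comment += 1
            else:
                break
    first_data_line = n_comment + 2  # comments, then header, then data

    ts = pd.to_datetime(df[dialect.columns[0]], errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise LogParseError("unparseable timestamp", line=first_data_line + bad)
    numeric = {}
    for col, out in zip(dialect.columns[1:], ("mass", "ldr", "switch1", "switch2")):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise LogParseError(f"unparseable value in column '{col}'",
                                line=first_data_line + bad)
        numeric[out] = vals.to_numpy(dtype=float)
    if not np.isfinite(numeric["mass"]).all():
        raise LogParseError("non-finite mass value")
    for sw in ("switch1", "switch2"):
        if not np.isin(numeric[sw], (0.0, 1.0)).all():
            bad = int(np.flatnonzero(~np.isin(numeric[sw], (0.0, 1.0)))[0])
            raise LogParseError(f"column '{sw}' must be 0 or 1",
                                line=first_data_line + bad)

    t_abs = ts.to_numpy()
    dt_s = np.diff(t_abs).astype("timedelta64[ms]").astype(float) / 1000.0
    backwards = dt_s < 0
    if backwards.any() and (-dt_s[backwards]).max() > dialect.max_clock_skew_s:
        jump = float((-dt_s[backwards]).max())
        raise ClockFaultError(
            f"RTC jumped backwards by {jump:.1f} s "
            f"(limit {dialect.max_clock_skew_s:.1f} s)")

    order = np.argsort(t_abs, kind="stable")
    t_abs = t_abs[order]
    keep = np.ones(len(t_abs), dtype=bool)
    keep[1:] = np.diff(t_abs) > np.timedelta64(0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: collapsed %d duplicate-timestamp row(s), keep-first",
                       path.name, n_dropped)

    idx = order[keep]
    start = pd.Timestamp(t_abs[keep][0]).to_pydatetime()
    t_rel = (t_abs[keep] - t_abs[keep][0]).astype("timedelta64[ms]").astype(float) / 1000.0
    records = pd.DataFrame({
        "t": t_rel,
        "mass": numeric["mass"][idx],
        "ldr": numeric["ldr"][idx],
        "switch1": numeric["switch1"][idx].astype(int),
        "switch2": numeric["switch2"][idx].astype(int),
    })
    return RawLog(
        records=records,
        calibration_mass=float(meta["calibration_mass_g"]),
        start_time=start,
        source_id=meta.get("source_id", path.stem),
        n_dropped=n_dropped,
    )


def write_log(log: RawLog, path: str | Path,
              dialect: LogDialect = DEFAULT_DIALECT) -> Path:
    """Write a :class:`RawLog` back to the device-log dialect (read_log inverse)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec = log.records
    fractional = not np.allclose(rec["t"] % 1.0, 0.0)
    fmt = dialect.timestamp_format + (".%f" if fractional else "")
    stamps = [
        (log.start_time + timedelta(seconds=float(t))).strftime(fmt)
        for t in rec["t"]
    ]
    mass_fmt = f"%.{dialect.mass_decimals}f"
    ldr = rec["ldr"].to_numpy()
    ldr_int = np.allclose(ldr % 1.0, 0.0)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{dialect.comment_prefix} calibration_mass_g: "
                 f"{log.calibration_mass:.3f}\n")
        if log.source_id:
            fh.write(f"{dialect.comment_prefix} source_id: {log.source_id}\n")
        fh.write(",".join(dialect.columns) + "\n")
        mass = rec["mass"].to_numpy()
        s1 = rec["switch1"].to_numpy().astype(int)
        s2 = rec["switch2"].to_numpy().astype(int)
        for i, stamp in enumerate(stamps):
            ldr_s = f"{int(ldr[i])}" if ldr_int else f"{ldr[i]:.3f}"
            fh.write(f"{stamp},{mass_fmt % mass[i]},{ldr_s},{s1[i]},{s2[i]}\n")
    return path


def write_outputs(trace, meta, outdir: str | Path, compress: bool = False,
                  stem: str | None = None) -> list[Path]:
    """Write the processed CSV and metadata CSV (always), plus a compressed CSV.

    ``trace`` is a :class:`~cagescale.trace.ProcessedTrace`, ``meta`` a
    :class:`~cagescale.trace.RunMetadata`.  Returns the 2 or 3 paths written.
    The processed file prints floats at 6 decimals; re-reading reproduces the
    trace columns at that precision.
    """
    if len(trace.times) == 0:
        raise ValueError("refusing to write an empty trace")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable parent
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    stem = stem or meta.descriptive.get("source_id", "recording")

    paths: list[Path] = []
    processed = outdir / f"{stem}-processed.csv"
    trace.to_frame().to_csv(processed, index=False, float_format="%.6f")
    paths.append(processed)

    meta_path = outdir / f"{stem}-metadata.csv"
    meta.to_frame().to_csv(meta_path, index=False)
    paths.append(meta_path)

    if compress:
        comp = outdir / f"{stem}-compressed.csv"
        trace.compressed_frame().to_csv(comp, index=False, float_format="%.6f")
        paths.append(comp)
    return paths
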