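"""End-to-end processing: the nine-step pipeline behind the CLI.

Steps, in order: 1) raw ingest and switch assessment, 2) cropping, 3) mass
band-pass filtering, 4) plateau and chip filtering, 5) intake/interaction
derivation with rate outputs, 6) light-trace smoothing and classification,
7) output summary, 8) daily cropping/alignment (ZT/CT) and rhythm fitting,
9) compression and file output.  Any stage failure aborts with a
stage-named :class:`~cagescale.errors.PipelineError` and removes partial
outputs.  Runs are deterministic: identical config and inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import events as ev
from . import filtering as flt
from . import light as lgt
from . import rhythms as rhy
from .errors import CagescaleError, ConfigError, PipelineError
from .log_io import RawLog, read_log, write_outputs
from .trace import ProcessedTrace, RunMetadata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a processing run.

    ``input`` may be a log path or an in-memory :class:`RawLog`.  A run is
    fully determined by this object plus the input bytes; there is no
    hidden randomness in processing (``seed`` is provenance only, echoed
    into the metadata).
    """

    input: str | Path | RawLog
    outdir: str | Path | None = None
    filter: flt.FilterConfig = field(default_factory=flt.FilterConfig)
    compress: bool = True
    figures: bool = False
    fit_rhythm: bool = True
    rhythm_target: str = "feeding_rate"      # or 'interaction_rate'
    rhythm_period_bounds_h: tuple[float, float] = (4.0, 48.0)
    manual_chip_intervals: tuple = ()
    ct_reference_s: float | None = None
    descriptive: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "input": str(self.input) if not isinstance(self.input, RawLog)
            else "<in-memory>",
            "outdir": str(self.outdir) if self.outdir else None,
            "filter": self.filter.to_dict(),
            "compress": self.compress,
            "figures": self.figures,
            "fit_rhythm": self.fit_rhythm,
            "rhythm_target": self.rhythm_target,
            "rhythm_period_bounds_h": list(self.rhythm_period_bounds_h),
            "manual_chip_intervals": [list(iv) for iv in self.manual_chip_intervals],
            "ct_reference_s": self.ct_reference_s,
            "descriptive": dict(self.descriptive),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["filter"] = flt.FilterConfig.from_dict(d.get("filter", {}))
        d["rhythm_period_bounds_h"] = tuple(d.get("rhythm_period_bounds_h", (4.0, 48.0)))
        d["manual_chip_intervals"] = tuple(
            tuple(iv) for iv in d.get("manual_chip_intervals", ()))
        d.update(overrides)
        return cls(**d)


@dataclass
class PipelineResult:
    trace: ProcessedTrace
    metadata: RunMetadata
    paths: list[Path]
    summary: dict
    schedule: lgt.LightSchedule | None = None
    sine_fit: rhy.SineFit | None = None
    folded: dict | None = None


def _figure(outdir: Path, step: int, name: str, plot_fn) -> Path:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 3))
    plot_fn(ax)
    ax.set_title(f"step {step}: {name}")
    path = outdir / f"step{step}_{name}.png"
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the nine processing steps and (optionally) write outputs."""
    written: list[Path] = []
    outdir = Path(config.outdir) if config.outdir is not None else None
    figdir = None
    if outdir is not None and config.figures:
        figdir = outdir / "figures"
        figdir.mkdir(parents=True, exist_ok=True)

    def fig(step: int, name: str, plot_fn) -> None:
        if figdir is not None:
            written.append(_figure(figdir, step, name, plot_fn))

    stage = "ingest"
    try:
        # -- step 1: raw data and switch assessment --------------------------
        if isinstance(config.input, RawLog):
            log = config.input
        else:
            log = read_log(config.input)
        if len(log) == 0:
            raise ConfigError("empty recording")
        n_flips = int(np.abs(np.diff(log.records["switch1"])).sum()
                      + np.abs(np.diff(log.records["switch2"])).sum())
        fig(1, "raw", lambda ax: (ax.plot(log.t, log.mass, lw=0.4),
                                  ax.set_ylabel("mass (g)")))

        # -- step 2: crop ----------------------------------------------------
        stage = "crop"
        fc = config.filter
        if fc.crop is not None:
            log = flt.crop_trace(log, fc.crop[0], fc.crop[1])
        t = log.t
        raw = log.mass
        fig(2, "crop", lambda ax: ax.plot(t, raw, lw=0.4))

        # -- step 3: mass filtering -------------------------------------------
        stage = "mass_filter"
        filtered = flt.mass_filter(t, raw, fc.buffer, fc.plateau_min_duration)
        fig(3, "mass_filter", lambda ax: (ax.plot(t, raw, lw=0.3, alpha=0.5),
                                          ax.plot(t, filtered, lw=0.8)))

        # -- step 4: plateau + chip filters ------------------------------------
        stage = "plateau_filter"
        plateaus = flt.plateau_filter(t, filtered, fc, raw=raw)
        plateaus, chip_report = flt.chip_filter(
            plateaus, fc, manual_intervals=config.manual_chip_intervals,
            reference=filtered)
        fig(4, "plateau", lambda ax: ax.plot(t, plateaus.mass, lw=0.8))

        # -- step 5: interactions and frequency analysis -----------------------
        stage = "events"
        intake = ev.cumulative_intake(plateaus, log.calibration_mass, fc.buffer)
        inter = ev.detect_interactions(t, raw, plateaus, fc.threshold,
                                       fc.refractory)
        feeding_rate = ev.rates(t, intake.cumulative, fc.rate_window, "g/h")
        inter_rate = ev.rates(t, inter.cumulative, fc.rate_window, "events/h")
        fig(5, "intake", lambda ax: ax.plot(t, intake.cumulative, lw=0.8))

        # -- step 6: LDR filtering ---------------------------------------------
        stage = "light"
        ldr_s = flt.ldr_smooth(log.ldr, fc.ldr_smooth_window)
        segments = lgt.classify_light(t, ldr_s)
        schedule = lgt.infer_schedule(segments, start_time=log.start_time)
        labels = segments.label_at(t)
        fig(6, "ldr", lambda ax: ax.plot(t, ldr_s, lw=0.5))

        # -- step 7: output summary --------------------------------------------
        stage = "summary"
        duration_d = max(log.duration_s / 86400.0, 1e-9)
        totals = {
            "total_intake_g": intake.total,
            "intake_g_per_day": intake.total / duration_d,
            "interactions": inter.count,
            "interactions_per_day": inter.count / duration_d,
            "duration_h": log.duration_s / 3600.0,
            "n_switch_flips": n_flips,
            "light_mode": schedule.mode,
        }
        if schedule.mode == "LD":
            ph = ev.phase_totals(t, intake.increments, segments)
            totals.update(light_intake_g=ph["light_total"],
                          dark_intake_g=ph["dark_total"])
            phe = ev.phase_totals(t, inter.increments, segments)
            totals.update(light_interactions=phe["light_total"],
                          dark_interactions=phe["dark_total"])

        # -- step 8: cropping and alignment (+ rhythm fit) ----------------------
        stage = "alignment"
        folded = None
        sine_fit = None
        extras: dict = {}
        if fc.fold_mode != "none":
            if fc.fold_mode == "ZT":
                if schedule.mode != "LD" or schedule.lights_on_s is None:
                    raise ConfigError("ZT folding needs an LD schedule")
                anchor = schedule.lights_on_s
            else:
                if config.ct_reference_s is None:
                    raise ConfigError("CT folding needs a reference lights-on")
                anchor = config.ct_reference_s
            zb, zf, zn = flt.fold_daily(t, feeding_rate.rate, anchor,
                                        mode=fc.fold_mode)
            _, zi, _ = flt.fold_daily(t, inter_rate.rate, anchor,
                                      mode=fc.fold_mode)
            folded = {"bins_h": zb, "feeding_rate": zf,
                      "interaction_rate": zi, "n": zn}
        if config.fit_rhythm and len(t) >= 6:
            target = feeding_rate if config.rhythm_target == "feeding_rate" \
                else inter_rate
            sine_fit = rhy.fit_sum_of_sines(t / 3600.0, target.rate, j=1,
                                            period_bounds_h=config.rhythm_period_bounds_h)
            if not sine_fit.degenerate:
                m = rhy.sine_metrics(sine_fit)
                extras.update({
                    "rhythm.target": config.rhythm_target,
                    "rhythm.period_h": m["T"],
                    "rhythm.intensity": m["A"],
                    "rhythm.intensity_per_day": m["A"] * 24.0,
                    "rhythm.r2": m["r2"],
                })
            else:
                extras["rhythm.degenerate"] = True
        if folded is not None:
            fig(8, "folded", lambda ax: ax.plot(folded["bins_h"],
                                                folded["feeding_rate"]))

        # -- step 9: compression and output -------------------------------------
        stage = "output"
        trace = ProcessedTrace(
            times=t, mass_raw=raw, mass_filtered=filtered,
            plateau=plateaus.mass, intake=intake.cumulative,
            interactions=inter.cumulative, feeding_rate=feeding_rate.rate,
            interaction_rate=inter_rate.rate, ldr_raw=log.ldr,
            ldr_smooth=ldr_s, light_label=labels,
            switch1=log.records["switch1"].to_numpy(),
            switch2=log.records["switch2"].to_numpy(),
            config=fc, calibration_mass=log.calibration_mass,
            start_time=log.start_time, event_times=inter.event_times,
        )
        descriptive = {"source_id": log.source_id, "seed": config.seed,
                       **config.descriptive}
        meta = RunMetadata(descriptive=descriptive, config=fc,
                           chip_report=chip_report, crop=fc.crop,
                           totals=totals, extras=extras)
        paths: list[Path] = []
        if outdir is not None:
            paths = write_outputs(trace, meta, outdir, compress=config.compress)
            written.extend(paths)
            fig(9, "compressed", lambda ax: ax.plot(
                trace.compressed_frame()["t"],
                trace.compressed_frame()["feeding_rate_g_per_h"], lw=0.8))
        return PipelineResult(trace=trace, metadata=meta, paths=paths,
                              summary=totals, schedule=schedule,
                              sine_fit=sine_fit, folded=folded)
    except (CagescaleError, FileNotFoundError, OSError) as exc:
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
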