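"""Exception hierarchy for cagescale.

Everything raised deliberately by the library derives from :class:`CagescaleError`
so callers (and the CLI) can catch one base class.
"""


class CagescaleError(Exception):
    """Base class for all cagescale errors."""


class LogParseError(CagescaleError):
    """A device log file could not be parsed (malformed row, bad header, empty body)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ClockFaultError(CagescaleError):
    """The real-time-clock column jumped backwards by more than the allowed skew."""


class CalibrationError(CagescaleError):
    """Mass trace inconsistent with the calibration mass entered at setup."""


class ConfigError(CagescaleError):
    """A configuration object violates its invariants or is infeasible."""


class PipelineError(CagescaleError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
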