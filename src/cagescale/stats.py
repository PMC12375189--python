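"""Validation statistics: origin-constrained regression and Pearson matrices.

Benchtop and in-vivo calibration checks compare device-reported masses (x)
with manually weighed masses (y).  Both are true zeros — an empty holder
reads zero — so the regression line is constrained through the origin:
``slope = Σxy / Σx²`` in closed form.  Agreement is tested against the null
hypothesis of a 1:1 relationship (y = x) with a two-tailed F test.  Pearson
correlation matrices compare device-derived timelines with external activity
traces (e.g. capacitive cage-rack recordings) after alignment and binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError

__all__ = [
    "RegressionResult",
    "CorrelationMatrix",
    "regression_origin",
    "slope_unity_test",
    "pearson_matrix",
    "read_external_trace",
]


@dataclass
class RegressionResult:
    """Origin-constrained least-squares fit.

    ``r2`` measures spread about the fitted line relative to spread about
    the origin (primary definition for a through-origin fit, always in
    [0, 1]); ``r2_about_mean`` is the conventional about-the-mean version,
    reported alongside.  ``F``/``p`` with (dfn, dfd) test the slope against
    the null value used to build the result (0 for the plain fit, 1 for the
    slope-vs-unity test).
    """

    slope: float
    r2: float
    r2_about_mean: float
    F: float
    dfn: int
    dfd: int
    p: float
    n: int
    null_slope: float = 0.0


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ConfigError("need at least 3 points")
    if np.allclose(x, 0.0):
        raise ConfigError("x must not be identically zero")
    return x, y


def _origin_fit(x: np.ndarray, y: np.ndarray, null_slope: float,
                ) -> RegressionResult:
    n = len(x)
    slope = float(np.sum(x * y) / np.sum(x * x))
    rss = float(np.sum((y - slope * x) ** 2))
    rss_null = float(np.sum((y - null_slope * x) ** 2))
    ss_origin = float(np.sum(y * y))
    ss_mean = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_origin if ss_origin > 0 else 1.0
    r2_mean = 1.0 - rss / ss_mean if ss_mean > 0 else 1.0
    dfd = n - 1
    if rss <= 0:
        F = np.inf if rss_null > 0 else 0.0
        p = 0.0 if rss_null > 0 else 1.0
    else:
        F = max((rss_null - rss) / (rss / dfd), 0.0)
        p = float(sps.f.sf(F, 1, dfd))
    return RegressionResult(slope=slope, r2=r2, r2_about_mean=r2_mean,
                            F=float(F), dfn=1, dfd=dfd, p=p, n=n,
                            null_slope=null_slope)


def regression_origin(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line through the origin: slope = Σxy / Σx² (closed form)."""
    x, y = _validate_xy(x, y)
    return _origin_fit(x, y, null_slope=0.0)


def slope_unity_test(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Two-tailed F test of the origin-constrained slope against 1 (y = x).

    F = [RSS(slope=1) − RSS(slope-hat)] / [RSS(slope-hat) / (n − 1)] with
    (1, n − 1) degrees of freedom.  Under Gaussian errors and a true unit
    slope the statistic is F-distributed, giving a calibrated type-I rate.
    """
    x, y = _validate_xy(x, y)
    return _origin_fit(x, y, null_slope=1.0)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r matrix with unit diagonal.

    Pairs involving a zero-variance trace are undefined: the entry is NaN
    and the pair is listed in ``undefined`` so it cannot silently propagate.
    """

    labels: list[str]
    r: np.ndarray
    undefined: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def pearson_matrix(traces: Sequence[Sequence[float]],
                   labels: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson r between aligned, equal-length traces."""
    arrays = [np.asarray(tr, dtype=float) for tr in traces]
    if len(arrays) < 2:
        raise ConfigError("need at least 2 traces")
    n = len(arrays[0])
    if n < 3:
        raise ConfigError("traces need at least 3 samples")
    if any(len(a) != n for a in arrays):
        raise ConfigError("traces must be aligned to equal length")
    labels = list(labels) if labels is not None else \
        [f"trace{i}" for i in range(len(arrays))]
    k = len(arrays)
    r = np.eye(k)
    undefined: list[tuple[int, int]] = []
    sd = [float(np.std(a)) for a in arrays]
    for i in range(k):
        for jj in range(i + 1, k):
            if sd[i] == 0.0 or sd[jj] == 0.0:
                r[i, jj] = r[jj, i] = np.nan
                undefined.append((i, jj))
            else:
                rij = float(np.corrcoef(arrays[i], arrays[jj])[0, 1])
                r[i, jj] = r[jj, i] = rij
    return CorrelationMatrix(labels=labels, r=r, undefined=undefined)


def read_external_trace(path, time_col: str = "time",
                        value_col: str = "value") -> tuple[np.ndarray, np.ndarray]:
    """Read a generic two-column time,value CSV (external activity trace).

    The exchange format for comparing against other monitoring systems:
    time in seconds, value in the source's units.  Vendor-specific export
    schemas are deliberately not reimplemented.
    """
    df = pd.read_csv(path)
    if time_col not in df.columns or value_col not in df.columns:
        raise ConfigError(
            f"external trace needs columns '{time_col}','{value_col}', "
            f"got {list(df.columns)}")
    return (df[time_col].to_numpy(dtype=float),
            df[value_col].to_numpy(dtype=float))
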