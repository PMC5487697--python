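"""Time-weighted integration of irregular station series and variability statistics.

The central quantity is the *time-integrated average* of a station's season:

    mean = sum(X_i * w_i) / sum(w_i)

where the weight ``w_i`` is the length of the interval assigned to sample
``i`` by the midpoints between consecutive sampling times.  The season is
taken to extend half a gap beyond the first and last samples, so that an
equally spaced series reproduces its plain arithmetic mean exactly.

Integrating each station first and only then comparing stations ("pooling
over time") collapses seasonal trend, autocorrelation and non-normality into
a single well-behaved value per station; the between-station spread of these
values is typically far smaller than the raw spatial or temporal spread.
The :func:`area_summary` / :func:`variability_table` pair quantifies both
sides of that comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridError, SeriesError

__all__ = [
    "StationSeries",
    "AreaSummary",
    "VariabilityTable",
    "interval_weights",
    "time_integrated_mean",
    "area_summary",
    "variability_table",
    "normality_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StationSeries:
    """One station's irregular time series for a single variable."""

    station_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise SeriesError("times and values must be 1-D arrays of equal length")
        if times.size == 0:
            raise SeriesError(f"empty series for station {self.station_id!r}")
        if np.any(np.diff(times) <= 0):
            raise SeriesError(
                f"times must be strictly increasing (station {self.station_id!r})"
            )

    def __len__(self) -> int:
        return self.times.size

    def thin(self, indices: Sequence[int]) -> "StationSeries":
        """Return the sub-series at the given (strictly increasing) indices."""
        idx = np.asarray(indices, dtype=int)
        return StationSeries(self.station_id, self.times[idx], self.values[idx])


@dataclass(frozen=True)
class AreaSummary:
    """Across-station summary of time-integrated means for one variable."""

    variable: str
    station_means: dict[str, float]
    area_mean: float
    sd: float
    cv_percent: float | None  # None when the mean is 0 (CV undefined)
    n_stations: int


@dataclass(frozen=True)
class VariabilityTable:
    """Per-unit CV% statistics along one axis of the station x occasion grid.

    ``axis='over_time'`` computes one CV% across stations per occasion;
    ``axis='over_stations'`` one CV% across occasions per station.
    """

    axis: Literal["over_time", "over_stations"]
    transform: Literal["raw", "log"]
    cv_percents: tuple[float, ...]
    mean_cv: float
    cv_range: tuple[float, float]
    grand_mean: float
    unit_labels: tuple = field(default=())


def interval_weights(times) -> np.ndarray:
    """Interval lengths assigned to each sampling time by midpoint splitting.

    Interior sample i owns [m_{i-1}, m_i] with m_i the midpoint of the gap to
    the next sample; the first and last samples additionally extend half the
    adjacent gap outward, so the covered period is
    [t_1 - g_1/2, t_N + g_{N-1}/2].  A single sample gets unit weight.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise SeriesError("times must be a nonempty 1-D array")
    if t.size == 1:
        return np.ones(1)
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise SeriesError("times must be strictly increasing")
    w = np.empty_like(t)
    w[0] = gaps[0]
    w[-1] = gaps[-1]
    w[1:-1] = (t[2:] - t[:-2]) / 2.0
    return w


def time_integrated_mean(series: StationSeries) -> float:
    """Time-weighted mean sum(X_i*w_i)/sum(w_i) with midpoint interval weights.

    Equals the arithmetic mean for equally spaced series.
    """
    w = interval_weights(series.times)
    return float(np.dot(series.values, w) / w.sum())


def _cv_percent(values: np.ndarray) -> float | None:
    """Sample CV% (SD with denominator n-1, as percent of the mean); None at mean 0."""
    mean = values.mean()
    if mean == 0:
        return None
    return float(100.0 * values.std(ddof=1) / mean)


def area_summary(station_series: Sequence[StationSeries], variable: str = "") -> AreaSummary:
    """Integrate each station over time, then summarize across stations.

    Returns the across-station arithmetic mean, sample SD (n-1) and CV% of the
    time-integrated station means.  Requires at least 2 stations.
    """
    if len(station_series) < 2:
        raise SeriesError("area_summary requires at least 2 stations")
    means = {s.station_id: time_integrated_mean(s) for s in station_series}
    arr = np.array(list(means.values()))
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = _cv_percent(arr)
    if cv is None:
        logger.warning("area mean is 0 for %r: CV%% undefined", variable)
    return AreaSummary(
        variable=variable,
        station_means=means,
        area_mean=mean,
        sd=sd,
        cv_percent=cv,
        n_stations=len(means),
    )


def variability_table(
    grid: pd.DataFrame,
    axis: Literal["over_time", "over_stations"],
    transform: Literal["raw", "log"] = "raw",
) -> VariabilityTable:
    """CV% statistics along one axis of a station (rows) x occasion (columns) grid.

    ``transform='log'`` natural-log-transforms the values first and applies the
    same mean/SD/CV arithmetic on the transformed scale; the grand mean is then
    reported back-transformed (exponential of the mean of logs, i.e. the
    geometric mean), while for ``'raw'`` it is the plain mean of all values.
    """
    if axis not in ("over_time", "over_stations"):
        raise ValueError(f"unknown axis {axis!r}")
    values = grid.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise GridError("variability_table requires a complete station x occasion grid")
    if transform == "log":
        bad = values <= 0
        if bad.any():
            rows, cols = np.nonzero(bad)
            offenders = [
                f"(station {grid.index[r]!r}, occasion {grid.columns[c]!r}: {values[r, c]})"
                for r, c in zip(rows, cols)
            ]
            raise GridError(
                "log transform requires positive values; offending records: "
                + ", ".join(offenders[:10])
            )
        work = np.log(values)
        grand_mean = float(np.exp(work.mean()))
    elif transform == "raw":
        work = values
        grand_mean = float(work.mean())
    else:
        raise ValueError(f"unknown transform {transform!r}")

    # over_time: CV across stations per occasion (columns); over_stations: per row
    sliced = work.T if axis == "over_time" else work
    labels = tuple(grid.columns) if axis == "over_time" else tuple(grid.index)
    cvs = []
    for unit in sliced:
        cv = _cv_percent(unit)
        if cv is None:
            raise GridError("CV undefined: a unit mean is exactly 0")
        cvs.append(cv)
    cvs_arr = np.array(cvs)
    return VariabilityTable(
        axis=axis,
        transform=transform,
        cv_percents=tuple(cvs),
        mean_cv=float(cvs_arr.mean()),
        cv_range=(float(cvs_arr.min()), float(cvs_arr.max())),
        grand_mean=grand_mean,
        unit_labels=labels,
    )


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test of the station-level integrated means.

    Returns (W, p).  The conventional reading is that p > alpha indicates no
    significant deviation from normality — the licence for the plain t-based
    precision and power calculus downstream.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for zero-variance samples")
    w, p = stats.shapiro(arr)
    return float(w), float(p)
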