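"""Sampling-frequency reduction analysis.

Given a pilot season sampled at high frequency (weekly, say 24 occasions) at
every station, recompute the time-integrated area mean under progressively
thinned schedules and ask how far the result drifts from the full-frequency
reference.  Results are standardized so the reference equals 100%; the lowest
frequency whose standardized mean stays within a tolerance band (default
±5%) is the recommended number of surveys per year, the N_time knob of the
cost model in :mod:`monalloc.design`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import GridError
from .integration import StationSeries, time_integrated_mean

__all__ = [
    "FrequencyResult",
    "subsample_schedule",
    "frequency_analysis",
    "min_frequency",
]

logger = logging.getLogger(__name__)

DEFAULT_KEEP_COUNTS = (24, 12, 8, 6, 5, 4)


@dataclass(frozen=True)
class FrequencyResult:
    """Outcome of thinning to ``n_keep`` occasions, as percent of the reference."""

    n_keep: int
    schedule: tuple[int, ...]
    standardized_mean: float
    ci95_low: float
    ci95_high: float
    within_tolerance: bool


def subsample_schedule(n_total: int, n_keep: int, phase: int = 0) -> list[int]:
    """Evenly spread ``n_keep`` occasion indices over ``n_total``.

    Index j of the schedule is ``floor(j * n_total / n_keep) + phase``.  When
    ``n_keep`` divides ``n_total`` this is exact every-(n_total/n_keep)th
    sampling starting at ``phase``.
    """
    if not 1 <= n_keep <= n_total:
        raise ValueError(f"need 1 <= n_keep <= n_total (got {n_keep}, {n_total})")
    if phase < 0:
        raise ValueError("phase must be >= 0")
    idx = [j * n_total // n_keep + phase for j in range(n_keep)]
    if idx[-1] >= n_total:
        raise ValueError(
            f"phase {phase} pushes schedule past the grid (max index {idx[-1]} >= {n_total})"
        )
    return idx


def frequency_analysis(
    station_series: Sequence[StationSeries],
    keep_counts: Sequence[int] = DEFAULT_KEEP_COUNTS,
    tolerance: float = 5.0,
    phase: int = 0,
) -> list[FrequencyResult]:
    """Standardized area means and 95% CIs under each thinned schedule.

    All stations must share the same occasion grid; its length must equal the
    largest keep count (the full-frequency reference).  For each ``n_keep``
    every station is thinned by the same schedule, time-integrated, and
    averaged across stations; the result is expressed as percent of the
    full-frequency area mean.  The 95% CI uses the Student t quantile at
    ``n_stations - 1`` degrees of freedom across station means, standardized
    the same way.
    """
    if not station_series:
        raise GridError("no station series supplied")
    grid = station_series[0].times
    for s in station_series[1:]:
        if len(s.times) != len(grid) or not np.allclose(s.times, grid):
            raise GridError(
                f"station {s.station_id!r} does not share the common occasion grid"
            )
    n_total = len(grid)
    keep_counts = sorted(set(int(k) for k in keep_counts), reverse=True)
    if keep_counts[0] != n_total:
        raise GridError(
            f"largest keep count ({keep_counts[0]}) must equal the number of "
            f"occasions available ({n_total})"
        )

    ref_mean = float(
        np.mean([time_integrated_mean(s) for s in station_series])
    )
    if ref_mean == 0:
        raise GridError("full-frequency area mean is 0: standardization undefined")

    n_st = len(station_series)
    t_mult = stats.t.ppf(0.975, n_st - 1) if n_st > 1 else math.nan

    results = []
    for n_keep in keep_counts:
        # the identity schedule admits no phase shift
        schedule = subsample_schedule(n_total, n_keep, 0 if n_keep == n_total else phase)
        means = np.array(
            [time_integrated_mean(s.thin(schedule)) for s in station_series]
        )
        area_mean = means.mean()
        half = t_mult * means.std(ddof=1) / math.sqrt(n_st) if n_st > 1 else 0.0
        std_mean = 100.0 * area_mean / ref_mean
        results.append(
            FrequencyResult(
                n_keep=n_keep,
                schedule=tuple(schedule),
                standardized_mean=std_mean,
                ci95_low=100.0 * (area_mean - half) / ref_mean,
                ci95_high=100.0 * (area_mean + half) / ref_mean,
                within_tolerance=abs(std_mean - 100.0) <= tolerance,
            )
        )
    return results


def min_frequency(results: Sequence[FrequencyResult]) -> int:
    """Lowest acceptable sampling frequency under the monotone-acceptance rule.

    Walking down from the full-frequency reference, acceptance stops at the
    first keep count outside tolerance; the smallest still-accepted count is
    returned.  If an intermediate count fails, later passes do not rescue it
    (contiguity with the reference is required).  When nothing but the
    reference passes, the reference count is returned with a warning.
    """
    ordered = sorted(results, key=lambda r: r.n_keep, reverse=True)
    if not ordered:
        raise ValueError("no frequency results supplied")
    accepted = ordered[0].n_keep
    if not ordered[0].within_tolerance:
        logger.warning("reference frequency itself flagged outside tolerance")
    for res in ordered[1:]:
        if not res.within_tolerance:
            break
        accepted = res.n_keep
    if accepted == ordered[0].n_keep and len(ordered) > 1:
        logger.warning(
            "no reduced frequency within tolerance; keeping reference count %d",
            accepted,
        )
    return accepted
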