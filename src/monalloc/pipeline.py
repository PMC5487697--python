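"""Full analysis pipeline: casts -> station series -> variability -> frequency -> design.

Stages run in a fixed order, each consuming the previous stage's output:

1. **profiles** — reduce each cast to one scalar per (station, occasion):
   the 0-3 m band mean for scalar variables, the fitted attenuation
   coefficient for the light variable.
2. **integration** — time-integrate each station, summarize across stations
   (area mean, CV% of integrated means, CI% prefactor) and tabulate raw /
   log variability along both axes of the station x occasion grid.
3. **frequency** — thinning ladder per variable and the recommended number
   of surveys per year.
4. **design** — stations for a target precision, the portfolio budget, and
   power-based minimum sample sizes per change level.

Every table is carried at full precision; display rounding happens only at
serialization time, and the rounded file carries the full-precision value in
adjacent columns of the machine-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from .config import RunConfig
from .errors import MonallocError
from .frequency import frequency_analysis, min_frequency
from .integration import (
    StationSeries,
    area_summary,
    normality_check,
    time_integrated_mean,
    variability_table,
)
from .io import ObservationSet
from .profiles import band_mean, fit_extinction

__all__ = ["ReportBundle", "station_series_by_variable", "run_pipeline", "design_report"]

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """All pipeline outputs as data frames, plus the recommended N_time."""

    summary: pd.DataFrame  # Table-1 style: per-variable mean/range/CV%/CI% prefactor
    variability: pd.DataFrame  # Table-2 style: axis x transform x variable
    frequency: pd.DataFrame  # thinning ladder per variable
    allocation: pd.DataFrame  # stations/cost for target precision per variable
    power: pd.DataFrame  # min n per (variable, delta%)
    n_time_recommended: int
    portfolio: dict = field(default_factory=dict)
    config: RunConfig | None = None

    def write(self, out_dir) -> None:
        """Serialize every table as CSV plus one structured-text report.

        CSV cells keep full precision; `report.yaml` adds 2-d.p. display
        values next to the exact ones.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.variability.to_csv(out / "variability.csv", index=False)
        self.frequency.to_csv(out / "frequency.csv", index=False)
        self.allocation.to_csv(out / "allocation.csv", index=False)
        self.power.to_csv(out / "power.csv", index=False)
        report = {
            "n_time_recommended": int(self.n_time_recommended),
            "portfolio": {
                k: (float(v) if np.isscalar(v) else v) for k, v in self.portfolio.items()
            },
            "summary": _with_display(self.summary),
            "allocation": _with_display(self.allocation),
            "power": _with_display(self.power),
        }
        (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))


def _with_display(df: pd.DataFrame) -> list[dict]:
    rows = []
    for rec in df.to_dict(orient="records"):
        row = {}
        for k, v in rec.items():
            if isinstance(v, float):
                row[k] = float(v)
                row[f"{k}_display"] = round(v, 2)
            else:
                row[k] = v
        rows.append(row)
    return rows


def station_series_by_variable(
    obs: ObservationSet, config: RunConfig
) -> dict[str, list[StationSeries]]:
    """Stage 1: reduce casts to per-station scalar series for every variable."""
    lo, hi = config.depth_band
    out: dict[str, list[StationSeries]] = {}
    for variable in obs.variables:
        per_station: dict[str, list[tuple[float, float]]] = {}
        if variable == config.light_variable:
            for prof in obs.light_profiles(variable):
                fit = fit_extinction(prof)
                per_station.setdefault(prof.station_id, []).append((prof.day, fit.k))
        else:
            for cast in obs.casts(variable):
                val = band_mean(cast, variable, lo, hi)
                per_station.setdefault(cast.station_id, []).append((cast.day, val))
        series = []
        for station, pairs in sorted(per_station.items()):
            pairs.sort()
            if len(pairs) < config.min_occasions_per_station:
                logger.warning(
                    "station %r excluded for %r: only %d occasions (< %d)",
                    station, variable, len(pairs), config.min_occasions_per_station,
                )
                continue
            times, values = zip(*pairs)
            series.append(StationSeries(station, np.array(times), np.array(values)))
        out[variable] = series
    return out


def _grid(series_list: list[StationSeries]) -> pd.DataFrame:
    """Station x occasion value grid (rows: stations, columns: days)."""
    frames = {
        s.station_id: pd.Series(s.values, index=s.times) for s in series_list
    }
    return pd.DataFrame(frames).T.sort_index()


def run_pipeline(config: RunConfig, observations: ObservationSet) -> ReportBundle:
    """Execute all stages on an observation set; any stage error aborts."""
    if len(observations) == 0:
        raise MonallocError("pipeline: empty observation set")
    try:
        by_var = station_series_by_variable(observations, config)
    except MonallocError as exc:
        raise MonallocError(f"profiles stage: {exc}") from exc

    summaries, var_rows, freq_rows, n_time_by_var = [], [], [], {}
    for variable, series_list in by_var.items():
        try:
            summ = area_summary(series_list, variable)
            means = np.array(list(summ.station_means.values()))
            if means.size >= 3 and np.ptp(means) > 0:
                w_stat, p_val = normality_check(means)
            else:
                logger.warning("normality check skipped for %r (degenerate means)", variable)
                w_stat, p_val = float("nan"), float("nan")
            raw_all = np.concatenate([s.values for s in series_list])
            cv = summ.cv_percent if summ.cv_percent is not None else float("nan")
            summaries.append(
                {
                    "variable": variable,
                    "area_mean": summ.area_mean,
                    "value_min": float(raw_all.min()),
                    "value_max": float(raw_all.max()),
                    "cv_percent": cv,
                    "ci_prefactor": dz.T_FIXED * cv,
                    "n_stations": summ.n_stations,
                    "shapiro_w": w_stat,
                    "shapiro_p": p_val,
                }
            )
        except MonallocError as exc:
            raise MonallocError(f"integration stage [{variable}]: {exc}") from exc

        grid = _grid(series_list)
        complete = grid.dropna(axis=1)  # occasions observed at every station
        for axis in ("over_time", "over_stations"):
            for transform in ("raw", "log"):
                if transform == "log" and (complete.to_numpy() <= 0).any():
                    logger.warning("skipping log variability for %r (nonpositive values)", variable)
                    continue
                vt = variability_table(complete, axis, transform)
                var_rows.append(
                    {
                        "variable": variable,
                        "axis": axis,
                        "transform": transform,
                        "grand_mean": vt.grand_mean,
                        "mean_cv": vt.mean_cv,
                        "cv_min": vt.cv_range[0],
                        "cv_max": vt.cv_range[1],
                    }
                )

        try:
            n_occ = complete.shape[1]
            keep = tuple(k for k in config.keep_counts if k <= n_occ)
            if n_occ not in keep:
                keep = (n_occ,) + keep
            full_series = [
                StationSeries(st, complete.columns.to_numpy(float), row.to_numpy(float))
                for st, row in complete.iterrows()
            ]
            results = frequency_analysis(
                full_series, keep_counts=keep, tolerance=config.tolerance_percent
            )
            for r in results:
                freq_rows.append(
                    {
                        "variable": variable,
                        "n_keep": r.n_keep,
                        "standardized_mean": r.standardized_mean,
                        "ci95_low": r.ci95_low,
                        "ci95_high": r.ci95_high,
                        "within_tolerance": r.within_tolerance,
                    }
                )
            n_time_by_var[variable] = min_frequency(results)
        except MonallocError as exc:
            raise MonallocError(f"frequency stage [{variable}]: {exc}") from exc

    summary = pd.DataFrame(summaries)
    n_time = int(max(n_time_by_var.values())) if n_time_by_var else config.N_time
    cvs = {row["variable"]: row["cv_percent"] for row in summaries}
    allocation, power, portfolio = _design_tables(config, cvs)
    return ReportBundle(
        summary=summary,
        variability=pd.DataFrame(var_rows),
        frequency=pd.DataFrame(freq_rows),
        allocation=allocation,
        power=power,
        n_time_recommended=n_time,
        portfolio=portfolio,
        config=config,
    )


def _design_tables(config: RunConfig, cvs: dict[str, float]):
    model = config.cost_model()
    alloc_rows, power_rows = [], []
    for variable, cv in cvs.items():
        if not np.isfinite(cv) or cv < 0:
            logger.warning("skipping design tables for %r (CV%% unavailable)", variable)
            continue
        n_for_5 = dz.stations_for_precision(cv, 5.0, config.t_mode)
        n_for_target = dz.stations_for_precision(cv, config.target_ci_percent, config.t_mode)
        alloc_rows.append(
            {
                "variable": variable,
                "cv_percent": cv,
                "ci_at_1_station": dz.ci_percent(cv, 1, "fixed"),
                "stations_for_5pct": n_for_5,
                f"stations_for_{config.target_ci_percent:g}pct": n_for_target,
                "cost_for_5pct": dz.cost_for_precision(model, cv, 5.0, config.t_mode),
                f"cost_for_{config.target_ci_percent:g}pct": dz.cost_for_precision(
                    model, cv, config.target_ci_percent, config.t_mode
                ),
            }
        )
        for delta in config.delta_percents:
            if cv == 0:
                logger.warning("no power analysis for %r: CV%% is 0", variable)
                continue
            spec = dz.PowerSpec(
                delta_percent=delta, cv_percent=cv, alpha=config.alpha, beta=config.beta
            )
            n_min = dz.min_n_for_power(spec)
            power_rows.append(
                {
                    "variable": variable,
                    "delta_percent": delta,
                    "cv_percent": cv,
                    "effect_d": spec.d,
                    "min_n": n_min,
                    "power_at_min_n": dz.power_one_sample(n_min, spec),
                }
            )
    portfolio = {}
    if cvs:
        finite = {k: v for k, v in cvs.items() if np.isfinite(v) and v > 0}
        if finite:
            pb = dz.budget_for_portfolio(model, finite, config.target_ci_percent)
            portfolio = {
                "target_ci_percent": config.target_ci_percent,
                "budget": pb.budget,
                "budget_exact": pb.budget_exact,
                "n_space": pb.n_space,
                "worst_cv": pb.worst_cv,
                "achieved_ci": {k: float(v) for k, v in pb.achieved_ci.items()},
            }
    return pd.DataFrame(alloc_rows), pd.DataFrame(power_rows), portfolio


def design_report(config: RunConfig, cvs: dict[str, float]) -> ReportBundle:
    """Design-only entry: skip the data stages, feed CV% values directly."""
    allocation, power, portfolio = _design_tables(config, cvs)
    return ReportBundle(
        summary=pd.DataFrame(
            [{"variable": k, "cv_percent": v, "ci_prefactor": dz.T_FIXED * v} for k, v in cvs.items()]
        ),
        variability=pd.DataFrame(),
        frequency=pd.DataFrame(),
        allocation=allocation,
        power=power,
        n_time_recommended=config.N_time,
        portfolio=portfolio,
        config=config,
    )
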