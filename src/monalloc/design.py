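"""Cost-precision allocation calculus and power-based sample-size planning.

The survey cost model is linear in the two allocation knobs, surveys per
year ``N_time`` and stations per survey ``N_space``::

    Cost = N_time * N_space * (A/n + sum(m_i)) + B

with ``A`` the ship cost per day, ``n`` the stations covered per cruise day,
``m_i`` the per-variable sampling/analysis costs, and ``B`` the fixed labor
and overhead cost.  Inverting for ``N_space`` at a given budget and feeding
the result into the precision relation::

    CI% = t * CV% / sqrt(N)

links money to the attainable half-width of the 95% confidence interval of
the area mean, expressed as a percent of the mean.  ``CV%`` is the
coefficient of variation of the stations' time-integrated averages — the
small, well-behaved spread that pooling over time buys.

Two t-multiplier conventions are offered: ``"fixed"`` uses the constant
2.01 (the two-sided 5% Student t multiplier at the pilot study's ~50 degrees
of freedom, kept fixed so precision curves depend on N only through the
square root), and ``"exact_df"`` looks up the two-sided 97.5th t quantile at
``ceil(N) - 1`` degrees of freedom.

Detecting a delta% change of the area mean between years is a one-sample t
test on the station integrated means; with the change expressed as a percent
of the mean and CV% the percent SD, the standardized effect is simply
``d = delta% / CV%`` and power follows from the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DesignError

__all__ = [
    "CostModel",
    "PrecisionResult",
    "PowerSpec",
    "PortfolioBudget",
    "T_FIXED",
    "survey_cost",
    "stations_from_budget",
    "ci_percent",
    "stations_for_precision",
    "cost_for_precision",
    "budget_for_portfolio",
    "power_one_sample",
    "min_n_for_power",
    "power_curve",
]

#: Fixed two-sided 5% Student-t multiplier used by the "fixed" precision mode.
T_FIXED = 2.01

TMode = Literal["fixed", "exact_df"]


@dataclass(frozen=True)
class CostModel:
    """Linear survey cost model Cost = N_time*N_space*(A/n + sum(m)) + B."""

    A: float = 1.0  # ship cost per day
    B: float = 20.0  # fixed labor/overhead cost
    n: float = 3.0  # stations per cruise day
    m: tuple[float, ...] = (0.1,)  # per-variable sampling+analysis costs
    N_time: int = 12  # surveys per year

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise DesignError("costs A and B must be >= 0")
        if self.n <= 0:
            raise DesignError("stations per cruise day n must be > 0")
        if any(mi < 0 for mi in self.m):
            raise DesignError("per-variable costs must be >= 0")
        if self.N_time < 1:
            raise DesignError("N_time must be >= 1")

    @property
    def sum_m(self) -> float:
        return float(sum(self.m))

    @property
    def per_station_cost(self) -> float:
        """Marginal cost of one station visit: A/n + sum(m_i)."""
        return self.A / self.n + self.sum_m


@dataclass(frozen=True)
class PrecisionResult:
    """A CV% / N / CI% triple with the t multiplier that links them."""

    cv_percent: float
    n_stations: float
    t_value: float
    ci_percent: float
    t_mode: str = "fixed"


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the one-sample t power analysis for inter-annual change.

    ``delta_percent`` is the change to detect as a percent of the mean;
    ``cv_percent`` the between-station CV of the integrated means.  The
    standardized effect is ``d = delta_percent / cv_percent``.
    """

    delta_percent: float
    cv_percent: float
    alpha: float = 0.05
    beta: float = 0.2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DesignError("alpha must be in (0, 1)")
        if not 0 < self.beta < 1:
            raise DesignError("beta must be in (0, 1)")
        if self.delta_percent < 0 or self.cv_percent <= 0:
            raise DesignError("delta_percent must be >= 0 and cv_percent > 0")

    @property
    def d(self) -> float:
        return self.delta_percent / self.cv_percent

    @property
    def target_power(self) -> float:
        return 1.0 - self.beta


@dataclass(frozen=True)
class PortfolioBudget:
    """Minimal budget meeting a CI% target for every variable in a portfolio."""

    budget: float  # rounded to nearest whole cost unit
    budget_exact: float
    n_space: float  # fractional stations implied by the worst variable
    worst_cv: float
    achieved_ci: dict[str, float] = field(default_factory=dict)


def _t_value(n: float, t_mode: TMode) -> float:
    if t_mode == "fixed":
        return T_FIXED
    if t_mode == "exact_df":
        if n < 2:
            raise DesignError("exact_df mode requires N >= 2 (df >= 1)")
        return float(stats.t.ppf(0.975, math.ceil(n) - 1))
    raise ValueError(f"unknown t_mode {t_mode!r}")


def survey_cost(model: CostModel, n_space: float) -> float:
    """Total annual survey cost at ``n_space`` stations per survey."""
    if n_space < 0:
        raise DesignError("N_space must be >= 0")
    return model.N_time * n_space * model.per_station_cost + model.B


def stations_from_budget(model: CostModel, budget: float) -> float:
    """Stations per survey affordable at ``budget``; fractional by design.

    Exact algebraic inverse of :func:`survey_cost`; rounding (e.g. to a whole
    station count) is the caller's decision.
    """
    if budget <= model.B:
        raise DesignError(
            f"budget {budget} below fixed costs B = {model.B}: no stations affordable"
        )
    return (budget - model.B) / (model.N_time * model.per_station_cost)


def ci_percent(cv: float, n: float, t_mode: TMode = "fixed") -> float:
    """Precision CI% = t * CV% / sqrt(N): half-width of the 95% CI as % of mean."""
    if n <= 0:
        raise DesignError("N must be > 0")
    if cv < 0:
        raise DesignError("CV% must be >= 0")
    return _t_value(n, t_mode) * cv / math.sqrt(n)


def stations_for_precision(cv: float, target_ci: float, t_mode: TMode = "fixed") -> int:
    """Smallest integer N >= 1 with ci_percent(cv, N) <= target_ci."""
    if target_ci <= 0:
        raise DesignError("target CI% must be > 0")
    if cv == 0:
        return 1
    if t_mode == "fixed":
        n = math.ceil((T_FIXED * cv / target_ci) ** 2)
        return max(int(n), 1)
    n = 2  # exact_df needs df >= 1
    while ci_percent(cv, n, t_mode) > target_ci:
        n += 1
    return n


def cost_for_precision(
    model: CostModel,
    cv: float,
    target_ci: float,
    t_mode: TMode = "fixed",
    continuous: bool = True,
) -> float:
    """Annual cost required to reach ``target_ci`` precision for one variable.

    ``continuous=True`` keeps the implied station count fractional, tracing
    the smooth cost-precision curve; ``False`` rounds it up to a whole number
    of stations first.
    """
    if target_ci <= 0:
        raise DesignError("target CI% must be > 0")
    if not continuous:
        n_space = stations_for_precision(cv, target_ci, t_mode)
    elif t_mode == "fixed":
        n_space = (T_FIXED * cv / target_ci) ** 2
    else:
        # exact_df: t depends on N; iterate the fixed point from the normal limit
        t = float(stats.norm.ppf(0.975))
        n_space = max((t * cv / target_ci) ** 2, 2.0)
        for _ in range(50):
            t = _t_value(n_space, t_mode)
            n_new = max((t * cv / target_ci) ** 2, 2.0)
            if abs(n_new - n_space) < 1e-12:
                break
            n_space = n_new
    return survey_cost(model, n_space)


def budget_for_portfolio(
    model: CostModel,
    cvs: dict[str, float] | Sequence[float],
    target_ci: float,
) -> PortfolioBudget:
    """Minimal budget at which every variable attains ``target_ci`` precision.

    The binding variable is the one with the largest CV%; the budget is the
    continuous-mode cost for that variable, rounded to the nearest whole cost
    unit for reporting (the exact value is retained).  Achieved CI% per
    variable at the implied station count is returned alongside.
    """
    if isinstance(cvs, dict):
        cv_map = dict(cvs)
    else:
        cv_map = {f"var{i + 1}": float(c) for i, c in enumerate(cvs)}
    if not cv_map:
        raise DesignError("empty CV portfolio")
    worst = max(cv_map.values())
    n_space = (T_FIXED * worst / target_ci) ** 2
    exact = survey_cost(model, n_space)
    achieved = {name: ci_percent(cv, n_space) for name, cv in cv_map.items()}
    return PortfolioBudget(
        budget=float(round(exact)),
        budget_exact=exact,
        n_space=n_space,
        worst_cv=worst,
        achieved_ci=achieved,
    )


def power_one_sample(n: int, spec: PowerSpec) -> float:
    """Power of the two-sided one-sample t test at sample size ``n``.

    With standardized effect ``d`` the test statistic follows a noncentral t
    distribution with ``n - 1`` degrees of freedom and noncentrality
    ``d * sqrt(n)``; power is the probability that it exceeds the two-sided
    critical value.
    """
    if n < 2:
        raise DesignError("one-sample t test needs n >= 2")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    nc = spec.d * math.sqrt(n)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    # scipy's noncentral-t cdf underflows to nan far in the lower tail; the
    # true mass there is below machine epsilon
    if math.isnan(lower):
        lower = 0.0
    if math.isnan(upper):
        upper = 1.0
    return float(upper + lower)


def min_n_for_power(spec: PowerSpec, n_start: int = 2, n_cap: int = 1_000_000) -> int:
    """Smallest n >= 2 whose one-sample t power reaches ``1 - beta``.

    Power is monotone increasing in n for d > 0, so a linear scan from a
    normal-approximation starting point terminates quickly.
    """
    if spec.d <= 0:
        raise DesignError("min_n_for_power requires a positive effect d")
    # normal-approximation lower bound, backed off to stay conservative
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.target_power)
    n = max(n_start, int(((z_a + z_b) / spec.d) ** 2 * 0.5))
    while n > n_start and power_one_sample(n, spec) >= spec.target_power:
        n -= 1  # guard against overshooting the approximation
    while power_one_sample(n, spec) < spec.target_power:
        n += 1
        if n > n_cap:
            raise DesignError("sample size search exceeded cap")
    return n


def power_curve(spec: PowerSpec, n_max: int) -> list[tuple[int, float]]:
    """Power at each n = 2..n_max; strictly increasing in n for d > 0."""
    if n_max < 2:
        raise DesignError("n_max must be >= 2")
    return [(n, power_one_sample(n, spec)) for n in range(2, n_max + 1)]
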