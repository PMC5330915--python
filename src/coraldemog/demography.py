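"""Period-partitioned demographic trajectory analysis for tagged coral colonies.

Colonies are observed on a fixed photographic schedule (months 0, 6, 9, 22,
34, 46, 58, 71, 89 after an initial bleaching event) and analysed over four
named periods: the initial observation, the post-bleaching response, a
thermally stable recovery window, and the response to a second stress
event.  The module computes

* group live-area totals as a percent of the month-0 baseline,
* annualized % change rates per colony and per group, either from the
  endpoint ratio or from a linear regression of log(area) on months,
* time-to-recovery from a quadratic fit of group relative area (vertex of
  the parabola, where the slope crosses zero),
* compound-interest horizons for regrowing (or shrinking) to a target
  fraction of the baseline, and
* Student's t comparisons of bleaching extent between size classes.

Colonies are classified ``large`` when their month-0 live planar area
exceeds the species mean in the sample, ``small`` otherwise.  Colonies lost
to follow-up drop out of all group statistics from their first missing
observation onward; colonies that die contribute zero live area to group
totals.  Rates are multiplicative throughout: a monthly log-area slope
``b`` annualizes to ``100 * (exp(12 b) - 1)`` %/yr, which keeps regression
and endpoint estimates exactly consistent on noise-free exponential
trajectories and matches the compound-interest extrapolation arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "SPECIES",
    "GROUPS",
    "OBSERVATION_MONTHS",
    "Period",
    "AnalysisPeriods",
    "DEFAULT_PERIODS",
    "RateEstimate",
    "RecoveryEstimate",
    "HorizonEstimate",
    "TTestResult",
    "DemographyError",
    "UndefinedBaselineError",
    "load_colony_table",
    "assign_size_classes",
    "percent_of_baseline",
    "percent_of_baseline_totals",
    "annualized_rate_endpoint",
    "annualized_rate_regression",
    "group_rate",
    "group_percent_change",
    "recovery_time",
    "recovery_time_bootstrap",
    "horizon_years",
    "compare_size_classes",
]

SPECIES = ("O_franksi", "S_michelini", "S_siderea")
GROUPS = ("bleached", "unbleached")
OBSERVATION_MONTHS = (0, 6, 9, 22, 34, 46, 58, 71, 89)


class DemographyError(ValueError):
    """Base class for demography-module errors."""


class UndefinedBaselineError(DemographyError):
    """Group baseline live area sums to zero."""


@dataclass(frozen=True)
class Period:
    """A named analysis window with the observation months it spans.

    ``months`` includes the anchor observation used as the starting point
    for rate estimation (e.g. the second-event response spans observations
    71 and 89 but is anchored at the month-58 area).
    """

    name: str
    start: int
    end: int
    months: tuple[int, ...]

    @property
    def span_months(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnalysisPeriods:
    initial: Period = field(default_factory=lambda: Period("initial", 0, 0, (0,)))
    response: Period = field(default_factory=lambda: Period("response", 0, 9, (0, 6, 9)))
    recovery: Period = field(
        default_factory=lambda: Period("recovery", 22, 58, (22, 34, 46, 58))
    )
    second_event_response: Period = field(
        default_factory=lambda: Period("second_event_response", 58, 89, (58, 71, 89))
    )

    def __post_init__(self):
        spans = [
            (p.start, p.end)
            for p in (self.response, self.recovery, self.second_event_response)
        ]
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:  # shared endpoints allowed (anchor observations)
                raise DemographyError("analysis periods overlap or are out of order")

    def __iter__(self):
        return iter((self.response, self.recovery, self.second_event_response))


DEFAULT_PERIODS = AnalysisPeriods()


@dataclass(frozen=True)
class RateEstimate:
    rate_pct_per_year: float
    method: str  # "regression" | "endpoint" | "mixed"
    n_colonies: int
    se_pct: float | None
    period: str

    def __post_init__(self):
        if not math.isfinite(self.rate_pct_per_year):
            raise DemographyError("rate must be finite")
        if self.n_colonies < 1:
            raise DemographyError("rate needs at least one colony")


@dataclass(frozen=True)
class RecoveryEstimate:
    t_star_months: float | None
    r_squared: float
    extrapolated: bool
    coefficients: tuple[float, float, float]  # a, b, c of a t^2 + b t + c


@dataclass(frozen=True)
class HorizonEstimate:
    years: float  # math.inf when the target is unreachable at this rate
    start_fraction: float
    target_fraction: float
    annual_rate_pct: float

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.years)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# table handling

_REQUIRED_COLS = ("colony_id", "species", "group2005", "month", "live_area_cm2", "status")


def load_colony_table(path) -> pd.DataFrame:
    """Read a delimited colony-observation table.

    Required columns: colony_id, species, group2005, month, live_area_cm2,
    status; optional: frac_bleached, frac_partial, dead_area_cm2.
    """
    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLS) - set(df.columns)
    if missing:
        raise DemographyError(f"colony table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise DemographyError("colony table is empty")
    return df


def assign_size_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Attach a size_class column: large if the month-0 live planar area
    exceeds the species mean of month-0 areas, small otherwise (ties small).
    """
    base = table[table["month"] == 0]
    if len(base) == 0:
        raise DemographyError("size classes need month-0 observations")
    out = table.copy()
    out["size_class"] = "small"
    for sp, g in base.groupby("species"):
        areas = g.set_index("colony_id")["live_area_cm2"]
        if len(areas) < 2 or np.ptp(areas.to_numpy()) == 0:
            warnings.warn(
                f"degenerate size split for {sp}: "
                f"{len(areas)} colony(ies), all assigned small",
                stacklevel=2,
            )
            continue
        large_ids = set(areas[areas > areas.mean()].index)
        out.loc[out["colony_id"].isin(large_ids), "size_class"] = "large"
    return out


def _cohort(table: pd.DataFrame, month: int, baseline_month: int) -> pd.DataFrame:
    """Colonies with observations at both months (lost colonies drop out)."""
    sub = table[table["month"].isin((baseline_month, month))]
    sub = sub[sub["status"] != "lost"]
    counts = sub.groupby("colony_id")["month"].nunique()
    keep = counts[counts == (1 if month == baseline_month else 2)].index
    return sub[sub["colony_id"].isin(keep)]


def percent_of_baseline(
    table: pd.DataFrame, month: int, baseline_month: int = 0
) -> float:
    """Group live area at ``month`` as a percent of the baseline total.

    ``100 * sum(live_area(month)) / sum(live_area(baseline))`` over colonies
    still in the record at ``month`` (dead colonies contribute zero; lost
    colonies are excluded from both sums).  Full precision is returned;
    round to 2 decimals for reporting.
    """
    sub = _cohort(table, month, baseline_month)
    s0 = sub.loc[sub["month"] == baseline_month, "live_area_cm2"].sum()
    sm = sub.loc[sub["month"] == month, "live_area_cm2"].sum()
    if not s0 > 0:
        raise UndefinedBaselineError("baseline live area sums to zero")
    return 100.0 * float(sm) / float(s0)


def percent_of_baseline_totals(area_cm2: float, baseline_cm2: float) -> float:
    """Percent of baseline from pre-summed group totals (cm²)."""
    if not baseline_cm2 > 0:
        raise UndefinedBaselineError("baseline live area must be positive")
    return 100.0 * float(area_cm2) / float(baseline_cm2)


# ---------------------------------------------------------------------------
# annualized rates

def annualized_rate_endpoint(a_start: float, a_end: float, months: float) -> float:
    """Annualized % change from the endpoint area ratio.

    ``100 * ((a_end / a_start) ** (12 / months) - 1)``; a colony ending at
    zero area returns exactly -100.
    """
    if a_start <= 0:
        raise DemographyError("endpoint rate requires a positive starting area")
    if months <= 0:
        raise DemographyError("endpoint rate requires a positive time span")
    if a_end == 0:
        return -100.0
    return 100.0 * ((a_end / a_start) ** (12.0 / months) - 1.0)


def annualized_rate_regression(
    months: Sequence[float], areas: Sequence[float]
) -> tuple[float, str]:
    """Annualized % change from the slope of log(area) on months.

    Returns ``(rate_pct_per_year, method)``.  Fewer than three usable
    points, or any non-positive area, falls back to the endpoint method
    (flagged ``"endpoint"``).
    """
    m = np.asarray(months, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(m) != len(a) or len(m) < 2:
        raise DemographyError("need at least two paired observations")
    if len(m) < 3 or np.any(a <= 0):
        return (
            annualized_rate_endpoint(a[0], a[-1], m[-1] - m[0]),
            "endpoint",
        )
    beta = np.polyfit(m, np.log(a), 1)[0]
    return 100.0 * (math.exp(12.0 * beta) - 1.0), "regression"


def _colony_period_obs(g: pd.DataFrame, period: Period) -> tuple[np.ndarray, np.ndarray] | None:
    g = g[(g["month"].isin(period.months)) & (g["status"] != "lost")]
    if g["month"].nunique() != len(period.months):
        return None  # lost to follow-up within the period
    g = g.sort_values("month")
    return g["month"].to_numpy(dtype=float), g["live_area_cm2"].to_numpy(dtype=float)


def _colony_log_slope(m: np.ndarray, a: np.ndarray, method: str) -> tuple[float, str]:
    """Per-colony monthly log-area slope, with endpoint fallback for zeros."""
    if a[-1] == 0:
        return -np.inf, "endpoint"  # dead within the period
    if method == "endpoint" or len(m) < 3 or np.any(a <= 0):
        ratio = a[-1] / a[0]
        return math.log(ratio) / (m[-1] - m[0]), "endpoint"
    return float(np.polyfit(m, np.log(a), 1)[0]), "regression"


def group_rate(
    table: pd.DataFrame,
    period: Period,
    method: Literal["regression", "endpoint"] = "regression",
    include_dead: bool = False,
    aggregate: Literal["geometric", "arithmetic"] = "geometric",
) -> RateEstimate:
    """Group annualized rate over a period, aggregated across colonies.

    With the default ``aggregate="geometric"`` the per-colony monthly
    log-area slopes are averaged and then annualized, which is unbiased
    under multiplicative (lognormal) colony-to-colony variation;
    ``"arithmetic"`` averages the per-colony % rates directly.  Colonies
    that die within the period are excluded unless ``include_dead`` is
    set, in which case they enter as -100 %/yr (endpoint method) and the
    estimate is flagged ``"mixed"``.
    """
    slopes: list[float] = []
    rates: list[float] = []
    methods: set[str] = set()
    for _, g in table.groupby("colony_id"):
        obs = _colony_period_obs(g, period)
        if obs is None:
            continue
        m, a = obs
        if a[0] <= 0:
            continue  # dead before the period began
        slope, used = _colony_log_slope(m, a, method)
        if not math.isfinite(slope):  # died within the period
            if not include_dead:
                continue
            methods.add("endpoint")
            rates.append(-100.0)
            slopes.append(np.nan)
            continue
        methods.add(used)
        slopes.append(slope)
        rates.append(100.0 * (math.exp(12.0 * slope) - 1.0))
    n = len(rates)
    if n == 0:
        raise DemographyError(f"no usable colonies for period {period.name!r}")
    rates_arr = np.asarray(rates)
    if aggregate == "geometric" and not any(np.isnan(slopes)):
        sl = np.asarray(slopes)
        mean_rate = 100.0 * (math.exp(12.0 * sl.mean()) - 1.0)
        # delta-method SE on the annualized scale
        se = (
            100.0 * math.exp(12.0 * sl.mean()) * 12.0 * sl.std(ddof=1) / math.sqrt(n)
            if n >= 2
            else None
        )
    else:
        mean_rate = float(rates_arr.mean())
        se = float(rates_arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    used_method = methods.pop() if len(methods) == 1 else "mixed"
    return RateEstimate(mean_rate, used_method, n, se, period.name)


def group_percent_change(
    table: pd.DataFrame,
    start_month: int = 0,
    end_month: int = 9,
    include_dead: bool = False,
) -> tuple[float, float | None, int]:
    """Mean per-colony % change in live area between two observations.

    Returns ``(mean_pct_change, se, n)``; a loss appears as a negative
    change.  Lost colonies are excluded; colonies dead by ``end_month``
    are excluded by default (their mortality is reported separately), or
    included as -100% with ``include_dead``.
    """
    changes = []
    for _, g in table.groupby("colony_id"):
        g = g[(g["month"].isin((start_month, end_month))) & (g["status"] != "lost")]
        if g["month"].nunique() != 2:
            continue
        g = g.sort_values("month")
        a0, a1 = g["live_area_cm2"].to_numpy(dtype=float)
        if a0 <= 0:
            continue
        if a1 == 0 and not include_dead:
            continue
        changes.append(100.0 * (a1 / a0 - 1.0))
    n = len(changes)
    if n == 0:
        raise DemographyError("no usable colonies for percent change")
    arr = np.asarray(changes)
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return float(arr.mean()), se, n


# ---------------------------------------------------------------------------
# recovery time and horizons

def recovery_time(
    months: Sequence[float],
    values: Sequence[float],
    curvature_tol: float = 1e-12,
) -> RecoveryEstimate:
    """Time at which a quadratic fit of group relative area has zero slope.

    Fits ``a t^2 + b t + c`` by least squares and reports the vertex
    ``t* = -b / (2a)`` together with r².  When the normalized curvature is
    below ``curvature_tol`` (an effectively linear trajectory) no vertex is
    reported.  ``extrapolated`` flags a vertex outside the observed span.
    """
    m = np.asarray(months, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(m) != len(v) or len(m) < 4:
        raise DemographyError("recovery fit needs at least 4 time points")
    a, b, c = np.polyfit(m, v, 2)
    fitted = np.polyval((a, b, c), m)
    ss_res = float(np.sum((v - fitted) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    span = float(np.ptp(m)) or 1.0
    scale = max(float(np.max(np.abs(v))), 1.0)
    if abs(a) * span**2 / scale < curvature_tol:
        return RecoveryEstimate(None, r2, False, (float(a), float(b), float(c)))
    t_star = -b / (2.0 * a)
    extrapolated = not (m.min() <= t_star <= m.max())
    return RecoveryEstimate(float(t_star), r2, extrapolated, (float(a), float(b), float(c)))


def recovery_time_bootstrap(
    months: Sequence[float],
    values: Sequence[float],
    n_boot: int = 400,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[RecoveryEstimate, tuple[float, float], np.ndarray]:
    """Residual-bootstrap confidence interval for the recovery vertex.

    Resamples fit residuals with replacement, refits the quadratic, and
    returns the point estimate, the percentile CI, and the bootstrap
    vertex samples (degenerate no-curvature draws are dropped).
    """
    m = np.asarray(months, dtype=float)
    v = np.asarray(values, dtype=float)
    est = recovery_time(m, v)
    fitted = np.polyval(est.coefficients, m)
    resid = v - fitted
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_boot):
        vb = fitted + rng.choice(resid, size=len(resid), replace=True)
        rb = recovery_time(m, vb)
        if rb.t_star_months is not None:
            samples.append(rb.t_star_months)
    arr = np.asarray(samples)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
    return est, (float(lo), float(hi)), arr


def horizon_years(
    start_fraction: float, annual_rate_pct: float, target_fraction: float
) -> HorizonEstimate:
    """Years of compound growth to move from start to target fraction.

    ``years = ln(target/start) / ln(1 + rate/100)`` when the sign of the
    rate moves the start toward the target; otherwise the horizon is
    unreachable (infinite years).
    """
    if start_fraction <= 0:
        raise DemographyError("start fraction must be positive")
    if target_fraction <= 0:
        raise DemographyError("target fraction must be positive")
    if annual_rate_pct <= -100:
        raise DemographyError("rate must exceed -100 %/yr")
    if annual_rate_pct == 0:
        raise DemographyError("rate must be nonzero")
    toward = (target_fraction > start_fraction) == (annual_rate_pct > 0)
    if start_fraction == target_fraction:
        years = 0.0
    elif not toward:
        years = math.inf
    else:
        years = math.log(target_fraction / start_fraction) / math.log1p(
            annual_rate_pct / 100.0
        )
    return HorizonEstimate(years, start_fraction, target_fraction, annual_rate_pct)


# ---------------------------------------------------------------------------
# size-class comparison

def compare_size_classes(
    values_large: Sequence[float],
    values_small: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sample two-tailed t test between size classes.

    Student's pooled-variance t by default (df = n1 + n2 - 2); Welch's
    unequal-variance variant behind the ``welch`` flag.  Two identical
    zero-variance samples give t = 0, p = 1.
    """
    x = np.asarray(values_large, dtype=float)
    y = np.asarray(values_small, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DemographyError("t test needs at least two values per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2
        return TTestResult(0.0, float(df), 1.0, alpha)
    res = _stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if welch else float(len(x) + len(y) - 2)
    return TTestResult(float(res.statistic), df, float(res.pvalue), alpha)
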