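"""Gompertz curves for pig body weight and cumulative feed / water intake.

Cumulative weight, feed intake and drinking-water intake of fattening pigs
all follow the same four-parameter Gompertz form

    W(t) = A + M * exp(-exp(-B * (t - t_star)))

where ``t`` is the age of the animal in days, ``A`` is a constant offset,
``M`` is the asymptote (mature weight, or total mature feed/water intake),
``B`` controls how fast the asymptote is approached and ``t_star`` is the
age at which the daily rate is maximal.  Three of the four parameters are
fixed at values estimated by regression on Dutch fattening-pig data; the
asymptote is refitted per growing period so the curve passes through the
observed start and end weight (or the observed intake totals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GompertzParams",
    "GrowthTrajectory",
    "WEIGHT_DEFAULTS",
    "FEED_DEFAULTS",
    "WATER_DEFAULTS",
    "gompertz_value",
    "invert_gompertz",
    "fit_endpoints",
    "fit_total",
    "daily_series",
    "build_trajectory",
]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of one cumulative Gompertz curve.

    Units of ``offset_A`` and ``asymptote_M`` follow the curve (kg body
    weight, kg feed, or L water); ``rate_B`` is per day and ``t_star`` a
    day of age.
    """

    offset_A: float
    asymptote_M: float
    rate_B: float
    t_star: float

    def __post_init__(self) -> None:
        if not self.rate_B > 0:
            raise ValueError(f"rate_B must be > 0, got {self.rate_B}")
        if not self.asymptote_M > 0:
            raise ValueError(f"asymptote_M must be > 0, got {self.asymptote_M}")
        if not self.t_star > 0:
            raise ValueError(f"t_star must be > 0, got {self.t_star}")

    def replace(self, **kw) -> "GompertzParams":
        d = dict(
            offset_A=self.offset_A,
            asymptote_M=self.asymptote_M,
            rate_B=self.rate_B,
            t_star=self.t_star,
        )
        d.update(kw)
        return GompertzParams(**d)


#: Regression estimates for Dutch fattening pigs (weight in kg, feed in kg,
#: drinking water in L).  Asymptotes are refitted to scenario endpoints.
WEIGHT_DEFAULTS = GompertzParams(0.0, 164.2, 0.0146, 110.4)
FEED_DEFAULTS = GompertzParams(-41.9, 608.0, 0.0111, 154.7)
WATER_DEFAULTS = GompertzParams(-149.0, 1432.0, 0.0103, 147.4)


@dataclass(frozen=True)
class GrowthTrajectory:
    """Daily performance of the average pig over one growing period."""

    age_at_entry: float
    period_length: int
    daily_weight: np.ndarray  # kg, weight at end of each day
    daily_gain: np.ndarray  # kg/d
    daily_feed: np.ndarray  # kg/d
    daily_water: np.ndarray  # L/d


def gompertz_value(params: GompertzParams, t: float):
    """Evaluate the cumulative Gompertz curve at age ``t`` (days).

    Total function: accepts scalars or arrays, any finite ``t``.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # far-past t: inner exp -> inf, value -> A
        val = params.offset_A + params.asymptote_M * np.exp(
            -np.exp(-params.rate_B * (t - params.t_star))
        )
    return float(val) if val.ndim == 0 else val


def invert_gompertz(params: GompertzParams, value: float) -> float:
    """Age at which the curve reaches ``value`` (closed-form inverse).

    Requires ``offset_A < value < offset_A + asymptote_M``.
    """
    frac = (value - params.offset_A) / params.asymptote_M
    if not 0.0 < frac < 1.0:
        raise ValueError(
            f"value {value} outside the open range "
            f"({params.offset_A}, {params.offset_A + params.asymptote_M})"
        )
    return params.t_star - math.log(-math.log(frac)) / params.rate_B


def fit_endpoints(
    defaults: GompertzParams,
    start_value: float,
    end_value: float,
    period_length: float,
    max_asymptote_factor: float = 3.0,
) -> tuple[float, float]:
    """Fit the asymptote and entry age to period endpoints.

    Holds ``offset_A``, ``rate_B`` and ``t_star`` at their default values
    and finds ``(asymptote_M, age_at_entry)`` such that the curve passes
    through ``start_value`` at entry and ``end_value`` exactly
    ``period_length`` days later.

    The entry age follows analytically from the asymptote (the Gompertz
    curve is invertible in ``t``), which reduces the fit to a 1-D root
    find on the asymptote.  The asymptote bracket runs from just above
    the end value up to ``max_asymptote_factor`` times the default mature
    value: without that cap, implausibly fast endpoint pairs can always
    be "fitted" by a biologically meaningless multi-tonne mature weight.

    Raises
    ------
    ValueError
        If ``end_value`` is unreachable for any asymptote in the bracket
        (the residual does not change sign).
    """
    if not 0 < start_value < end_value:
        raise ValueError(
            f"need 0 < start_value < end_value, got {start_value}, {end_value}"
        )
    if not period_length > 0:
        raise ValueError(f"period_length must be > 0, got {period_length}")

    def residual(m: float) -> float:
        p = defaults.replace(asymptote_M=m)
        t0 = invert_gompertz(p, start_value)
        return gompertz_value(p, t0 + period_length) - end_value

    lo = (end_value - defaults.offset_A) * 1.0001
    hi = max_asymptote_factor * defaults.asymptote_M
    if hi <= lo:
        raise ValueError(
            f"end value {end_value} not reachable: it exceeds the plausible "
            f"asymptote range (cap {hi:.4g}, need > {lo:.4g})"
        )
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise ValueError(
            f"end value {end_value} kg not reachable in {period_length} d from "
            f"{start_value} kg for any asymptote in [{lo:.4g}, {hi:.4g}] "
            f"(residuals {r_lo:.4g}, {r_hi:.4g} do not bracket a root)"
        )
    m = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-15)
    t0 = invert_gompertz(defaults.replace(asymptote_M=m), start_value)
    return float(m), float(t0)


def fit_total(
    defaults: GompertzParams,
    total: float,
    age_at_entry: float,
    period_length: float,
) -> float:
    """Fit the asymptote so the cumulative increase over the period equals
    ``total`` (used for feed and drinking-water curves, with the entry age
    taken from the weight fit).

    The offset cancels in the difference, so the asymptote is linear in the
    total:  M = total / (g(t0 + L) - g(t0))  with g the double exponential.
    """
    if total <= 0:
        raise ValueError(f"total must be > 0, got {total}")

    def g(t: float) -> float:
        return math.exp(-math.exp(-defaults.rate_B * (t - defaults.t_star)))

    delta = g(age_at_entry + period_length) - g(age_at_entry)
    if delta <= 0:
        raise ValueError("degenerate period: cumulative curve does not increase")
    return total / delta


def daily_series(
    params: GompertzParams,
    age_at_entry: float,
    period_length: int,
    clamp_nonnegative: bool = True,
) -> np.ndarray:
    """Daily values as first differences of the cumulative curve.

    Day ``d`` (1-based) gets ``C(t0+d) - C(t0+d-1)``.  Negative differences
    cannot occur for ``rate_B > 0``, but the feed and water curves have
    negative offsets, so very early cumulative *values* can be negative;
    daily intakes are clamped at zero by default as a guard.
    """
    if period_length < 1:
        raise ValueError("period_length must be >= 1")
    t = age_at_entry + np.arange(period_length + 1, dtype=float)
    cum = gompertz_value(params, t)
    diff = np.diff(cum)
    if clamp_nonnegative:
        diff = np.maximum(diff, 0.0)
    return diff


def build_trajectory(
    start_weight: float,
    end_weight: float,
    period_length: int,
    total_feed: float,
    total_water: float,
    weight_defaults: GompertzParams = WEIGHT_DEFAULTS,
    feed_defaults: GompertzParams = FEED_DEFAULTS,
    water_defaults: GompertzParams = WATER_DEFAULTS,
) -> GrowthTrajectory:
    """Fit all three curves for one growing period and extract daily series.

    Weight is fitted to the (start, end) endpoints; feed and water
    asymptotes are fitted so the cumulative increase over the period equals
    the total intakes, with the entry age taken from the weight fit.
    """
    m_w, t0 = fit_endpoints(weight_defaults, start_weight, end_weight, period_length)
    wp = weight_defaults.replace(asymptote_M=m_w)
    m_f = fit_total(feed_defaults, total_feed, t0, period_length)
    m_d = fit_total(water_defaults, total_water, t0, period_length)
    fp = feed_defaults.replace(asymptote_M=m_f)
    dp = water_defaults.replace(asymptote_M=m_d)

    days = np.arange(1, period_length + 1, dtype=float)
    weight = gompertz_value(wp, t0 + days)
    gain = daily_series(wp, t0, period_length, clamp_nonnegative=False)
    feed = daily_series(fp, t0, period_length)
    water = daily_series(dp, t0, period_length)
    return GrowthTrajectory(
        age_at_entry=t0,
        period_length=period_length,
        daily_weight=weight,
        daily_gain=gain,
        daily_feed=feed,
        daily_water=water,
    )
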