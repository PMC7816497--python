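"""Product-limit survival estimation and smoothed hazards.

Overall survival (OS) treats death from any cause as the event; cancer-
specific survival (CSS) treats only cancer-specific deaths as events and
censors other-cause deaths at their death time (the registry cause-specific
convention — not a cumulative-incidence quantity).  Kaplan-Meier fitting
and the log-rank test are delegated to :mod:`lifelines`; the Greenwood
variance is assembled from the event table, and the hazard smoother is an
Epanechnikov kernel over Nelson-Aalen increments with boundary
renormalization.

Conventions: survival curves are right-continuous (the value at an event
time is the post-drop value), and tied deaths precede tied censorings
within a month — the natural reading for registry data recorded in whole
months.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

Endpoint = Literal["OS", "CSS"]

__all__ = [
    "SurvivalCurve",
    "HazardCurve",
    "LogRankResult",
    "SurvivalPoint",
    "endpoint_durations_events",
    "km_curve",
    "survival_at",
    "log_rank",
    "smoothed_hazard",
    "median_followup",
]


def endpoint_durations_events(
    cohort: pd.DataFrame, endpoint: Endpoint
) -> tuple[np.ndarray, np.ndarray]:
    """Durations (months) and event indicators for an endpoint.

    OS: event = death from any cause.  CSS: event = cancer-specific death;
    alive subjects and other-cause deaths are censored.
    """
    if endpoint not in ("OS", "CSS"):
        raise ValueError(f"endpoint must be 'OS' or 'CSS', got {endpoint!r}")
    durations = cohort["followup_months"].to_numpy(dtype=float)
    dead = (cohort["vital_status"] == "dead").to_numpy()
    if endpoint == "OS":
        events = dead
    else:
        events = dead & cohort["cancer_specific_death"].fillna(False).to_numpy(
            dtype=bool
        )
    return durations, events.astype(bool)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with per-event-time bookkeeping.

    ``event_times`` lists only times with at least one event; ``survival``
    holds the post-drop values S(t) there, with Greenwood variance.
    ``max_time`` is the largest observed time (event or censoring); the
    curve is undefined beyond it.
    """

    endpoint: Endpoint
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    max_time: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "n_censored": self.n_censored,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
            }
        )


class SurvivalPoint(NamedTuple):
    survival: float
    variance: float


@dataclass(frozen=True)
class HazardCurve:
    endpoint: Endpoint
    grid_times: np.ndarray
    hazard: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def km_curve(cohort: pd.DataFrame, endpoint: Endpoint = "OS") -> SurvivalCurve:
    """Product-limit estimate of OS or CSS with Greenwood variance."""
    if len(cohort) == 0:
        raise ValueError("cannot estimate a survival curve from an empty cohort")
    durations, events = endpoint_durations_events(cohort, endpoint)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table  # indexed by time, incl. a t=0 row
    obs = table[table["observed"] > 0]
    times = obs.index.to_numpy(dtype=float)
    d = obs["observed"].to_numpy(dtype=float)
    n = obs["at_risk"].to_numpy(dtype=float)
    censored = obs["censored"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return SurvivalCurve(
        endpoint=endpoint,
        event_times=times,
        n_at_risk=n.astype(int),
        n_events=d.astype(int),
        n_censored=censored.astype(int),
        survival=surv,
        greenwood_var=var,
        n_total=len(cohort),
        max_time=float(np.max(durations)),
    )


def survival_at(curve: SurvivalCurve, t: float) -> SurvivalPoint:
    """Step-function lookup S(t): the value at the largest event time <= t.

    Right-continuous, so ``t`` exactly at an event time returns the
    post-drop value.  The one exception is t=0: deaths recorded at zero
    months occurred within the first month (floored registry times), so
    S(0) = 1 by definition.  ``t`` beyond the last observed time is an
    error — the estimator does not extrapolate.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if t == 0:
        return SurvivalPoint(1.0, 0.0)
    if t > curve.max_time:
        raise ValueError(
            f"t={t} exceeds the last observed time {curve.max_time}; "
            "no extrapolation"
        )
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return SurvivalPoint(1.0, 0.0)
    return SurvivalPoint(
        float(curve.survival[idx]), float(curve.greenwood_var[idx])
    )


def log_rank(
    groups: Sequence[tuple[str, pd.DataFrame]], endpoint: Endpoint = "OS"
) -> LogRankResult:
    """k-group log-rank chi-square test with df = k - 1."""
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two groups")
    for label, g in groups:
        if len(g) == 0:
            raise ValueError(f"group {label!r} has zero subjects")
    durations, events, labels = [], [], []
    for label, g in groups:
        dur, ev = endpoint_durations_events(g, endpoint)
        durations.append(dur)
        events.append(ev)
        labels.extend([label] * len(g))
    result = multivariate_logrank_test(
        np.concatenate(durations), labels, np.concatenate(events)
    )
    return LogRankResult(
        statistic=float(result.test_statistic),
        df=len(groups) - 1,
        p_value=float(result.p_value),
    )


def _epanechnikov_integral(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Integral of the Epanechnikov kernel over [lo, hi] within [-1, 1]."""
    lo = np.clip(lo, -1.0, 1.0)
    hi = np.clip(hi, -1.0, 1.0)
    antideriv = lambda u: 0.75 * (u - u**3 / 3.0)
    return antideriv(hi) - antideriv(lo)


def smoothed_hazard(
    cohort: pd.DataFrame,
    endpoint: Endpoint = "OS",
    bandwidth: float = 12.0,
    grid: Iterable[float] | None = None,
) -> HazardCurve:
    """Kernel-smoothed instantaneous hazard (per month).

    Smooths the Nelson-Aalen increments d_i/n_i at each event time with an
    Epanechnikov kernel of the given bandwidth, renormalizing the kernel
    mass near t=0 and the last follow-up time so boundary estimates are not
    biased downward.  A cohort with no events yields an all-zero curve.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    durations, events = endpoint_durations_events(cohort, endpoint)
    t_max = float(np.max(durations)) if len(durations) else 0.0
    grid_arr = (
        np.arange(0.0, t_max + 1.0) if grid is None else np.asarray(list(grid), float)
    )
    if not events.any():
        return HazardCurve(endpoint, grid_arr, np.zeros_like(grid_arr), bandwidth)
    curve = km_curve(cohort, endpoint)
    increments = curve.n_events / curve.n_at_risk  # Nelson-Aalen dA
    u = (grid_arr[:, None] - curve.event_times[None, :]) / bandwidth
    weights = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0) / bandwidth
    raw = weights @ increments
    mass = _epanechnikov_integral(
        (grid_arr - t_max) / bandwidth, grid_arr / bandwidth
    )
    hazard = np.where(mass > 0, raw / np.maximum(mass, 1e-300), 0.0)
    return HazardCurve(endpoint, grid_arr, hazard, bandwidth)


def median_followup(cohort: pd.DataFrame) -> float:
    """Median potential follow-up by the reverse Kaplan-Meier method
    (censoring-distribution median).  Diagnostic only."""
    durations = cohort["followup_months"].to_numpy(dtype=float)
    censored = (cohort["vital_status"] == "alive").to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=censored)
    return float(kmf.median_survival_time_)
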