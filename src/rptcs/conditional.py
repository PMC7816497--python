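"""Conditional survival and standardized-difference comparisons.

Conditional survival answers the survivor's question rather than the
newly-diagnosed patient's: given that a patient is still alive x years
after resection, what is the probability of surviving y further years?

    CS(y | x) = S(x + y) / S(x)

with S either overall survival (OS) or cancer-specific survival (CSS).
The 3-year flavours — COS3(x) = OS(x+3)/OS(x) and CCSS3(x) =
CSS(x+3)/CSS(x) — track how the 3-year outlook evolves with time already
survived.  Under a decreasing hazard CS3 rises with x even while actual
survival keeps falling; under a constant hazard it is flat (memorylessness).

Between-group contrasts use the standardized difference of proportions

    d = (P2 - P1) / sqrt(P (1 - P))

where P is the pooled whole-cohort conditional rate at the same time point,
with |d| < 0.1 read as no difference, 0.1-0.3 small, 0.3-0.5 moderate and
>= 0.5 significant.  In a contrast labelled "A vs B", P2 is group A's rate
and P1 group B's, so d is positive when A fares better.

All ratios are computed on unrounded survival values; rounding to one
decimal (percent) or two decimals (d) happens only at presentation.  When
printed one-decimal percentages are supplied directly, the ratio is taken
on those values as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .survival import Endpoint, SurvivalCurve, km_curve, survival_at

__all__ = [
    "ConditionalUndefinedError",
    "CS3Series",
    "ConditionalSurvivalMatrix",
    "StandardizedDifference",
    "conditional_survival",
    "cs3_series",
    "conditional_matrix",
    "stratified_cs3",
    "standardized_difference",
    "d_series",
    "classify_band",
]

MONTHS_PER_YEAR = 12

Band = Literal["none", "small", "moderate", "significant"]


class ConditionalUndefinedError(ValueError):
    """CS(y|x) is undefined because S(x) = 0."""


def conditional_survival(
    curve_or_values: SurvivalCurve | tuple[float, float],
    x: float,
    y: float,
) -> float:
    """CS(y|x) = 100 * S(x+y)/S(x), in percent.

    ``curve_or_values`` is either a fitted :class:`SurvivalCurve` (x, y in
    years, looked up on the monthly step function) or a pair
    ``(S(x), S(x+y))`` of raw survival values — proportions or printed
    percentages, the ratio being scale-invariant.
    """
    if x < 0 or y < 0:
        raise ValueError("x and y must be non-negative")
    if isinstance(curve_or_values, SurvivalCurve):
        s_x = survival_at(curve_or_values, MONTHS_PER_YEAR * x).survival
        if s_x <= 0:
            raise ConditionalUndefinedError(
                f"S(x)={s_x}: conditional survival undefined"
            )
        s_xy = survival_at(curve_or_values, MONTHS_PER_YEAR * (x + y)).survival
    else:
        s_x, s_xy = curve_or_values
        if s_x <= 0:
            raise ConditionalUndefinedError(
                f"S(x)={s_x}: conditional survival undefined"
            )
    return 100.0 * s_xy / s_x


@dataclass
class CS3Series:
    """Conditional y-year survival (default y=3) over years already survived.

    ``actual`` pairs each CS value with the unconditional S(x+window) so the
    widening gap between the survivor's outlook and the baseline curve can
    be displayed directly.  ``cs[0]`` equals the actual window-year survival
    by construction.
    """

    endpoint: Endpoint
    x_years: list[int]
    cs: list[float]  # percent, unrounded
    actual: list[float]  # percent, S(x + window), unrounded
    window: int = 3

    def at(self, x: int) -> float:
        return self.cs[self.x_years.index(x)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_years": self.x_years,
                f"cs{self.window}_percent": self.cs,
                "actual_percent": self.actual,
            }
        )


def cs3_series(
    curve: SurvivalCurve, x_max: int, window: int = 3
) -> CS3Series:
    """CS(window|x) for x = 0..x_max on the yearly grid.

    If follow-up does not extend to (x_max + window) years the series is
    truncated at the last supported x with a warning — never silently
    extrapolated.
    """
    xs: list[int] = []
    cs: list[float] = []
    actual: list[float] = []
    for x in range(x_max + 1):
        horizon = MONTHS_PER_YEAR * (x + window)
        if horizon > curve.max_time:
            warnings.warn(
                f"follow-up ends at {curve.max_time} months; CS{window} series "
                f"truncated at x={x - 1}",
                stacklevel=2,
            )
            break
        s_x = survival_at(curve, MONTHS_PER_YEAR * x).survival
        if s_x <= 0:
            warnings.warn(
                f"S({x}y)=0; CS{window} series truncated at x={x - 1}",
                stacklevel=2,
            )
            break
        xs.append(x)
        cs.append(conditional_survival(curve, x, window))
        actual.append(100.0 * survival_at(curve, horizon).survival)
    return CS3Series(curve.endpoint, xs, cs, actual, window)


@dataclass
class ConditionalSurvivalMatrix:
    """CS grid: rows are total survival time (years), columns years already
    survived; cell (total, x) = CS(total-x | x) in percent.  Cells with
    x > total are undefined (NaN); the diagonal is exactly 100."""

    endpoint: Endpoint
    table: pd.DataFrame  # index: total years; columns: x years survived

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.table.round(decimals)


def conditional_matrix(
    curve: SurvivalCurve, max_total_years: int
) -> ConditionalSurvivalMatrix:
    """Fill the conditional grid up to ``max_total_years``.

    Column x=0 reproduces the unconditional curve; requires follow-up
    through ``max_total_years``.
    """
    totals = range(1, max_total_years + 1)
    xs = range(0, max_total_years + 1)
    data = np.full((max_total_years, max_total_years + 1), np.nan)
    for i, total in enumerate(totals):
        for x in xs:
            if x > total:
                continue
            if x == total:
                data[i, x] = 100.0
            else:
                data[i, x] = conditional_survival(curve, x, total - x)
    table = pd.DataFrame(data, index=list(totals), columns=list(xs))
    table.index.name = "total_years"
    table.columns.name = "x_years_survived"
    return ConditionalSurvivalMatrix(curve.endpoint, table)


def stratified_cs3(
    cohort: pd.DataFrame,
    factor: str,
    endpoint: Endpoint = "OS",
    x_max: int = 5,
    window: int = 3,
    levels: Sequence[str] | None = None,
) -> dict[str, CS3Series]:
    """Per-level CS series: a Kaplan-Meier curve then a CS series per level
    of ``factor``.  Levels with exhausted follow-up truncate individually."""
    if levels is None:
        observed = cohort[factor]
        if observed.dtype == bool:
            levels = ["no", "yes"]
            groups = {"no": cohort[~observed], "yes": cohort[observed]}
        else:
            levels = [lv for lv in pd.unique(observed)]
            groups = {lv: cohort[observed == lv] for lv in levels}
    else:
        if cohort[factor].dtype == bool:
            mapped = cohort[factor].map({False: "no", True: "yes"})
        else:
            mapped = cohort[factor]
        groups = {lv: cohort[mapped == lv] for lv in levels}
    out: dict[str, CS3Series] = {}
    for lv, group in groups.items():
        if len(group) == 0:
            raise ValueError(f"stratum {factor}={lv!r} is empty")
        out[lv] = cs3_series(km_curve(group, endpoint), x_max, window)
    return out


def classify_band(d: float) -> Band:
    """Interpretation band for |d|: <0.1 none, 0.1-0.3 small,
    0.3-0.5 moderate, >=0.5 significant."""
    a = abs(d)
    if a < 0.1:
        return "none"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "significant"


@dataclass(frozen=True)
class StandardizedDifference:
    p2: float  # rate of the first-listed group ("A" in "A vs B")
    p1: float  # rate of the second-listed group
    p_overall: float  # pooled cohort rate at the same time point
    d: float
    band: Band


def standardized_difference(
    p2: float, p1: float, p_overall: float
) -> StandardizedDifference:
    """d = (p2 - p1)/sqrt(p_overall (1 - p_overall)), all as proportions.

    ``p_overall`` at 0 or 1 makes the denominator vanish and is an error.
    """
    for name, p in (("p2", p2), ("p1", p1), ("p_overall", p_overall)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if p_overall in (0.0, 1.0):
        raise ValueError("p_overall of 0 or 1 leaves d undefined")
    d = (p2 - p1) / np.sqrt(p_overall * (1.0 - p_overall))
    return StandardizedDifference(p2, p1, p_overall, float(d), classify_band(d))


def d_series(
    stratified: dict[str, CS3Series],
    pooled: CS3Series,
    comparisons: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], list[tuple[int, StandardizedDifference]]]:
    """Standardized differences over x for each level pair.

    For the pair (A, B) at each common x: p2 = A's conditional rate,
    p1 = B's, and P = the pooled cohort's conditional rate at the same x.
    """
    out: dict[tuple[str, str], list[tuple[int, StandardizedDifference]]] = {}
    for a, b in comparisons:
        if a not in stratified or b not in stratified:
            missing = a if a not in stratified else b
            raise KeyError(f"level {missing!r} absent from the stratified series")
        sa, sb = stratified[a], stratified[b]
        common = [
            x for x in pooled.x_years if x in sa.x_years and x in sb.x_years
        ]
        out[(a, b)] = [
            (
                x,
                standardized_difference(
                    sa.at(x) / 100.0, sb.at(x) / 100.0, pooled.at(x) / 100.0
                ),
            )
            for x in common
        ]
    return out
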