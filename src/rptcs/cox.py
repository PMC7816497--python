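"""Proportional-hazards modelling: univariable screens and multivariable
fits for OS and CSS.

Categorical covariates are dummy-coded against explicit reference levels
(the levels carrying implicit hazard ratio 1).  Partial-likelihood
maximization uses :class:`lifelines.CoxPHFitter` with Efron's tie
correction — registry times floored to whole months are heavily tied, and
Efron's approximation is markedly less biased than Breslow's there.
Intervals and p-values are Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from .records import CATEGORICAL_LEVELS, REFERENCE_LEVELS
from .survival import Endpoint, endpoint_durations_events

__all__ = [
    "CoxTerm",
    "CoxFit",
    "UnivariableResult",
    "fit_cox",
    "univariable_screen",
]

_BOOLEAN_COVARIATES = ("radiation", "chemotherapy", "chemoradiotherapy")


@dataclass(frozen=True)
class CoxTerm:
    covariate: str
    level: str
    reference_level: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class CoxFit:
    endpoint: Endpoint
    terms: list[CoxTerm]
    ties_method: str
    log_partial_likelihood: float
    n_events: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def term(self, covariate: str, level: str) -> CoxTerm:
        for t in self.terms:
            if t.covariate == covariate and t.level == level:
                return t
        raise KeyError(f"no term for {covariate}={level}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": t.covariate,
                    "level": t.level,
                    "reference": t.reference_level,
                    "hr": t.hr,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ]
        )


def _design_matrix(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: dict[str, str],
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Dummy-coded design; returns (X, [(covariate, level, reference)])."""
    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str, str]] = []
    for cov in covariates:
        values = cohort[cov]
        if cov in _BOOLEAN_COVARIATES or values.dtype == bool:
            flags = values.astype(bool)
            if flags.nunique() < 2:
                raise ValueError(
                    f"covariate {cov!r} is constant: zero-subject contrast"
                )
            cols[f"{cov}[yes]"] = flags.to_numpy(dtype=float)
            meta.append((cov, "yes", "no"))
            continue
        observed = [
            lv for lv in CATEGORICAL_LEVELS[cov] if (values == lv).any()
        ]
        if len(observed) < 2:
            raise ValueError(
                f"covariate {cov!r} is constant: zero-subject contrast"
            )
        ref = reference_levels.get(cov, observed[0])
        if ref not in observed:
            ref = observed[0]
        for lv in observed:
            if lv == ref:
                continue
            cols[f"{cov}[{lv}]"] = (values == lv).to_numpy(dtype=float)
            meta.append((cov, lv, ref))
    return pd.DataFrame(cols, index=cohort.index), meta


def fit_cox(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    endpoint: Endpoint = "OS",
    reference_levels: dict[str, str] | None = None,
) -> CoxFit:
    """Multivariable Cox fit for the given endpoint.

    Raises a diagnostic error on non-convergence; monotone-likelihood
    (separation) cases are fitted but flagged in ``warnings``.
    """
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    durations, events = endpoint_durations_events(cohort, endpoint)
    if events.sum() < 1:
        raise ValueError(f"no {endpoint} events in the cohort")
    X, meta = _design_matrix(cohort, covariates, refs)
    data = X.copy()
    data["__duration"] = durations
    data["__event"] = events.astype(int)

    cph = CoxPHFitter()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(data, duration_col="__duration", event_col="__event")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
        captured = [str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)]

    summary = cph.summary
    terms = []
    for (cov, level, ref), name in zip(meta, X.columns):
        row = summary.loc[name]
        terms.append(
            CoxTerm(
                covariate=cov,
                level=level,
                reference_level=ref,
                coef=float(row["coef"]),
                hr=float(np.exp(row["coef"])),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
            )
        )
    return CoxFit(
        endpoint=endpoint,
        terms=terms,
        ties_method="efron",
        log_partial_likelihood=float(cph.log_likelihood_),
        n_events=int(events.sum()),
        converged=not captured,
        warnings=captured,
    )


@dataclass
class UnivariableResult:
    covariate: str
    fit: CoxFit
    significant: bool  # any level with Wald p < alpha: carried forward


def univariable_screen(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    endpoint: Endpoint = "OS",
    alpha: float = 0.05,
    reference_levels: dict[str, str] | None = None,
) -> list[UnivariableResult]:
    """One single-covariate Cox fit per covariate, flagging p < alpha.

    The flag marks covariates carried forward into the multivariable model.
    """
    results = []
    for cov in covariates:
        fit = fit_cox(cohort, [cov], endpoint, reference_levels)
        results.append(
            UnivariableResult(
                covariate=cov,
                fit=fit,
                significant=any(t.p_value < alpha for t in fit.terms),
            )
        )
    return results
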