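"""Automated forward selection of parameter-covariate relationships.

Each candidate (parameter, covariate) pair is screened with three functional
forms on the log scale of the individual parameter estimates:

- linear:       P = theta1 * (1 + theta2 * (COV - COVmedian))
- power:        P = theta1 * (COV / COVmedian) ** theta2
- exponential:  P = theta1 * exp(theta2 * (COV - COVmedian))

Model comparison uses AIC = n * log(SS_res / n) + 2k on log-scale residual
sums of squares with unit weights (the log transform already variance-
stabilises).  Statistical significance of theta2 comes from a likelihood-
ratio-style test, Delta = n * ln(SS_base / SS_full) referred to chi-square
with 1 degree of freedom.  Per parameter, at most one relation is kept: the
lowest-AIC form among those with p < alpha and a negative AIC change; ties
resolve simplest-first (linear < power < exponential).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .estimation import PopulationResult
from .exceptions import InvalidInputError

logger = logging.getLogger("poppk")

__all__ = [
    "CovariateRelation",
    "SelectionResult",
    "aic",
    "fit_relation",
    "forward_select",
]

_FORM_ORDER = {"linear": 0, "power": 1, "exponential": 2}


def aic(n: int, ss_res: float, k: int) -> float:
    """Akaike information criterion, ``n * log(SS_res / n) + 2k``.

    A perfect fit (``ss_res == 0``) returns a negative-infinity sentinel with
    a logged warning.
    """
    if n <= 0 or k < 0 or ss_res < 0:
        raise InvalidInputError("aic requires n > 0, ss_res >= 0, k >= 0")
    if ss_res == 0:
        logger.warning("aic: zero residual sum of squares; returning -inf")
        return -np.inf
    return float(n * np.log(ss_res / n) + 2 * k)


@dataclass
class CovariateRelation:
    """One screened parameter-covariate relation with its statistics."""

    parameter: str
    covariate: str
    form: str
    theta1: float
    theta2: float
    reference: float
    p_value: float
    delta_aic: float
    ss_res: float = np.nan
    testable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SelectionResult:
    """Outcome of forward selection: at most one relation per parameter."""

    selected: list[CovariateRelation]
    screened: list[CovariateRelation]
    alpha: float

    def selected_for(self, parameter: str) -> CovariateRelation | None:
        for rel in self.selected:
            if rel.parameter == parameter:
                return rel
        return None

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "selected": [r.to_dict() for r in self.selected],
            "screened": [r.to_dict() for r in self.screened],
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fit_linear_form(y: np.ndarray, delta: np.ndarray) -> tuple[float, float, float]:
    """Least squares for log P = log(theta1 * (1 + theta2*delta)).

    Nonlinear in theta2; run Nelder-Mead from several theta2 seeds with an
    infinite barrier where 1 + theta2*delta <= 0.
    """
    ybar = float(y.mean())

    def sse(x):
        log_t1, t2 = x
        arg = 1.0 + t2 * delta
        if np.any(arg <= 0):
            return np.inf
        r = y - log_t1 - np.log(arg)
        return float(r @ r)

    # seed theta2 from the exponential-form OLS slope (local equivalence)
    denom = float(delta @ delta)
    seed = float(delta @ (y - ybar)) / denom if denom > 0 else 0.0
    lim = 1.0 / max(np.max(np.abs(delta)), 1e-12)
    best = None
    for t2_0 in {0.0, np.clip(seed, -0.9 * lim, 0.9 * lim)}:
        res = minimize(
            sse,
            np.array([ybar, t2_0]),
            method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-14, maxiter=5000),
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(np.exp(best.x[0])), float(best.x[1]), float(best.fun)


def fit_relation(
    individual_params: Sequence[float],
    covariate_values: Sequence[float],
    form: str,
    parameter: str = "p",
    covariate: str = "cov",
    reference: float | None = None,
) -> CovariateRelation:
    """Least-squares fit of one relation form on the log-parameter scale,
    with a chi-square(1) likelihood-ratio p-value for theta2 = 0.

    A degenerate covariate (zero variance, or all values equal to the
    reference) yields a not-testable result with ``p_value = 1``.
    """
    p = np.asarray(individual_params, float)
    c = np.asarray(covariate_values, float)
    if p.size != c.size or p.size < 4:
        raise InvalidInputError("need >= 4 paired subjects")
    if np.any(p <= 0):
        raise InvalidInputError("parameter values must be positive")
    if form not in _FORM_ORDER:
        raise InvalidInputError(f"unknown form {form!r}")
    n = p.size
    ref = float(np.median(c)) if reference is None else float(reference)
    y = np.log(p)
    ss_base = float(np.sum((y - y.mean()) ** 2))
    not_testable = CovariateRelation(
        parameter, covariate, form,
        theta1=float(np.exp(y.mean())), theta2=0.0, reference=ref,
        p_value=1.0, delta_aic=2.0, ss_res=ss_base, testable=False,
    )
    if np.ptp(c) == 0:
        return not_testable
    if form == "power":
        if ref <= 0 or np.any(c <= 0):
            return not_testable
        x = np.log(c / ref)
    elif form == "exponential":
        x = c - ref
    else:
        x = None
    if form in ("power", "exponential"):
        denom = float(np.sum((x - x.mean()) ** 2))
        if denom == 0:
            return not_testable
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / denom)
        intercept = float(y.mean() - slope * x.mean())
        resid = y - intercept - slope * x
        ss_full = float(resid @ resid)
        theta1, theta2 = float(np.exp(intercept)), slope
    else:
        theta1, theta2, ss_full = _fit_linear_form(y, c - ref)
    if ss_full <= 0:
        p_value = 0.0
    else:
        delta = n * np.log(ss_base / ss_full) if ss_base > 0 else 0.0
        p_value = float(stats.chi2.sf(max(delta, 0.0), df=1))
    delta_aic = aic(n, ss_full, 2) - aic(n, ss_base, 1)
    return CovariateRelation(
        parameter, covariate, form, theta1, theta2, ref,
        p_value=p_value, delta_aic=float(delta_aic), ss_res=ss_full,
    )


def forward_select(
    pop: PopulationResult,
    covariate_table: pd.DataFrame | None = None,
    candidates: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> SelectionResult:
    """Screen candidate (parameter, covariate) pairs over all three forms and
    keep, per parameter, the single best relation by lowest AIC among those
    significant at ``alpha`` with ``delta_aic < 0``.

    ``covariate_table`` defaults to the covariates carried by the converged
    subjects; ``candidates`` defaults to every estimated parameter crossed
    with every numeric covariate.
    """
    fits = pop.converged_fits
    if len(fits) < 4:
        raise InvalidInputError("forward selection needs >= 4 converged fits")
    if covariate_table is None:
        covariate_table = pd.DataFrame(
            [f.subject.covariates for f in fits],
            index=[f.subject_id for f in fits],
        )
    numeric = covariate_table.select_dtypes("number")
    names = pop.parameter_names
    if candidates is None:
        candidates = [(p, c) for p in names for c in numeric.columns]
    est = {
        p: np.array([getattr(f.estimates, p) for f in fits]) for p in names
    }
    screened: list[CovariateRelation] = []
    for param, cov in candidates:
        if param not in est or cov not in numeric.columns:
            raise InvalidInputError(f"unknown candidate pair ({param}, {cov})")
        values = numeric[cov].to_numpy(float)
        for form in ("linear", "power", "exponential"):
            screened.append(
                fit_relation(est[param], values, form, parameter=param, covariate=cov)
            )
    selected = []
    for param in names:
        eligible = [
            r
            for r in screened
            if r.parameter == param
            and r.testable
            and r.p_value < alpha
            and r.delta_aic < 0
        ]
        if eligible:
            eligible.sort(key=lambda r: (r.delta_aic, _FORM_ORDER[r.form]))
            selected.append(eligible[0])
    return SelectionResult(selected=selected, screened=screened, alpha=alpha)
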