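"""Individual maximum-likelihood fitting and two-stage population summary.

Stage one fits each subject separately by minimising a log-scale weighted
sum of squared residuals over log-transformed parameters (positivity by
construction),

.. math::

    O(\\theta) = \\sum_i \\frac{(\\log C_{obs,i} - \\log C_{pred,i})^2}{\\sigma^2}
                + \\text{penalty},

with a smooth quadratic penalty outside the parameter bounds.  Initial
estimates come from data-driven heuristics expanded over a grid of scale
factors with small log-normal perturbations; optimisation uses Nelder-Mead
with automatic fallback to Powell's method, advancing to the next starting
point on failure.

Stage two summarises converged individual estimates: population typical
values are geometric means, between-subject variability is the CV% implied
by the unbiased variance of log-estimates, and the residual error is
re-estimated post hoc from pooled log-residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data import SubjectRecord
from .exceptions import (
    PopulationEstimationError,
    UnfittableSubjectError,
)
from .pk_models import (
    FAST_DISPATCH,
    DoseRegimen,
    ModelKind,
    PKParameters,
    predict_conc,
)

logger = logging.getLogger("poppk")

__all__ = [
    "ErrorModel",
    "FitSettings",
    "IndividualFit",
    "PopulationResult",
    "objective",
    "initial_estimates",
    "fit_individual",
    "fit_population",
    "estimate_population",
    "handle_blq",
]

#: concentrations at or below this floor are excluded from the log-likelihood
CONC_FLOOR = 1e-10

#: cap applied to the heuristic absorption-rate starting value (1/h)
KA_INIT_RANGE = (0.05, 20.0)


@dataclass(frozen=True)
class ErrorModel:
    """Combined proportional + additive residual error model.

    ``prop_sd`` is the proportional residual SD (fraction of the prediction),
    the primary component; ``add_sd`` is an additive SD in mg/L used for low
    concentrations.  During individual fitting only the relative weighting
    matters, so a unit sigma is used when ``prop_sd`` is zero.
    """

    prop_sd: float = 0.1
    add_sd: float = 0.0

    def __post_init__(self):
        if self.prop_sd < 0 or self.add_sd < 0:
            raise ValueError("error SDs must be non-negative")

    @property
    def weighting_sd(self) -> float:
        return self.prop_sd if self.prop_sd > 0 else 1.0


@dataclass(frozen=True)
class FitSettings:
    """Tuning knobs of the automated fitting strategy.

    The defaults implement the automated initialisation strategy: heuristic
    base estimates scaled by ``scale_factors``, each perturbed multiplicatively
    by ``exp(N(0, perturb_sd^2))`` per parameter.  ``bound_span`` sets the
    default per-parameter bounds ``[base/span, base*span]`` around the
    heuristic base estimate.
    """

    scale_factors: tuple[float, ...] = (0.1, 0.5, 1.0, 1.5, 2.0)
    perturb_sd: float = 0.1
    max_iter: int = 9999
    bounds: dict[str, tuple[float, float]] | None = None
    bound_span: float = 50.0
    penalty_weight: float = 1e4
    xatol: float = 1e-8
    fatol: float = 1e-12
    initial_estimates: PKParameters | None = None


@dataclass
class IndividualFit:
    """Outcome of one subject's fit."""

    subject_id: str
    estimates: PKParameters | None
    objective: float
    converged: bool
    n_attempts: int
    method_used: str | None
    r2: float
    subject: SubjectRecord | None = None
    bounds: dict[str, tuple[float, float]] | None = None

    def predictions(self, kind: ModelKind) -> np.ndarray:
        """Model predictions at the subject's sampling times."""
        return predict_conc(self.estimates, self.subject.dose, self.subject.times, kind)


@dataclass
class PopulationResult:
    """Two-stage population summary over converged individual fits."""

    kind: ModelKind
    typical: PKParameters
    omega_cv: dict[str, float]
    log_cov: np.ndarray
    resid: ErrorModel
    fits: list[IndividualFit]
    success_rate: float

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.kind.parameter_names

    @property
    def converged_fits(self) -> list[IndividualFit]:
        return [f for f in self.fits if f.converged]

    @property
    def n_subjects(self) -> int:
        return len(self.fits)


def _usable_mask(subject: SubjectRecord) -> np.ndarray:
    # blq flags are provenance (e.g. half-lloq imputation), not an exclusion:
    # only values at/below the positivity floor leave the log-likelihood
    return subject.concentrations > CONC_FLOOR


def objective(
    params: PKParameters,
    subject: SubjectRecord,
    model: ModelKind,
    error: ErrorModel | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    penalty_weight: float = 1e4,
) -> float:
    """Weighted log-scale SSR plus a smooth out-of-bounds penalty.

    Observations at or below the concentration floor are excluded.  Sigma
    enters only as a relative weight, so the argmin is invariant to its
    scale.
    """
    mask = _usable_mask(subject)
    if not mask.any():
        raise UnfittableSubjectError(
            f"subject {subject.subject_id}: no quantifiable observations"
        )
    sigma = (error or ErrorModel(prop_sd=0.0)).weighting_sd
    pred = predict_conc(params, subject.dose, subject.times[mask], model)
    pred = np.clip(pred, 1e-12, None)
    resid = np.log(subject.concentrations[mask]) - np.log(pred)
    value = float(np.sum(resid * resid) / sigma**2)
    if bounds:
        for name, (lo, hi) in bounds.items():
            x = getattr(params, name)
            if x is None:
                continue
            if x < lo:
                value += penalty_weight * np.log(lo / x) ** 2
            elif x > hi:
                value += penalty_weight * np.log(x / hi) ** 2
    return value


def _terminal_slope(times: np.ndarray, concs: np.ndarray) -> float | None:
    """Log-linear slope magnitude of the last three quantifiable points."""
    if times.size < 3:
        return None
    t, c = times[-3:], concs[-3:]
    if np.ptp(t) <= 0:
        return None
    slope = np.polyfit(t, np.log(c), 1)[0]
    return -slope if slope < 0 else None


def base_estimate(subject: SubjectRecord, model: ModelKind) -> PKParameters:
    """Data-driven heuristic base estimate.

    V (central volume) from Dose/Cmax for IV or Dose/(2*Cmax) for oral;
    lambda_z from a log-linear regression on the last three quantifiable
    points; CL = lambda_z * V for one-compartment models and Dose/AUC
    (trapezoid with lambda_z tail) for two-compartment models, where the
    terminal slope reflects only the slow disposition phase; Ka = 4*lambda_z
    capped to [0.05, 20] 1/h.  Order-of-magnitude correctness is all the
    scale grid requires.
    """
    mask = _usable_mask(subject)
    if mask.sum() < 3:
        raise UnfittableSubjectError(
            f"subject {subject.subject_id}: fewer than 3 quantifiable observations"
        )
    order = np.argsort(subject.times[mask], kind="stable")
    t = subject.times[mask][order]
    c = subject.concentrations[mask][order]
    dose = subject.dose.amount
    cmax = float(c.max())
    lz = _terminal_slope(t, c)
    if lz is None or not np.isfinite(lz) or lz <= 0:
        # fall back to a half-life of ~30% of the observation span
        lz = np.log(2.0) / max(0.3 * float(t[-1]), 1e-3)
    v0 = dose / cmax if not model.has_absorption else dose / (2.0 * cmax)
    if model.is_twocomp:
        auc = float(np.trapezoid(c, t)) + float(c[-1]) / lz
        cl0 = dose / auc
        kwargs = dict(cl=cl0, v=v0, v2=v0, q=cl0)
    else:
        kwargs = dict(cl=lz * v0, v=v0)
    if model.has_absorption:
        if model.is_twocomp:
            # terminal slope reflects beta, far below the absorption rate;
            # seed Ka from the observed peak time instead so the start sits
            # in the ka > alpha basin (avoids the exact flip-flop twin of
            # the triexponential in which ka and alpha exchange roles)
            tmax = float(t[int(np.argmax(c))])
            ka0 = 4.0 / max(tmax, 1e-3)
        else:
            ka0 = 4.0 * lz
        kwargs["ka"] = float(np.clip(ka0, *KA_INIT_RANGE))
    return PKParameters(**kwargs)


def initial_estimates(
    subject: SubjectRecord,
    model: ModelKind,
    settings: FitSettings | None = None,
    seed=None,
) -> list[PKParameters]:
    """Ordered list of starting points: base heuristic (or user-supplied
    estimate) times each scale factor, each perturbed multiplicatively by
    ``exp(N(0, perturb_sd^2))`` per parameter.  Deterministic under a fixed
    seed."""
    settings = settings or FitSettings()
    base = settings.initial_estimates or base_estimate(subject, model)
    base.validate_for(model)
    rng = np.random.default_rng(seed)
    names = model.parameter_names
    starts = []
    for factor in settings.scale_factors:
        scaled = base.to_array(model) * factor
        perturb = np.exp(rng.normal(0.0, settings.perturb_sd, size=len(names)))
        starts.append(PKParameters.from_array(scaled * perturb, model))
    return starts


def default_bounds(base: PKParameters, model: ModelKind, span: float) -> dict:
    arr = base.to_array(model)
    return {
        name: (val / span, val * span)
        for name, val in zip(model.parameter_names, arr)
    }


def _interior(params: PKParameters, bounds: dict, rel: float = 1e-6) -> bool:
    for name, (lo, hi) in bounds.items():
        x = getattr(params, name)
        if x is None or not np.isfinite(x):
            return False
        if x <= lo * (1 + rel) or x >= hi * (1 - rel):
            return False
    return True


def _r_squared(subject: SubjectRecord, params: PKParameters, model: ModelKind) -> float:
    mask = _usable_mask(subject)
    obs = subject.concentrations[mask]
    pred = predict_conc(params, subject.dose, subject.times[mask], model)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        return np.nan
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def fit_individual(
    subject: SubjectRecord,
    model: ModelKind,
    settings: FitSettings | None = None,
    error: ErrorModel | None = None,
    seed=None,
) -> IndividualFit:
    """Fit one subject with automated multi-start initialisation and
    optimizer fallback.

    Optimisation runs over log-parameters.  Starting points are tried in
    ascending order of their initial objective value (non-finite starts are
    recorded as consumed attempts); each is optimised with Nelder-Mead and,
    if that fails to converge, Powell.  The first converged attempt is
    returned.  Total failure yields ``converged=False`` with a logged
    warning, never an exception.
    """
    settings = settings or FitSettings()
    model = ModelKind(model)
    failure = IndividualFit(
        subject_id=subject.subject_id,
        estimates=None,
        objective=np.inf,
        converged=False,
        n_attempts=0,
        method_used=None,
        r2=np.nan,
        subject=subject,
    )
    try:
        base = settings.initial_estimates or base_estimate(subject, model)
        starts = initial_estimates(subject, model, settings, seed)
    except UnfittableSubjectError as exc:
        logger.warning("fit skipped: %s", exc)
        return failure
    bounds = settings.bounds or default_bounds(base, model, settings.bound_span)
    failure.bounds = bounds

    # hot-path closure over precomputed arrays; numerically identical to
    # objective() (log-distance penalty == natural-scale log ratio)
    mask = _usable_mask(subject)
    t_used = subject.times[mask]
    log_obs = np.log(subject.concentrations[mask])
    dose_amt = subject.dose.amount
    sigma2 = ((error or ErrorModel(prop_sd=0.0)).weighting_sd) ** 2
    names = model.parameter_names
    log_lo = np.log([bounds[n][0] for n in names])
    log_hi = np.log([bounds[n][1] for n in names])
    fast = FAST_DISPATCH[model]
    weight = settings.penalty_weight

    n_par = len(names)

    def fun(log_x: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            x = np.exp(log_x)
            if not np.all(np.isfinite(x)):
                return np.inf
            try:
                conc = fast(x, dose_amt, t_used)
            except Exception:
                return np.inf
            resid = log_obs - np.log(np.maximum(conc, 1e-12))
            val = float(resid @ resid) / sigma2
        pen = 0.0
        for j in range(n_par):
            d = log_x[j] - log_hi[j]
            if d > 0.0:
                pen += d * d
            d = log_lo[j] - log_x[j]
            if d > 0.0:
                pen += d * d
        val += weight * pen
        return val if np.isfinite(val) else np.inf

    start_objs = []
    for p in starts:
        try:
            start_objs.append(
                objective(p, subject, model, error, bounds, settings.penalty_weight)
            )
        except Exception:
            start_objs.append(np.nan)
    start_objs = np.asarray(start_objs, float)
    invalid = ~np.isfinite(start_objs)
    n_attempts = int(invalid.sum())  # non-finite starts count as consumed
    order = np.argsort(np.where(invalid, np.inf, start_objs), kind="stable")

    best = failure
    for idx in order:
        if invalid[idx]:
            continue
        x0 = np.log(starts[idx].to_array(model))
        n_attempts += 1
        for method, options in (
            (
                "nelder_mead",
                dict(
                    xatol=settings.xatol,
                    fatol=settings.fatol,
                    maxiter=settings.max_iter,
                    maxfev=settings.max_iter,
                ),
            ),
            ("powell", dict(xtol=1e-10, ftol=1e-12, maxiter=settings.max_iter)),
        ):
            scipy_name = "Nelder-Mead" if method == "nelder_mead" else "Powell"
            try:
                res = minimize(fun, x0, method=scipy_name, options=options)
            except Exception as exc:  # optimizer blow-up: treat as failed attempt
                logger.warning(
                    "subject %s: %s raised %s", subject.subject_id, scipy_name, exc
                )
                continue
            params = PKParameters.from_array(np.exp(res.x), model)
            ok = (
                bool(res.success)
                and np.isfinite(res.fun)
                and _interior(params, bounds)
            )
            if ok:
                return IndividualFit(
                    subject_id=subject.subject_id,
                    estimates=params,
                    objective=float(res.fun),
                    converged=True,
                    n_attempts=n_attempts,
                    method_used=method,
                    r2=_r_squared(subject, params, model),
                    subject=subject,
                    bounds=bounds,
                )
            if np.isfinite(res.fun) and res.fun < best.objective:
                best = replace(
                    failure,
                    estimates=params,
                    objective=float(res.fun),
                    method_used=method,
                    n_attempts=n_attempts,
                )
    logger.warning(
        "subject %s: no starting point converged (%d attempts)",
        subject.subject_id,
        n_attempts,
    )
    best.n_attempts = n_attempts
    return best


def fit_population(
    subjects: Sequence[SubjectRecord],
    model: ModelKind,
    settings: FitSettings | None = None,
    error: ErrorModel | None = None,
    seed=None,
) -> list[IndividualFit]:
    """Fit every subject, deriving per-subject seeds from ``seed`` via a
    counter-based spawn for exact reproducibility."""
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(len(subjects))
    return [
        fit_individual(s, model, settings, error, child)
        for s, child in zip(subjects, children)
    ]


def estimate_population(
    fits: Sequence[IndividualFit], model: ModelKind
) -> PopulationResult:
    """Second stage: geometric-mean typical values and log-scale variability
    over converged fits.

    ``omega_cv = 100 * sqrt(exp(var_log) - 1)`` with the unbiased variance of
    log-estimates; the residual proportional SD is the RMS of pooled
    log-residuals of the converged fits.
    """
    model = ModelKind(model)
    converged = [f for f in fits if f.converged]
    if len(converged) < 2:
        raise PopulationEstimationError(
            f"need >=2 converged fits, got {len(converged)}"
        )
    names = model.parameter_names
    log_mat = np.log([f.estimates.to_array(model) for f in converged])
    typical = PKParameters.from_array(np.exp(log_mat.mean(axis=0)), model)
    var_log = log_mat.var(axis=0, ddof=1)
    omega_cv = {
        n: 100.0 * float(np.sqrt(np.expm1(v))) for n, v in zip(names, var_log)
    }
    log_cov = np.cov(log_mat, rowvar=False, ddof=1)
    pooled = []
    for f in converged:
        if f.subject is None:
            continue
        mask = _usable_mask(f.subject)
        pred = np.clip(f.predictions(model)[mask], 1e-12, None)
        pooled.append(np.log(f.subject.concentrations[mask]) - np.log(pred))
    pooled = np.concatenate(pooled) if pooled else np.array([0.0])
    resid = ErrorModel(prop_sd=float(np.sqrt(np.mean(pooled**2))), add_sd=0.0)
    return PopulationResult(
        kind=model,
        typical=typical,
        omega_cv=omega_cv,
        log_cov=np.atleast_2d(log_cov),
        resid=resid,
        fits=list(fits),
        success_rate=len(converged) / len(fits),
    )


def handle_blq(
    subject: SubjectRecord, lloq: float, policy: str = "drop"
) -> SubjectRecord:
    """Flag observations below the limit of quantification and apply a policy.

    ``drop`` removes flagged rows; ``half_lloq`` replaces their value with
    ``lloq/2``.  ``lloq=0`` leaves the record unchanged.  An empty result is
    allowed (callers treat it as an unfittable subject).
    """
    if lloq < 0:
        raise ValueError("lloq must be non-negative")
    if policy not in ("drop", "half_lloq"):
        raise ValueError(f"unknown BLQ policy {policy!r}")
    below = subject.concentrations < lloq
    if not below.any():
        return replace(subject)
    if policy == "drop":
        keep = ~below
        return subject.with_observations(
            subject.times[keep],
            subject.concentrations[keep],
            subject.blq_flags[keep],
        )
    concs = subject.concentrations.copy()
    concs[below] = lloq / 2.0
    flags = subject.blq_flags | below
    return subject.with_observations(subject.times, concs, flags)
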