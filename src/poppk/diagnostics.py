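"""Model-evaluation metrics and simulation-study metric battery.

Fold errors follow the geometric-mean formulation:

- ``AFE  = exp(mean(log(predicted/observed)))`` -- systematic bias
  (AFE > 1: overprediction);
- ``AAFE = exp(mean(|log(predicted/observed)|))`` -- overall accuracy
  regardless of direction (AAFE < 1.5 excellent, < 2.0 good).

Also provided: concentration-scale R^2/RMSE/MAE, visual predictive checks
by Monte-Carlo simulation from a fitted population, eta-shrinkage adapted
to two-stage output, the parameter-correlation condition number, and the
replicate-level study metrics (relative bias %, RMSE, CV%, recovery rate,
covariate detection rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariate_analysis import SelectionResult
from .estimation import PopulationResult, _usable_mask
from .exceptions import UndefinedMetricError
from .pk_models import DoseRegimen, ModelKind, PKParameters, predict_conc
from .simulation import ScenarioSpec

logger = logging.getLogger("poppk")

__all__ = [
    "FitMetrics",
    "StudyMetrics",
    "fold_errors",
    "fit_metrics",
    "study_metrics",
    "vpc",
    "VPCResult",
    "shrinkage_and_condition",
    "observed_vs_predicted",
]


def fold_errors(predicted, observed) -> tuple[float, float]:
    """(AFE, AAFE) over positive prediction/observation pairs.

    Pairs with a non-positive member are excluded with a warning; no valid
    pairs raises :class:`UndefinedMetricError`.
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape:
        raise UndefinedMetricError("predicted/observed length mismatch")
    valid = (pred > 0) & (obs > 0)
    if not valid.all():
        logger.warning(
            "fold_errors: excluded %d pair(s) with non-positive values",
            int((~valid).sum()),
        )
    if not valid.any():
        raise UndefinedMetricError("no positive prediction/observation pairs")
    ratios = np.log(pred[valid] / obs[valid])
    return float(np.exp(ratios.mean())), float(np.exp(np.abs(ratios).mean()))


@dataclass
class FitMetrics:
    """Goodness-of-fit summary on the concentration scale plus fold errors."""

    r2: float
    rmse: float
    mae: float
    mean_residual: float
    afe: float
    aafe: float

    def to_dict(self) -> dict:
        return asdict(self)


def fit_metrics(predicted, observed) -> FitMetrics:
    """R^2, RMSE, MAE and mean residual on the observed (concentration)
    scale, with residual = observed - predicted, plus AFE/AAFE."""
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or obs.size < 2:
        raise UndefinedMetricError("need >= 2 paired predictions/observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        raise UndefinedMetricError("observed values have zero variance")
    resid = obs - pred
    afe, aafe = fold_errors(pred, obs)
    return FitMetrics(
        r2=1.0 - float(np.sum(resid**2)) / ss_tot,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        mean_residual=float(np.mean(resid)),
        afe=afe,
        aafe=aafe,
    )


@dataclass
class StudyMetrics:
    """Replicate-level metrics of a simulation-study cell."""

    parameters: dict[str, dict[str, float]]
    mean_r2: float
    detection: dict[str, float]
    n_replicates: int
    estimates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.parameters).T


#: recovery counts replicate estimates within +/-20% of truth, inclusive
RECOVERY_BAND = 0.20


def study_metrics(
    replicates: Sequence[PopulationResult],
    truth: ScenarioSpec,
    selections: Sequence[SelectionResult] | None = None,
) -> StudyMetrics:
    """Accuracy/precision metrics across replicate population estimates.

    Per parameter over replicate typical values: relative bias
    ``100*(mean(est)-true)/true``, RMSE on the natural scale,
    ``CV% = 100*sd/mean``, and the recovery rate (share within +/-20% of
    truth, boundary inclusive).  ``mean_r2`` averages per-subject fit R^2
    within each replicate, then across replicates.  Detection rates require
    the selected relation to match the true covariate and functional form.
    """
    if len(replicates) < 2:
        raise UndefinedMetricError("need >= 2 replicates")
    names = truth.model.parameter_names
    params: dict[str, dict[str, float]] = {}
    estimates: dict[str, np.ndarray] = {}
    for name in names:
        true_val = getattr(truth.true_params, name)
        est = np.array([getattr(r.typical, name) for r in replicates], float)
        estimates[name] = est
        within = np.abs(est - true_val) <= RECOVERY_BAND * true_val + 1e-12
        params[name] = {
            "bias_pct": 100.0 * float((est.mean() - true_val) / true_val),
            "rmse": float(np.sqrt(np.mean((est - true_val) ** 2))),
            "cv_pct": 100.0 * float(est.std(ddof=1) / est.mean()),
            "recovery_pct": 100.0 * float(within.mean()),
        }
    rep_r2 = []
    for r in replicates:
        vals = [f.r2 for f in r.converged_fits if np.isfinite(f.r2)]
        if vals:
            rep_r2.append(float(np.mean(vals)))
    mean_r2 = float(np.mean(rep_r2)) if rep_r2 else np.nan
    detection: dict[str, float] = {}
    if selections is not None:
        for eff in truth.effects:
            hits = []
            for sel in selections:
                rel = sel.selected_for(eff.parameter)
                hits.append(
                    rel is not None
                    and rel.covariate == eff.covariate
                    and rel.form == eff.form
                )
            key = f"{eff.parameter}~{eff.covariate}"
            detection[key] = 100.0 * float(np.mean(hits))
    return StudyMetrics(
        parameters=params,
        mean_r2=mean_r2,
        detection=detection,
        n_replicates=len(replicates),
        estimates=estimates,
    )


@dataclass
class VPCResult:
    """Percentile bands of a visual predictive check."""

    times: np.ndarray
    simulated: dict[float, np.ndarray]  # percentile -> band over times
    observed: dict[float, np.ndarray]
    n_sim: int

    def bands_frame(self) -> pd.DataFrame:
        data = {"TIME": self.times}
        for pct, band in self.simulated.items():
            data[f"SIM_P{pct:g}"] = band
        for pct, band in self.observed.items():
            data[f"OBS_P{pct:g}"] = band
        return pd.DataFrame(data)


def vpc(
    pop: PopulationResult,
    schedule=None,
    dose: DoseRegimen | None = None,
    n_sim: int = 1000,
    seed=None,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual predictive check via Monte-Carlo simulation.

    Simulates ``n_sim`` populations of the original size from the estimated
    typical values, the log-scale covariance of individual estimates, and the
    residual error model, then reports simulated percentile bands per
    scheduled timepoint alongside the observed percentiles.  Deterministic
    under a fixed seed.
    """
    fits = pop.converged_fits
    subjects = [f.subject for f in fits]
    if schedule is None:
        schedule = subjects[0].times
    times = np.asarray(schedule, float)
    if dose is None:
        dose = subjects[0].dose
    rng = np.random.default_rng(seed)
    names = pop.parameter_names
    mu = np.log(pop.typical.to_array(pop.kind))
    cov = np.atleast_2d(pop.log_cov)
    # guard semidefiniteness against roundoff
    w, v = np.linalg.eigh(cov)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    n_subj = len(subjects)
    sims = np.empty((n_sim * n_subj, times.size))
    row = 0
    for _ in range(n_sim):
        z = rng.standard_normal((n_subj, len(names)))
        log_ind = mu + z @ chol.T
        for k in range(n_subj):
            params = PKParameters.from_array(np.exp(log_ind[k]), pop.kind)
            conc = predict_conc(params, dose, times, pop.kind)
            noisy = conc * (1.0 + rng.standard_normal(times.size) * pop.resid.prop_sd)
            if pop.resid.add_sd > 0:
                noisy = noisy + rng.standard_normal(times.size) * pop.resid.add_sd
            sims[row] = np.clip(noisy, 0.0, None)
            row += 1
    simulated = {p: np.percentile(sims, p, axis=0) for p in percentiles}
    observed: dict[float, np.ndarray] = {}
    obs_mat = []
    for subj in subjects:
        vals = np.full(times.size, np.nan)
        for j, t in enumerate(times):
            hit = np.isclose(subj.times, t)
            if hit.any():
                vals[j] = subj.concentrations[hit][0]
        obs_mat.append(vals)
    obs_mat = np.asarray(obs_mat)
    with np.errstate(all="ignore"):
        for p in percentiles:
            observed[p] = np.nanpercentile(obs_mat, p, axis=0)
    return VPCResult(times=times, simulated=simulated, observed=observed, n_sim=n_sim)


def shrinkage_and_condition(
    pop: PopulationResult,
    external_omega_cv: Mapping[str, float] | None = None,
) -> tuple[dict[str, float], float]:
    """Eta-shrinkage (adapted to two-stage output) and the condition number
    of the correlation matrix of log individual estimates.

    ``shrinkage_p = 100 * (1 - sd(log individual estimates of p) / omega_p)``
    with omega expressed as a log-scale SD.  Against the population's own
    omega this is ~0 by construction (a known two-stage limitation); pass
    ``external_omega_cv`` (CV%) to assess shrinkage against an external
    variability estimate.  A singular correlation matrix returns an infinite
    condition number with a warning; zero omega yields NaN shrinkage with a
    warning.
    """
    fits = pop.converged_fits
    if len(fits) < 3:
        raise UndefinedMetricError("need >= 3 converged fits")
    names = pop.parameter_names
    log_mat = np.log([f.estimates.to_array(pop.kind) for f in fits])
    sd_log = log_mat.std(axis=0, ddof=1)
    omega_cv = external_omega_cv if external_omega_cv is not None else pop.omega_cv
    shrinkage: dict[str, float] = {}
    for j, name in enumerate(names):
        cv = omega_cv.get(name, 0.0) / 100.0
        omega_sd = np.sqrt(np.log1p(cv**2))
        if omega_sd <= 0:
            logger.warning("shrinkage undefined for %s: zero omega", name)
            shrinkage[name] = np.nan
        else:
            shrinkage[name] = 100.0 * (1.0 - float(sd_log[j] / omega_sd))
    with np.errstate(all="ignore"):
        corr = np.corrcoef(log_mat, rowvar=False)
    corr = np.atleast_2d(corr)
    eig = np.linalg.eigvalsh(corr)
    if eig[0] <= max(1e-12 * eig[-1], 0.0):
        logger.warning("singular correlation matrix: condition number -> inf")
        cond = np.inf
    else:
        cond = float(eig[-1] / eig[0])
    return shrinkage, cond


def observed_vs_predicted(pop: PopulationResult) -> pd.DataFrame:
    """Pooled per-observation table of individual-fit predictions (plot data)."""
    rows = []
    for f in pop.converged_fits:
        mask = _usable_mask(f.subject)
        pred = f.predictions(pop.kind)[mask]
        obs = f.subject.concentrations[mask]
        t = f.subject.times[mask]
        for ti, oi, pi in zip(t, obs, pred):
            rows.append(
                {"ID": f.subject_id, "TIME": ti, "OBS": oi, "PRED": pi,
                 "RESID": oi - pi}
            )
    return pd.DataFrame(rows)
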