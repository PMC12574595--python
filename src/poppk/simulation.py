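"""Monte-Carlo virtual-population generator.

Implements the four built-in validation scenarios (one- and two-compartment
models, each with and without first-order absorption), demographic covariate
sampling, multiplicative covariate effects on typical parameters, log-normal
between-subject variability, and combined proportional + additive residual
noise.

Covariate distributions emulate a general adult clinical cohort: body weight
WT ~ truncated normal(70, 15^2) on [40, 120] kg, age AGE ~ uniform(20, 80)
years, creatinine clearance CRCL ~ truncated normal(100, 25^2) on
[30, 160] mL/min.  Reference values for covariate effects default to the
sampled cohort's median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectRecord
from .estimation import ErrorModel
from .exceptions import InvalidEffectError, InvalidInputError
from .pk_models import DoseRegimen, ModelKind, PKParameters, predict_conc

__all__ = [
    "CovariateEffect",
    "ScenarioSpec",
    "VirtualPopulation",
    "builtin_scenarios",
    "sample_covariates",
    "apply_covariate_effects",
    "simulate_population",
]


@dataclass(frozen=True)
class CovariateEffect:
    """A single parameter-covariate relation used in simulation truth.

    ``form`` is one of ``linear`` (theta1*(1 + theta2*(COV-ref))), ``power``
    (theta1*(COV/ref)^theta2) or ``exponential`` (theta1*exp(theta2*(COV-ref))).
    ``reference`` defaults to the sampled cohort median when None.
    """

    parameter: str
    covariate: str
    form: str
    coefficient: float
    reference: float | None = None

    def __post_init__(self):
        if self.form not in ("linear", "power", "exponential"):
            raise InvalidInputError(f"unknown covariate form {self.form!r}")

    def apply(self, value: float, covariate_value: float, reference: float) -> float:
        if self.form == "linear":
            out = value * (1.0 + self.coefficient * (covariate_value - reference))
        elif self.form == "power":
            if reference <= 0:
                raise InvalidEffectError("power form requires positive reference")
            out = value * (covariate_value / reference) ** self.coefficient
        else:
            out = value * np.exp(self.coefficient * (covariate_value - reference))
        if not np.isfinite(out) or out <= 0:
            raise InvalidEffectError(
                f"effect {self.parameter}~{self.covariate} ({self.form}) produced "
                f"non-positive value {out!r}"
            )
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation-study scenario: structural model, design and truth."""

    name: str
    model: ModelKind
    n_subjects: int
    dose: DoseRegimen
    schedule: tuple[float, ...]
    iiv_cv: Mapping[str, float]
    effects: tuple[CovariateEffect, ...]
    resid: ErrorModel
    true_params: PKParameters

    def __post_init__(self):
        sched = np.asarray(self.schedule, float)
        if np.any(np.diff(sched) <= 0) or np.any(sched < 0):
            raise InvalidInputError("schedule must be strictly increasing and >= 0")
        unknown = set(self.iiv_cv) - set(self.model.parameter_names)
        if unknown:
            raise InvalidInputError(f"iiv_cv keys {unknown} not in model parameters")

    def with_size(self, n: int) -> "ScenarioSpec":
        return replace(self, n_subjects=n)


@dataclass
class VirtualPopulation:
    """A simulated cohort with its per-subject truth."""

    subjects: list[SubjectRecord]
    true_individual_params: list[PKParameters]
    scenario: ScenarioSpec
    seed: object = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (ID, TIME, DV, AMT + covariates)."""
        rows = []
        for subj in self.subjects:
            for i, (t, c) in enumerate(zip(subj.times, subj.concentrations)):
                row = {
                    "ID": subj.subject_id,
                    "TIME": t,
                    "DV": c,
                    "AMT": subj.dose.amount if i == 0 else np.nan,
                }
                row.update(subj.covariates)
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path, truth_path=None) -> None:
        """Write the long-format CSV; optionally a companion JSON of truth."""
        self.to_dataframe().to_csv(path, index=False, na_rep="")
        if truth_path is not None:
            truth = {
                "scenario": self.scenario.name,
                "model": self.scenario.model.value,
                "typical": self.scenario.true_params.as_dict(self.scenario.model),
                "individual": [
                    p.as_dict(self.scenario.model)
                    for p in self.true_individual_params
                ],
            }
            with open(truth_path, "w") as fh:
                json.dump(truth, fh, indent=1)


# scenario design constants -------------------------------------------------

_ONECOMP_SCHEDULE = tuple(np.linspace(0.0, 24.0, 10))
# 12 points over 24 h, six intensive samples within the first 2 h
_ONECOMP_ABS_SCHEDULE = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0)
# 18 points over 48 h, dense early / sparse late
_TWOCOMP_SCHEDULE = (
    0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0,
    12.0, 16.0, 20.0, 24.0, 30.0, 36.0, 42.0, 48.0,
)
_TWOCOMP_ABS_SCHEDULE = tuple(sorted(_TWOCOMP_SCHEDULE + (0.75, 1.25)))


def builtin_scenarios(n_subjects: int = 20) -> dict[str, ScenarioSpec]:
    """The four built-in validation scenarios (100 mg single dose each).

    Typical values are CL=5 L/h and V=50 L for one-compartment models,
    CL=5, V1=30, V2=50 L, Q=10 L/h for two-compartment models, and
    Ka=1.5 1/h for absorption models; residual error defaults to 10%
    proportional.
    """
    resid = ErrorModel(prop_sd=0.1, add_sd=0.0)
    scenarios = {
        "onecomp": ScenarioSpec(
            name="onecomp",
            model=ModelKind.ONECOMP,
            n_subjects=n_subjects,
            dose=DoseRegimen(100.0, "iv_bolus"),
            schedule=_ONECOMP_SCHEDULE,
            iiv_cv={"cl": 0.30, "v": 0.30},
            effects=(
                CovariateEffect("cl", "CRCL", "power", 0.75),
                CovariateEffect("v", "WT", "power", 0.75),
            ),
            resid=resid,
            true_params=PKParameters(cl=5.0, v=50.0),
        ),
        "onecomp_abs": ScenarioSpec(
            name="onecomp_abs",
            model=ModelKind.ONECOMP_ABS,
            n_subjects=n_subjects,
            dose=DoseRegimen(100.0, "oral"),
            schedule=_ONECOMP_ABS_SCHEDULE,
            iiv_cv={"cl": 0.30, "v": 0.30, "ka": 0.30},
            effects=(
                CovariateEffect("cl", "CRCL", "power", 0.75),
                CovariateEffect("v", "WT", "power", 0.75),
                CovariateEffect("ka", "AGE", "exponential", -0.2),
            ),
            resid=resid,
            true_params=PKParameters(cl=5.0, v=50.0, ka=1.5),
        ),
        "twocomp": ScenarioSpec(
            name="twocomp",
            model=ModelKind.TWOCOMP,
            n_subjects=n_subjects,
            dose=DoseRegimen(100.0, "iv_bolus"),
            schedule=_TWOCOMP_SCHEDULE,
            iiv_cv={"cl": 0.25, "v": 0.25, "q": 0.30, "v2": 0.30},
            effects=(
                CovariateEffect("cl", "CRCL", "power", 0.75),
                CovariateEffect("v", "WT", "power", 1.0),
                CovariateEffect("v2", "WT", "power", 1.0),
            ),
            resid=resid,
            true_params=PKParameters(cl=5.0, v=30.0, v2=50.0, q=10.0),
        ),
        "twocomp_abs": ScenarioSpec(
            name="twocomp_abs",
            model=ModelKind.TWOCOMP_ABS,
            n_subjects=n_subjects,
            dose=DoseRegimen(100.0, "oral"),
            schedule=_TWOCOMP_ABS_SCHEDULE,
            iiv_cv={"cl": 0.30, "v": 0.30, "v2": 0.30, "q": 0.30, "ka": 0.30},
            effects=(
                CovariateEffect("cl", "CRCL", "power", 0.75),
                CovariateEffect("v", "WT", "power", 1.0),
                CovariateEffect("ka", "AGE", "exponential", -0.02),
            ),
            resid=resid,
            true_params=PKParameters(cl=5.0, v=30.0, v2=50.0, q=10.0, ka=1.5),
        ),
    }
    return scenarios


def sample_covariates(n: int, seed=None) -> pd.DataFrame:
    """Sample a demographic table: WT (kg), AGE (yr), CRCL (mL/min)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["WT", "AGE", "CRCL"])
    wt = stats.truncnorm.rvs(
        (40 - 70) / 15, (120 - 70) / 15, loc=70, scale=15, size=n, random_state=rng
    )
    age = rng.uniform(20.0, 80.0, size=n)
    crcl = stats.truncnorm.rvs(
        (30 - 100) / 25, (160 - 100) / 25, loc=100, scale=25, size=n, random_state=rng
    )
    return pd.DataFrame({"WT": wt, "AGE": age, "CRCL": crcl})


def apply_covariate_effects(
    typical: PKParameters,
    covariates: Mapping[str, float],
    effects: Sequence[CovariateEffect],
    references: Mapping[str, float] | None = None,
) -> PKParameters:
    """Adjust typical parameters for one subject's covariates.

    ``references`` supplies cohort medians for effects whose ``reference`` is
    None; effects on distinct parameters act independently (multiplicatively
    on their own parameter).
    """
    values = {
        n: getattr(typical, n)
        for n in ("cl", "v", "v2", "q", "ka")
        if getattr(typical, n) is not None
    }
    for eff in effects:
        if eff.covariate not in covariates:
            raise InvalidInputError(f"covariate {eff.covariate!r} missing")
        ref = eff.reference
        if ref is None:
            if references is None or eff.covariate not in references:
                raise InvalidInputError(
                    f"no reference value for covariate {eff.covariate!r}"
                )
            ref = references[eff.covariate]
        values[eff.parameter] = eff.apply(
            values[eff.parameter], covariates[eff.covariate], ref
        )
    return PKParameters(**values)


def simulate_population(spec: ScenarioSpec, seed=None) -> VirtualPopulation:
    """Simulate a virtual population under ``spec``.

    Per subject: sample covariates, apply covariate effects to the typical
    values, multiply by log-normal between-subject variability with the
    stated CV (log-SD = sqrt(ln(1 + CV^2))), evaluate the model on the
    schedule, then add proportional (and optional additive) residual noise,
    floored at zero.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    cov_table = sample_covariates(n, rng)
    references = {c: float(cov_table[c].median()) for c in cov_table.columns} if n else {}
    names = spec.model.parameter_names
    log_sd = np.array(
        [np.sqrt(np.log1p(spec.iiv_cv.get(p, 0.0) ** 2)) for p in names]
    )
    times = np.asarray(spec.schedule, float)
    subjects, truths = [], []
    width = max(3, len(str(n)))
    for i in range(n):
        cov = {c: float(cov_table[c].iloc[i]) for c in cov_table.columns}
        adjusted = apply_covariate_effects(spec.true_params, cov, spec.effects, references)
        eta = rng.normal(0.0, 1.0, size=len(names)) * log_sd
        individual = PKParameters.from_array(
            adjusted.to_array(spec.model) * np.exp(eta), spec.model
        )
        conc = predict_conc(individual, spec.dose, times, spec.model)
        noisy = conc * (1.0 + rng.normal(0.0, 1.0, times.size) * spec.resid.prop_sd)
        if spec.resid.add_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.resid.add_sd, times.size)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                dose=spec.dose,
                times=times.copy(),
                concentrations=np.clip(noisy, 0.0, None),
                covariates=cov,
            )
        )
        truths.append(individual)
    return VirtualPopulation(subjects, truths, spec, seed)
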