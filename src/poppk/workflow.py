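"""End-to-end analysis orchestration and reporting.

``run_workflow`` wires the full pipeline: dataset in -> BLQ handling ->
individual fits -> population summary -> covariate forward selection ->
NCA -> diagnostics + VPC -> serialisable report.  Configuration travels as
a :class:`RunConfig` (JSON round-trippable, unknown keys rejected); numbers
in the report are serialised with 6 significant digits and the seed/config
are echoed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SubjectRecord, subjects_from_dataframe
from .estimation import ErrorModel, FitSettings
from .exceptions import (
    InputFormatError,
    PopulationEstimationError,
    WorkflowError,
)
from .model import PopPKModel, PopPKResults
from .nca import nca_table
from .pk_models import ModelKind, PKParameters

logger = logging.getLogger("poppk")

__all__ = ["RunConfig", "AnalysisReport", "read_dataset", "run_workflow"]


@dataclass
class RunConfig:
    """JSON-serialisable run configuration.

    Times are hours, concentrations mg/L, doses mg.  Unknown keys in a JSON
    config are rejected rather than silently ignored.
    """

    model: str = "onecomp"
    dose: float | None = None
    lloq: float = 0.0
    blq_policy: str = "drop"
    error_prop_sd: float = 0.0
    error_add_sd: float = 0.0
    scale_factors: tuple[float, ...] = (0.1, 0.5, 1.0, 1.5, 2.0)
    perturb_sd: float = 0.1
    max_iter: int = 9999
    bound_span: float = 50.0
    initial_estimates: dict | None = None
    covariate_candidates: list | None = None
    alpha: float = 0.05
    vpc_n_sim: int = 1000
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self):
        self.scale_factors = tuple(self.scale_factors)

    @classmethod
    def from_json(cls, path_or_text) -> "RunConfig":
        if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("{"):
            payload = json.loads(path_or_text)
        else:
            with open(path_or_text) as fh:
                payload = json.load(fh)
        known = {f.name for f in dc_fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["scale_factors"] = list(self.scale_factors)
        return out

    def fit_settings(self) -> FitSettings:
        init = None
        if self.initial_estimates is not None:
            init = PKParameters(**self.initial_estimates)
        return FitSettings(
            scale_factors=tuple(self.scale_factors),
            perturb_sd=self.perturb_sd,
            max_iter=self.max_iter,
            bound_span=self.bound_span,
            initial_estimates=init,
        )

    def error_model(self) -> ErrorModel | None:
        if self.error_prop_sd > 0 or self.error_add_sd > 0:
            return ErrorModel(self.error_prop_sd, self.error_add_sd)
        return None


def read_dataset(path, config: RunConfig | None = None, dose: float | None = None):
    """Read a long-format CSV into subject records (see :mod:`poppk.data`)."""
    config = config or RunConfig()
    kind = ModelKind(config.model)
    frame = pd.read_csv(path)
    return subjects_from_dataframe(
        frame, route=kind.route, dose=dose if dose is not None else config.dose
    )


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def _round_sig(obj, digits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_sig(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_sig(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            return None
        return float(f"{float(obj):.{digits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_sig(obj.tolist(), digits)
    return obj


@dataclass
class AnalysisReport:
    """Complete serialisable analysis outcome (robust to partial subject
    failures)."""

    population: dict
    covariates: dict
    fit_metrics: dict
    nca: dict
    vpc: dict
    warnings: list[str]
    config: dict
    results: PopPKResults | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return _round_sig(
            {
                "population": self.population,
                "covariates": self.covariates,
                "fit_metrics": self.fit_metrics,
                "nca": self.nca,
                "vpc": self.vpc,
                "warnings": list(self.warnings),
                "config": self.config,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=float, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_workflow(
    dataset: Sequence[SubjectRecord], config: RunConfig | None = None
) -> AnalysisReport:
    """Run the integrated pipeline on ``dataset`` under ``config``.

    Fits all subjects, summarises the population, runs covariate forward
    selection, NCA, pooled diagnostics and a VPC, and returns a complete
    report.  Subject-level failures are contained and surfaced as warnings;
    too few converged subjects raises :class:`WorkflowError` with a
    per-subject failure summary.
    """
    config = config or RunConfig()
    if len(dataset) < 2:
        raise WorkflowError("workflow needs >= 2 subjects")
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        model = PopPKModel(
            dataset,
            config.model,
            settings=config.fit_settings(),
            error=config.error_model(),
            lloq=config.lloq,
            blq_policy=config.blq_policy,
        )
        try:
            results = model.fit(seed=config.seed)
        except PopulationEstimationError as exc:
            summary = ", ".join(
                f"{s.subject_id}: {s.n_obs} obs" for s in model.subjects
            )
            raise WorkflowError(
                f"too few converged subjects ({exc}); subjects: {summary}"
            ) from exc
        candidates = None
        if config.covariate_candidates is not None:
            candidates = [tuple(pair) for pair in config.covariate_candidates]
        try:
            selection = results.select_covariates(candidates, config.alpha)
            cov_section = json.loads(selection.to_json())
        except Exception as exc:
            logger.warning("covariate selection skipped: %s", exc)
            cov_section = {"alpha": config.alpha, "selected": [], "screened": []}
        nca_results, nca_summary = results.nca()
        pooled = results.pooled_metrics()
        per_subject = {
            f.subject_id: {
                "converged": f.converged,
                "objective": f.objective if np.isfinite(f.objective) else None,
                "r2": f.r2,
                "n_attempts": f.n_attempts,
                "method": f.method_used,
            }
            for f in results.fits
        }
        vpc_seed = None if config.seed is None else config.seed + 1
        vpc_res = results.vpc(n_sim=config.vpc_n_sim, seed=vpc_seed)
        pop_section = {
            "model": results.kind.value,
            "typical": results.typical.as_dict(results.kind),
            "omega_cv_pct": results.omega_cv,
            "log_cov": results.population.log_cov,
            "resid_prop_sd": results.resid.prop_sd,
            "success_rate": results.success_rate,
            "n_subjects": results.population.n_subjects,
            "n_converged": len(results.population.converged_fits),
        }
        report = AnalysisReport(
            population=pop_section,
            covariates=cov_section,
            fit_metrics={
                "pooled": pooled.to_dict(),
                "mean_r2": results.mean_r2(),
                "per_subject": per_subject,
            },
            nca={
                "summary": nca_summary,
                "per_subject": [r.to_dict() for r in nca_results],
            },
            vpc={
                "times": vpc_res.times,
                "simulated": {f"p{p:g}": b for p, b in vpc_res.simulated.items()},
                "observed": {f"p{p:g}": b for p, b in vpc_res.observed.items()},
                "n_sim": vpc_res.n_sim,
            },
            warnings=list(collector.messages),
            config=config.to_dict(),
            results=results,
        )
        return report
    finally:
        logger.removeHandler(collector)
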