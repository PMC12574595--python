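"""Model/Results interface for two-stage population PK analysis.

:class:`PopPKModel` is constructed from subject data and a structural model
kind; :meth:`PopPKModel.fit` runs the automated individual fits plus the
population summary and returns a :class:`PopPKResults` carrying estimates,
variability, diagnostics and a text ``summary()``.  Covariate selection,
NCA, VPC and simulation hang off the results object.

Example
-------
>>> from poppk import PopPKModel, builtin_scenarios, simulate_population
>>> vpop = simulate_population(builtin_scenarios()["onecomp"], seed=1)
>>> res = PopPKModel(vpop.subjects, "onecomp").fit(seed=1)
>>> round(res.typical.cl, 2)  # doctest: +SKIP
5.01
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .covariate_analysis import SelectionResult, forward_select
from .data import SubjectRecord, subjects_from_dataframe
from .diagnostics import (
    FitMetrics,
    VPCResult,
    fit_metrics,
    observed_vs_predicted,
    shrinkage_and_condition,
    vpc,
)
from .estimation import (
    ErrorModel,
    FitSettings,
    PopulationResult,
    estimate_population,
    fit_population,
    handle_blq,
)
from .exceptions import WorkflowError
from .nca import NCAResult, run_nca
from .pk_models import ModelKind, PKParameters

__all__ = ["PopPKModel", "PopPKResults"]


class PopPKModel:
    """Two-stage population pharmacokinetic model.

    Parameters
    ----------
    subjects :
        Subject records (dose, times, concentrations, covariates).
    kind :
        Structural model: ``onecomp``, ``onecomp_abs``, ``twocomp`` or
        ``twocomp_abs``.
    settings :
        Fitting strategy knobs (:class:`FitSettings`); defaults implement the
        automated multi-start initialisation.
    error :
        Residual error model used for objective weighting; the default unit
        sigma leaves the argmin unchanged.
    lloq, blq_policy :
        Below-limit-of-quantification handling applied at construction
        (``drop`` or ``half_lloq``).
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        kind: ModelKind | str,
        settings: FitSettings | None = None,
        error: ErrorModel | None = None,
        lloq: float = 0.0,
        blq_policy: str = "drop",
    ):
        self.kind = ModelKind(kind)
        self.settings = settings or FitSettings()
        self.error = error
        if lloq > 0:
            subjects = [handle_blq(s, lloq, blq_policy) for s in subjects]
        self.subjects = list(subjects)
        if len(self.subjects) < 2:
            raise WorkflowError("population analysis needs >= 2 subjects")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, kind: ModelKind | str, dose: float | None = None, **kwargs
    ) -> "PopPKModel":
        kind = ModelKind(kind)
        subjects = subjects_from_dataframe(df, route=kind.route, dose=dose)
        return cls(subjects, kind, **kwargs)

    @classmethod
    def from_csv(
        cls, path, kind: ModelKind | str, dose: float | None = None, **kwargs
    ) -> "PopPKModel":
        return cls.from_dataframe(pd.read_csv(path), kind, dose=dose, **kwargs)

    def fit(self, seed=None) -> "PopPKResults":
        """Fit every subject and summarise the population (two stages)."""
        fits = fit_population(
            self.subjects, self.kind, self.settings, self.error, seed
        )
        population = estimate_population(fits, self.kind)
        return PopPKResults(model=self, population=population)


@dataclass
class PopPKResults:
    """Fitted two-stage population analysis."""

    model: PopPKModel
    population: PopulationResult
    _selection: SelectionResult | None = field(default=None, repr=False)

    # -- estimates ---------------------------------------------------------
    @property
    def kind(self) -> ModelKind:
        return self.population.kind

    @property
    def typical(self) -> PKParameters:
        """Population typical values (geometric means)."""
        return self.population.typical

    @property
    def omega_cv(self) -> dict[str, float]:
        """Between-subject variability, CV% per parameter."""
        return self.population.omega_cv

    @property
    def resid(self) -> ErrorModel:
        return self.population.resid

    @property
    def fits(self):
        return self.population.fits

    @property
    def success_rate(self) -> float:
        return self.population.success_rate

    # -- downstream analyses ----------------------------------------------
    def select_covariates(
        self, candidates=None, alpha: float = 0.05
    ) -> SelectionResult:
        """AIC/significance forward selection over candidate pairs."""
        self._selection = forward_select(
            self.population, candidates=candidates, alpha=alpha
        )
        return self._selection

    def nca(self) -> tuple[list[NCAResult], dict]:
        """Non-compartmental analysis of the underlying subjects."""
        return run_nca(self.model.subjects)

    def vpc(self, n_sim: int = 1000, seed=None, percentiles=(5.0, 50.0, 95.0)) -> VPCResult:
        """Visual predictive check simulated from the fitted population."""
        return vpc(self.population, n_sim=n_sim, seed=seed, percentiles=percentiles)

    def pooled_metrics(self) -> FitMetrics:
        """Pooled per-observation goodness of fit over converged subjects."""
        table = observed_vs_predicted(self.population)
        return fit_metrics(table["PRED"].to_numpy(), table["OBS"].to_numpy())

    def shrinkage_condition(self, external_omega_cv=None):
        return shrinkage_and_condition(self.population, external_omega_cv)

    def mean_r2(self) -> float:
        vals = [f.r2 for f in self.population.converged_fits if np.isfinite(f.r2)]
        return float(np.mean(vals)) if vals else np.nan

    # -- presentation ------------------------------------------------------
    def parameter_frame(self) -> pd.DataFrame:
        names = self.population.parameter_names
        return pd.DataFrame(
            {
                "estimate": [getattr(self.typical, n) for n in names],
                "bsv_cv_pct": [self.omega_cv[n] for n in names],
            },
            index=[n.upper() for n in names],
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted population."""
        pop = self.population
        lines = [
            "Two-stage population PK fit",
            "=" * 42,
            f"model:            {self.kind.value}",
            f"subjects:         {pop.n_subjects}"
            f"  (converged {len(pop.converged_fits)},"
            f" success rate {pop.success_rate:.1%})",
            f"residual prop SD: {pop.resid.prop_sd:.4f}",
            f"mean R^2:         {self.mean_r2():.4f}",
            "",
            f"{'parameter':<10}{'typical':>12}{'BSV CV%':>12}",
            "-" * 34,
        ]
        for name in pop.parameter_names:
            lines.append(
                f"{name.upper():<10}{getattr(self.typical, name):>12.4g}"
                f"{self.omega_cv[name]:>12.3g}"
            )
        if self._selection is not None:
            lines.append("")
            lines.append("selected covariate relations:")
            if not self._selection.selected:
                lines.append("  (none)")
            for rel in self._selection.selected:
                lines.append(
                    f"  {rel.parameter.upper()} ~ {rel.covariate} [{rel.form}]"
                    f"  theta2={rel.theta2:.4g}  p={rel.p_value:.3g}"
                    f"  dAIC={rel.delta_aic:.3g}"
                )
        return "\n".join(lines)
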