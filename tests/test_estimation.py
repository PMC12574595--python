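"""Individual fitting, fallback behaviour and two-stage population summary."""

import numpy as np
import pytest

from poppk import (
    DoseRegimen,
    ErrorModel,
    FitSettings,
    IndividualFit,
    ModelKind,
    PKParameters,
    SubjectRecord,
    estimate_population,
    fit_individual,
    fit_population,
    handle_blq,
    initial_estimates,
    objective,
    predict_conc,
)
from poppk.estimation import base_estimate
from poppk.exceptions import PopulationEstimationError, UnfittableSubjectError

from conftest import make_subject

TRUTH = PKParameters(cl=5.0, v=50.0)


class TestObjective:
    def test_perfect_predictions_give_zero(self):
        subj = make_subject(TRUTH, "onecomp")
        assert objective(TRUTH, subj, ModelKind.ONECOMP) < 1e-20

    def test_constant_e_fold_misfit_counts_points(self):
        # predictions = e * observations => each squared log-residual is 1
        subj = make_subject(TRUTH, "onecomp")
        inflated = subj.with_observations(
            subj.times, subj.concentrations * np.e
        )
        val = objective(TRUTH, inflated, ModelKind.ONECOMP, ErrorModel(prop_sd=1.0))
        assert val == pytest.approx(10.0, rel=1e-12)

    def test_penalty_monotone_outside_bounds(self):
        subj = make_subject(TRUTH, "onecomp")
        bounds = {"cl": (1.0, 10.0), "v": (10.0, 100.0)}
        at_bound = objective(
            PKParameters(cl=10.0, v=50.0), subj, ModelKind.ONECOMP, bounds=bounds
        )
        above = objective(
            PKParameters(cl=100.0, v=50.0), subj, ModelKind.ONECOMP, bounds=bounds
        )
        assert above > at_bound

    def test_sigma_scales_objective_not_argmin(self):
        subj = make_subject(TRUTH, "onecomp", noise_sd=0.1)
        v1 = objective(TRUTH, subj, ModelKind.ONECOMP, ErrorModel(prop_sd=0.1))
        v2 = objective(TRUTH, subj, ModelKind.ONECOMP, ErrorModel(prop_sd=0.2))
        assert v1 == pytest.approx(4.0 * v2, rel=1e-12)

    def test_all_blq_subject_unfittable(self):
        subj = make_subject(TRUTH, "onecomp")
        zeroed = subj.with_observations(subj.times, np.zeros_like(subj.times))
        with pytest.raises(UnfittableSubjectError):
            objective(TRUTH, zeroed, ModelKind.ONECOMP)


class TestInitialEstimates:
    def test_default_scale_grid_gives_five_starts(self):
        subj = make_subject(TRUTH, "onecomp")
        starts = initial_estimates(subj, ModelKind.ONECOMP, seed=1)
        assert len(starts) == 5

    def test_deterministic_under_seed(self):
        subj = make_subject(TRUTH, "onecomp")
        a = initial_estimates(subj, ModelKind.ONECOMP, seed=7)
        b = initial_estimates(subj, ModelKind.ONECOMP, seed=7)
        assert [p.as_dict() for p in a] == [p.as_dict() for p in b]

    def test_base_heuristic_close_on_noise_free_iv(self):
        subj = make_subject(TRUTH, "onecomp", times=np.linspace(0, 24, 10))
        base = base_estimate(subj, ModelKind.ONECOMP)
        assert base.cl == pytest.approx(5.0, rel=0.25)
        assert base.v == pytest.approx(50.0, rel=0.25)

    def test_too_few_points_unfittable(self):
        subj = make_subject(TRUTH, "onecomp", times=[1.0, 2.0])
        with pytest.raises(UnfittableSubjectError):
            initial_estimates(subj, ModelKind.ONECOMP, seed=0)


class TestFitIndividual:
    def test_noise_free_recovery_within_one_percent(self):
        subj = make_subject(TRUTH, "onecomp", times=np.linspace(0.5, 24, 10))
        fit = fit_individual(subj, ModelKind.ONECOMP, seed=3)
        assert fit.converged
        assert fit.estimates.cl == pytest.approx(5.0, rel=0.01)
        assert fit.estimates.v == pytest.approx(50.0, rel=0.01)

    def test_reordering_observations_leaves_estimates(self):
        rng = np.random.default_rng(5)
        subj = make_subject(TRUTH, "onecomp", noise_sd=0.1, rng=rng)
        perm = np.random.default_rng(1).permutation(subj.n_obs)
        shuffled = subj.with_observations(
            subj.times[perm], subj.concentrations[perm]
        )
        f1 = fit_individual(subj, ModelKind.ONECOMP, seed=9)
        f2 = fit_individual(shuffled, ModelKind.ONECOMP, seed=9)
        assert f1.estimates.cl == pytest.approx(f2.estimates.cl, rel=1e-3)
        assert f1.estimates.v == pytest.approx(f2.estimates.v, rel=1e-3)

    def test_invalid_first_start_triggers_fallback(self):
        subj = make_subject(TRUTH, "onecomp", times=np.linspace(0.5, 24, 10))
        # scaling by 1e308 overflows the volume to inf: non-finite objective
        settings = FitSettings(scale_factors=(1e308, 1.0))
        fit = fit_individual(subj, ModelKind.ONECOMP, settings=settings, seed=2)
        assert fit.converged
        assert fit.n_attempts > 1

    def test_returned_objective_not_worse_than_any_start(self):
        rng = np.random.default_rng(8)
        subj = make_subject(TRUTH, "onecomp", noise_sd=0.15, rng=rng)
        settings = FitSettings()
        fit = fit_individual(subj, ModelKind.ONECOMP, settings=settings, seed=11)
        starts = initial_estimates(subj, ModelKind.ONECOMP, settings, seed=11)
        start_objs = [
            objective(p, subj, ModelKind.ONECOMP, bounds=fit.bounds) for p in starts
        ]
        assert fit.objective <= min(start_objs) + 1e-12

    def test_total_failure_returns_unconverged_not_raise(self):
        subj = make_subject(TRUTH, "onecomp", times=[1.0, 2.0])  # too few points
        fit = fit_individual(subj, ModelKind.ONECOMP, seed=0)
        assert not fit.converged and fit.estimates is None


class TestEstimatePopulation:
    @staticmethod
    def _mock_fits(cl_values, v_values):
        return [
            IndividualFit(
                subject_id=f"S{i}",
                estimates=PKParameters(cl=c, v=v),
                objective=0.0,
                converged=True,
                n_attempts=1,
                method_used="nelder_mead",
                r2=1.0,
            )
            for i, (c, v) in enumerate(zip(cl_values, v_values))
        ]

    def test_identical_individuals_zero_variability(self):
        pop = estimate_population(
            self._mock_fits([5.0] * 6, [50.0] * 6), ModelKind.ONECOMP
        )
        assert pop.typical.cl == pytest.approx(5.0, rel=1e-12)
        assert pop.typical.v == pytest.approx(50.0, rel=1e-12)
        assert pop.omega_cv["cl"] == pytest.approx(0.0, abs=1e-9)

    def test_geometric_mean_of_two(self):
        pop = estimate_population(
            self._mock_fits([1.0, 4.0], [50.0, 50.0]), ModelKind.ONECOMP
        )
        assert pop.typical.cl == pytest.approx(2.0, rel=1e-12)

    def test_lognormal_cv_recovered(self):
        rng = np.random.default_rng(0)
        sd = np.sqrt(np.log1p(0.3**2))
        cl = 5.0 * np.exp(rng.normal(0, sd, 5000))
        pop = estimate_population(
            self._mock_fits(cl, np.full(5000, 50.0)), ModelKind.ONECOMP
        )
        assert abs(pop.omega_cv["cl"] - 30.0) < 2.0

    def test_fewer_than_two_converged_raises(self):
        fits = self._mock_fits([5.0], [50.0])
        with pytest.raises(PopulationEstimationError):
            estimate_population(fits, ModelKind.ONECOMP)

    def test_log_cov_symmetric_psd(self):
        rng = np.random.default_rng(3)
        pop = estimate_population(
            self._mock_fits(
                5 * np.exp(rng.normal(0, 0.3, 40)), 50 * np.exp(rng.normal(0, 0.3, 40))
            ),
            ModelKind.ONECOMP,
        )
        cov = pop.log_cov
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)


class TestHandleBlq:
    def _subject(self, concs):
        return SubjectRecord(
            "S1", DoseRegimen(100.0), np.arange(len(concs), dtype=float), np.array(concs)
        )

    def test_zero_lloq_unchanged(self):
        subj = self._subject([0.05, 1.2, 3.0])
        out = handle_blq(subj, lloq=0.0)
        assert np.array_equal(out.concentrations, subj.concentrations)

    def test_drop_policy_removes_below_lloq(self):
        out = handle_blq(self._subject([0.05, 1.2, 3.0]), lloq=0.1, policy="drop")
        assert out.n_obs == 2

    def test_half_lloq_policy_imputes(self):
        out = handle_blq(self._subject([0.05, 1.2, 3.0]), lloq=0.1, policy="half_lloq")
        assert out.concentrations[0] == pytest.approx(0.05)
        assert out.blq_flags[0] and not out.blq_flags[1]


def test_round_trip_with_and_without_user_initials():
    rng = np.random.default_rng(21)
    subjects = [
        make_subject(
            PKParameters(cl=5 * np.exp(rng.normal(0, 0.3)), v=50 * np.exp(rng.normal(0, 0.3))),
            "onecomp",
            noise_sd=0.1,
            rng=rng,
            subject_id=f"S{i}",
        )
        for i in range(8)
    ]
    auto = estimate_population(
        fit_population(subjects, ModelKind.ONECOMP, seed=1), ModelKind.ONECOMP
    )
    user = estimate_population(
        fit_population(
            subjects,
            ModelKind.ONECOMP,
            FitSettings(initial_estimates=PKParameters(cl=4.0, v=40.0)),
            seed=2,
        ),
        ModelKind.ONECOMP,
    )
    assert auto.typical.cl == pytest.approx(user.typical.cl, rel=5e-4)
    assert auto.typical.v == pytest.approx(user.typical.v, rel=5e-4)
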