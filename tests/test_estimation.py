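"""Gauss-Newton solver behaviour, initialisation and Wald inference."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from gcc2vfs.cohort import CohortConfig, generate_cohort
from gcc2vfs.estimation import (
    ComparatorData,
    FitOptions,
    MultipleLogisticData,
    NonIdentifiableError,
    SimpleLogisticData,
    default_init,
    fit_area_model,
    gauss_newton_solve,
    wald_inference,
)
from gcc2vfs.models import SimpleLogisticParams, predict_vfs_simple
from gcc2vfs.reference import reference_multiple_params


def _simple_data(params, n=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    gcc = rng.uniform(30.0, 120.0, n)
    y = np.asarray(predict_vfs_simple(params, gcc))
    y = y + noise * rng.standard_normal(n)
    return SimpleLogisticData(gcc=gcc, observed=y)


class TestSolver:
    def test_linear_model_is_solved_in_one_step(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(40, 120, 50)
        y = 2.0 + 0.3 * g + rng.standard_normal(50)
        model = ComparatorData(gcc=g, observed=y, family="linear")
        fit = gauss_newton_solve(model, init=[0.0, 0.0])
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones_like(g), g]), y, rcond=None
        )
        # Gauss-Newton is exact for a linear model: the first step lands
        # on the least-squares solution, the second only confirms it.
        assert fit.converged and fit.n_iter <= 2
        assert fit.params == pytest.approx(coef, rel=1e-10)

    def test_noiseless_simple_model_recovered_to_machine_tolerance(self):
        truth = SimpleLogisticParams(33.0, 57.0, 0.09)
        fit = gauss_newton_solve(_simple_data(truth))
        assert fit.converged
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.params == pytest.approx(truth.as_array(), rel=1e-6)

    def test_matches_scipy_least_squares_on_noisy_data(self):
        truth = SimpleLogisticParams(33.0, 57.0, 0.09)
        model = _simple_data(truth, noise=3.0, seed=4)
        fit = gauss_newton_solve(model)
        init = default_init(model)
        ref = least_squares(
            lambda p: model.observed - model.predict(p), init, method="lm",
            xtol=1e-14, ftol=1e-14,
        )
        assert fit.sse == pytest.approx(2 * ref.cost, rel=1e-8)

    def test_damped_steps_never_increase_sse(self):
        truth = SimpleLogisticParams(33.0, 57.0, 0.09)
        model = _simple_data(truth, noise=4.0, seed=9)
        init = default_init(model)
        opts = FitOptions(damping=1.0, max_iter=1)
        sse_prev = float(
            np.sum((model.observed - model.predict(init)) ** 2)
        )
        theta = init
        for _ in range(30):  # one accepted step at a time
            fit = gauss_newton_solve(model, theta, opts)
            assert fit.sse <= sse_prev * (1 + 1e-12)
            sse_prev, theta = fit.sse, fit.params

    def test_permutation_invariance(self):
        truth = SimpleLogisticParams(33.0, 57.0, 0.09)
        model = _simple_data(truth, noise=3.0, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(model.gcc.size)
        shuffled = SimpleLogisticData(
            gcc=model.gcc[perm], observed=model.observed[perm]
        )
        a = gauss_newton_solve(model)
        b = gauss_newton_solve(shuffled)
        assert a.params == pytest.approx(b.params, rel=1e-9)

    def test_underdetermined_fit_rejected(self):
        truth = SimpleLogisticParams(33.0, 57.0, 0.09)
        with pytest.raises(NonIdentifiableError, match="underdetermined"):
            gauss_newton_solve(_simple_data(truth, n=3))

    def test_estimator_sd_shrinks_with_sample_size(self):
        """Consistency: spread of theta1 estimates falls as n grows."""
        sds = []
        for n in (83, 332, 1328):
            ests = []
            for rep in range(12):
                t = generate_cohort(CohortConfig(n_eyes=n, seed=500 + rep))
                fit = fit_area_model(t, "whole", "multiple")
                ests.append(fit.params[0])
            sds.append(np.std(ests))
        assert sds[0] > sds[1] > sds[2]


class TestInit:
    def test_theta1_starts_at_max_observed(self):
        model = _simple_data(SimpleLogisticParams(33.0, 57.0, 0.09))
        assert default_init(model)[0] == model.observed.max()

    def test_init_lies_in_attraction_basin(self):
        truth = SimpleLogisticParams(30.0, 62.0, 0.15)
        model = _simple_data(truth, seed=3)
        fit = gauss_newton_solve(model, default_init(model))
        assert fit.converged
        assert fit.params == pytest.approx(truth.as_array(), rel=1e-6)

    def test_constant_response_flagged_non_identifiable(self):
        model = SimpleLogisticData(
            gcc=np.linspace(40, 100, 10), observed=np.full(10, 25.0)
        )
        with pytest.raises(NonIdentifiableError, match="constant response"):
            default_init(model)

    def test_empty_dataset_rejected(self):
        model = SimpleLogisticData(gcc=np.array([]), observed=np.array([]))
        with pytest.raises(NonIdentifiableError, match="empty"):
            default_init(model)


class TestFitAreaModel:
    def test_missing_columns_named(self, synthetic_table):
        broken = synthetic_table.drop(columns=["vfs_whole_db"])
        with pytest.raises(KeyError, match="vfs_whole_db"):
            fit_area_model(broken, "whole", "multiple")

    def test_unknown_model_kind_rejected(self, synthetic_table):
        with pytest.raises(ValueError, match="unknown model kind"):
            fit_area_model(synthetic_table, "whole", "logit")

    def test_recovers_generating_parameters_on_low_noise_cohort(self):
        table = generate_cohort(CohortConfig(n_eyes=300, seed=21, noise_sd=0.5))
        truth = reference_multiple_params("inferior").as_array()
        fit = fit_area_model(table, "inferior", "multiple")
        assert fit.converged
        assert fit.params == pytest.approx(truth, rel=0.15, abs=0.02)

    def test_simple_model_fits_every_area(self, synthetic_table):
        for area in ("whole", "3_2", "6_3"):
            fit = fit_area_model(synthetic_table, area, "simple")
            assert fit.converged
            assert fit.model_kind == "simple" and fit.area == area

    def test_comparator_families_fit(self, synthetic_table):
        for kind in ("linear", "poly2", "poly3", "plateau"):
            fit = fit_area_model(synthetic_table, "whole", kind)
            assert fit.converged
            assert np.isfinite(fit.sse)


class TestWald:
    def test_zero_estimate_gives_p_of_one(self):
        model = _simple_data(SimpleLogisticParams(33.0, 57.0, 0.09), noise=2.0)
        fit = gauss_newton_solve(model)
        fit.params = np.zeros_like(fit.params)
        p = wald_inference(fit)
        assert p == pytest.approx(np.ones_like(p))

    def test_normal_limit_at_196_se(self):
        model = _simple_data(
            SimpleLogisticParams(33.0, 57.0, 0.09), n=5000, noise=2.0
        )
        fit = gauss_newton_solve(model)
        fit.params = 1.96 * fit.std_errors
        p = wald_inference(fit)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_significant_thickness_effect_on_default_cohort(self, synthetic_table):
        fit = fit_area_model(synthetic_table, "whole", "multiple")
        p_b1 = fit.p_values[fit.param_names.index("b1")]
        assert p_b1 < 0.001
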