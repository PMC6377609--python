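"""Likelihood, fitting, standard errors, LRT and model selection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvapk import (
    CovariateSpec,
    DesignSpec,
    FitResult,
    ModelSpec,
    PKParameters,
    SimulationConfig,
    fit,
    lrt,
    neg2_loglik,
    predict_amounts,
    prop_error_cv,
    select_model,
    simulate_dataset,
    standard_errors,
)
from larvapk.estimation import _ParamLayout


def _frame(ages, arms, times, amounts):
    return pd.DataFrame(
        {
            "age_dpf": ages,
            "arm": arms,
            "time_min": times,
            "amount_pmole": amounts,
        }
    )


class TestNeg2Loglik:
    spec = ModelSpec(error_model="additive")

    def test_zero_residuals_unit_additive_variance(self, design):
        p = PKParameters(ka_base=0.289, ke_base=0.0193, sigma2_add=1.0)
        df = _frame([3] * 4, ["constant"] * 4, [10.0, 30.0, 60.0, 120.0], [0.0] * 4)
        df["amount_pmole"] = predict_amounts(p, self.spec, df, design)
        assert neg2_loglik(p, self.spec, df, design) == pytest.approx(
            4 * math.log(2 * math.pi), rel=1e-12
        )

    def test_three_point_hand_computed_value(self, design):
        """Independent oracle: -2 * sum of Gaussian log densities."""
        p = PKParameters(
            ka_base=0.3, ke_base=0.02, sigma2_prop=0.04, sigma2_add=0.01
        )
        spec = ModelSpec(error_model="combined")
        df = _frame(
            [3, 3, 3], ["constant"] * 3, [20.0, 60.0, 120.0], [5.0, 10.0, 14.0]
        )
        pred = predict_amounts(p, spec, df, design)
        v = pred**2 * 0.04 + 0.01
        oracle = -2.0 * stats.norm.logpdf(
            df["amount_pmole"].to_numpy(), loc=pred, scale=np.sqrt(v)
        ).sum()
        ours = neg2_loglik(p, spec, df, design)
        assert ours == pytest.approx(oracle, rel=1e-12)
        # frozen value from the oracle above, guards against regressions
        assert ours == pytest.approx(9.066128, abs=1e-5)

    def test_gaussian_scaling_identity(self, design):
        """Scaling obs, pred and additive SD by c shifts the OFV by 2n ln c."""
        base = PKParameters(ka_base=0.3, ke_base=0.02, sigma2_add=0.25)
        df = _frame([3] * 3, ["constant"] * 3, [15.0, 45.0, 90.0], [4.0, 9.0, 11.0])
        c = 3.7
        scaled = PKParameters(ka_base=0.3 * c, ke_base=0.02, sigma2_add=0.25 * c**2)
        df2 = df.assign(amount_pmole=df["amount_pmole"] * c)
        lhs = neg2_loglik(scaled, self.spec, df2, design)
        rhs = neg2_loglik(base, self.spec, df, design) + 2 * len(df) * math.log(c)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_degenerate_error_model_raises(self, design):
        p = PKParameters(ka_base=0.3, ke_base=0.02, sigma2_prop=0.04, sigma2_add=0.0)
        spec = ModelSpec(error_model="proportional")
        df = _frame([3], ["constant"], [0.0], [0.0])  # pred = 0 -> v = 0
        with pytest.raises(ValueError, match="degenerate"):
            neg2_loglik(p, spec, df, design)


class TestFit:
    def test_near_noise_free_recovery(self, small_design):
        truth = PKParameters(
            ka_base=0.289, ka_coef=1.06, ke_base=0.0193, ke_coef=0.175,
            sigma2_prop=1e-8, sigma2_add=1e-10,
        )
        spec = ModelSpec(
            ka_covariate=CovariateSpec(form="discrete"),
            ke_covariate=CovariateSpec(form="power"),
            error_model="combined",
        )
        df = simulate_dataset(
            SimulationConfig(design=small_design, truth=truth, modelspec=spec, seed=3)
        )
        res = fit(df, spec, small_design, n_restarts=3, seed=0)
        est = res.estimate_dict()
        assert est["ka_base"] == pytest.approx(0.289, rel=1e-3)
        assert est["factor_a"] == pytest.approx(1.06, rel=1e-3)
        assert est["ke_base"] == pytest.approx(0.0193, rel=1e-3)
        assert est["slope_e"] == pytest.approx(0.175, rel=1e-3)

    def test_optimum_beats_truth(self, dataset, final_spec, design, truth):
        res = fit(dataset, final_spec, design, n_restarts=3, seed=0)
        assert res.ofv <= neg2_loglik(truth, final_spec, dataset, design) + 1e-6

    def test_fit_invariant_under_observation_reordering(self, dataset, final_spec, design):
        res1 = fit(dataset, final_spec, design, n_restarts=2, seed=0)
        shuffled = dataset.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = fit(shuffled, final_spec, design, n_restarts=2, seed=0)
        for k, v in res1.estimate_dict().items():
            assert res2.estimate_dict()[k] == pytest.approx(v, rel=1e-3)

    def test_too_few_observations_raises(self, design, final_spec):
        df = _frame([3, 3], ["constant"] * 2, [10.0, 20.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="observations"):
            fit(df, final_spec, design)

    def test_nesting_monotonicity_of_ofv(self, small_design):
        """Adding a redundant covariate never worsens the optimal OFV."""
        truth = PKParameters(ka_base=0.3, ke_base=0.02, sigma2_add=0.04)
        reduced = ModelSpec(error_model="additive")
        full = ModelSpec(
            error_model="additive", ka_covariate=CovariateSpec(form="discrete")
        )
        df = simulate_dataset(
            SimulationConfig(design=small_design, truth=truth, modelspec=reduced, seed=11)
        )
        r1 = fit(df, reduced, small_design, n_restarts=3, seed=0)
        r2 = fit(df, full, small_design, n_restarts=3, seed=0)
        assert r2.ofv <= r1.ofv + 1e-6


class TestStandardErrors:
    def test_quadratic_toy_matches_analytic_curvature(self, design):
        """For OFV = sum c_i (x_i - x0_i)^2 the natural-scale covariance is
        exactly diag(exp(2 x0_i) / c_i)."""
        spec = ModelSpec(error_model="additive")  # 3-parameter layout
        layout = _ParamLayout(spec)
        x0 = np.array([-1.0, -3.5, -2.0])
        c = np.array([4.0, 25.0, 0.5])

        def objective(x):
            return float(np.sum(c * (x - x0) ** 2))

        est = layout.unpack_natural(layout.to_natural(x0))
        res = FitResult(
            estimates=est, ofv=0.0, covariance=None, rse_percent=None,
            converged=True, n_obs=10, n_params=3,
            param_names=tuple(layout.names), spec=spec,
        )
        rse = standard_errors(res, None, spec, design, x_opt=x0, objective=objective)
        expected_var = np.exp(2 * x0) / c
        np.testing.assert_allclose(np.diag(res.covariance), expected_var, rtol=1e-4)
        for i, name in enumerate(layout.names):
            expected_rse = 100.0 * np.sqrt(expected_var[i]) / np.exp(x0[i])
            assert rse[name] == pytest.approx(expected_rse, rel=1e-4)

    def test_rse_shrinks_with_sample_size(self, truth, final_spec):
        """Quadrupling replication should shrink RSEs roughly 1/sqrt(n)."""
        rses = {}
        for reps in (3, 12):
            d = DesignSpec(
                treatment_times=(15.0, 45.0, 90.0, 180.0),
                washout_times=(75.0, 120.0, 180.0, 240.0),
                replicates=reps,
            )
            df = simulate_dataset(
                SimulationConfig(design=d, truth=truth, modelspec=final_spec, seed=21)
            )
            res = fit(df, final_spec, d, n_restarts=3, seed=0)
            assert res.se_ok
            rses[reps] = res.rse_percent["ka_base"]
        ratio = rses[12] / rses[3]
        assert 0.25 < ratio < 0.85  # ~0.5 expected, wide band for sampling noise

    def test_structural_rses_well_below_50_on_study_design(self, dataset, final_spec, design):
        res = fit(dataset, final_spec, design, n_restarts=3, seed=0)
        assert res.se_ok
        for name in ("ka_base", "factor_a", "ke_base", "slope_e"):
            assert res.rse_percent[name] < 50.0

    def test_non_converged_fit_rejected(self, design, final_spec):
        res = FitResult(
            estimates=PKParameters(), ofv=0.0, covariance=None, rse_percent=None,
            converged=False, n_obs=0, n_params=6, spec=final_spec,
        )
        with pytest.raises(ValueError):
            standard_errors(res, None, final_spec, design)


def _mock_fit(ofv, n_params, n_obs=100):
    return FitResult(
        estimates=PKParameters(), ofv=ofv, covariance=None, rse_percent=None,
        converged=True, n_obs=n_obs, n_params=n_params,
    )


class TestLRT:
    def test_chi2_quantile_at_critical_value(self):
        p = lrt(_mock_fit(106.635, 3), _mock_fit(100.0, 4))
        assert p == pytest.approx(0.01, abs=2e-4)

    def test_identical_fits_give_p_one(self):
        assert lrt(_mock_fit(100.0, 3), _mock_fit(100.0, 4)) == pytest.approx(1.0)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = lrt(_mock_fit(100.0, 3), _mock_fit(100.5, 4))
        assert p == pytest.approx(1.0)

    def test_non_nested_or_mismatched_raise(self):
        with pytest.raises(ValueError):
            lrt(_mock_fit(100.0, 4), _mock_fit(90.0, 3))
        with pytest.raises(ValueError):
            lrt(_mock_fit(100.0, 3, n_obs=50), _mock_fit(90.0, 4, n_obs=60))


class TestSelectModel:
    def test_single_candidate_ladder(self, dataset, design):
        spec = ModelSpec(error_model="combined")
        chosen, res, trace = select_model(
            dataset, design, [spec], n_restarts=2, seed=0
        )
        assert chosen is spec
        assert trace == []
        assert res.converged

    def test_recovers_age_covariates_on_final_model_data(self, dataset, design, final_spec):
        base = ModelSpec(error_model="combined")
        step_ka = ModelSpec(
            error_model="combined", ka_covariate=CovariateSpec(form="discrete")
        )
        chosen, res, trace = select_model(
            dataset, design, [base, step_ka, final_spec], alpha=0.01,
            n_restarts=3, seed=0,
        )
        assert chosen is final_spec
        assert all(step.accepted for step in trace)
        assert trace[0].p_value < 1e-6  # strong absorption age effect

    def test_rejects_covariates_without_age_effect(self, small_design):
        truth = PKParameters(ka_base=0.3, ke_base=0.02, sigma2_prop=0.02, sigma2_add=0.01)
        base = ModelSpec(error_model="combined")
        df = simulate_dataset(
            SimulationConfig(design=small_design, truth=truth, modelspec=base, seed=13)
        )
        step_ka = ModelSpec(
            error_model="combined", ka_covariate=CovariateSpec(form="discrete")
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen, _, trace = select_model(
                df, small_design, [base, step_ka], alpha=0.01, n_restarts=3, seed=0
            )
        assert chosen is base
        assert not trace[0].accepted

    def test_empty_ladder_raises(self, dataset, design):
        with pytest.raises(ValueError):
            select_model(dataset, design, [])


class TestPropErrorCV:
    def test_reported_value(self):
        assert float(f"{prop_error_cv(0.109):.2g}") == 33.0

    @pytest.mark.parametrize("s2,cv", [(0.0, 0.0), (0.25, 50.0), (1.0, 100.0)])
    def test_exact_squares(self, s2, cv):
        assert prop_error_cv(s2) == pytest.approx(cv)

    def test_negative_variance_raises(self):
        with pytest.raises(ValueError):
            prop_error_cv(-0.1)
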