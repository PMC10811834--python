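"""From-scratch logistic and conditional logistic regression against
closed forms and the statsmodels reference implementation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from obesnp.regression import (
    RankDeficiencyError,
    SeparationError,
    build_design,
    fit_conditional_logistic,
    fit_logistic,
    model_report,
)


def simulate(seed, n=600, k=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [rng.normal(size=n)] + [rng.binomial(1, 0.4, n) for _ in range(k - 1)]
    )
    beta = np.array([0.5, -0.7, 0.3])[:k]
    eta = -0.2 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y, rng


class TestFitLogistic:
    def test_saturated_2x2_recovers_cross_product_odds_ratio(self):
        # cells: exposed cases 30, exposed non 20, unexposed cases 10, unexposed non 40
        x = np.repeat([1, 1, 0, 0], [30, 20, 10, 40]).astype(float)
        y = np.repeat([1, 0, 1, 0], [30, 20, 10, 40])
        fit = fit_logistic(x[:, None], y, names=["exposed"])
        assert fit.coef("exposed") == pytest.approx(np.log((30 * 40) / (20 * 10)), abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_agrees_with_statsmodels(self, seed):
        X, y, _ = simulate(seed)
        fit = fit_logistic(X, y, names=["x0", "x1", "x2"])
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-7)
        assert np.allclose(fit.se, ref.bse, atol=1e-7)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)
        assert fit.converged

    def test_cluster_sandwich_agrees_with_statsmodels(self):
        X, y, rng = simulate(5)
        clusters = rng.integers(0, 20, len(y))
        fit = fit_logistic(X, y, names=["x0", "x1", "x2"], cluster_ids=clusters)
        ref = sm.Logit(y, sm.add_constant(X)).fit(
            disp=0, cov_type="cluster", cov_kwds={"groups": clusters}
        )
        assert np.allclose(fit.se, ref.bse, rtol=1e-6)

    def test_null_covariate_within_three_se(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x_null = rng.normal(size=n)
        y = rng.binomial(1, 0.3, n)
        fit = fit_logistic(x_null[:, None], y, names=["noise"])
        assert abs(fit.coef("noise")) < 3 * fit.coef_se("noise")

    def test_separation_detected(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_logistic(x[:, None], y, names=["sep"])

    def test_rank_deficiency_names_columns(self):
        X, y, _ = simulate(3)
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(RankDeficiencyError, match="x3"):
            fit_logistic(X, y, names=["x0", "x1", "x2", "x3"])

    def test_loglik_not_below_null_model(self):
        X, y, _ = simulate(7)
        fit = fit_logistic(X, y, names=["x0", "x1", "x2"])
        p = y.mean()
        null_ll = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
        assert fit.loglik >= null_ll


class TestConditionalLogistic:
    def test_mcnemar_closed_form(self):
        """With one binary exposure, the conditional MLE is log(b/c) for b
        case-exposed-only and c control-exposed-only discordant pairs."""
        d = np.repeat([1.0, -1.0, 0.0], [12, 5, 20])[:, None]
        fit = fit_conditional_logistic(d, names=["exposure"])
        assert fit.coef("exposure") == pytest.approx(np.log(12 / 5), abs=1e-7)
        assert fit.n_dropped_concordant == 20
        assert fit.n == 17

    def test_swapping_case_and_control_negates_estimate(self):
        rng = np.random.default_rng(21)
        d = rng.normal(size=(40, 2)) + 0.3
        fit = fit_conditional_logistic(d, names=["a", "b"])
        fit_swapped = fit_conditional_logistic(-d, names=["a", "b"])
        assert np.allclose(fit_swapped.beta, -fit.beta, atol=1e-8)

    def test_all_concordant_is_error(self):
        with pytest.raises(ValueError, match="discordant"):
            fit_conditional_logistic(np.zeros((5, 1)), names=["x"])

    def test_agrees_with_statsmodels_conditional_logit(self):
        rng = np.random.default_rng(31)
        n_pairs = 150
        x_case = rng.normal(size=(n_pairs, 2)) + [0.4, 0.0]
        x_ctrl = rng.normal(size=(n_pairs, 2))
        fit = fit_conditional_logistic(x_case - x_ctrl, names=["a", "b"])
        X = np.vstack([x_case, x_ctrl])
        y = np.r_[np.ones(n_pairs), np.zeros(n_pairs)]
        groups = np.r_[np.arange(n_pairs), np.arange(n_pairs)]
        ref = ConditionalLogit(y, X, groups=groups).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-4)
        assert np.allclose(fit.se, ref.bse, atol=1e-4)


class TestModelReport:
    def test_inverted_reference_interval(self):
        from obesnp.regression import RegressionFit

        fit = RegressionFit(
            names=["snp_dominant"],
            beta=np.array([0.4762]),
            cov=np.array([[0.188**2]]),
            loglik=0.0,
            n=100,
            converged=True,
            n_iter=3,
        )
        row = model_report(fit).iloc[0]
        assert round(row["or"], 2) == 1.61
        assert round(row["ci_low"], 2) == 1.11
        assert round(row["ci_high"], 2) == 2.33

    def test_null_term(self):
        from obesnp.regression import RegressionFit

        fit = RegressionFit(
            names=["x"], beta=np.array([0.0]), cov=np.array([[1.0]]),
            loglik=0.0, n=10, converged=True, n_iter=1,
        )
        row = model_report(fit).iloc[0]
        assert row["or"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)
        assert round(row["ci_low"], 2) == 0.14
        assert round(row["ci_high"], 2) == 7.10

    def test_nonconverged_fit_rejected(self):
        from obesnp.regression import RegressionFit

        fit = RegressionFit(
            names=["x"], beta=np.array([0.0]), cov=np.array([[1.0]]),
            loglik=0.0, n=10, converged=False, n_iter=50,
        )
        with pytest.raises(ValueError, match="converged"):
            model_report(fit)


class TestBuildDesign:
    def test_reference_levels_and_dummy_names(self):
        frame = pd.DataFrame(
            {
                "sex": ["female", "male"],
                "smoking": ["never", "current"],
                "age_band": ["20-29", "50-59"],
            }
        )
        design = build_design(frame, ["sex", "smoking", "age_band"])
        assert list(design.columns) == [
            "sex_male",
            "smoking_former",
            "smoking_current",
            "age_band_30_39",
            "age_band_40_49",
            "age_band_50_59",
            "age_band_60_80",
        ]
        assert design.iloc[0].tolist() == [0, 0, 0, 0, 0, 0, 0]
        assert design.iloc[1].tolist() == [1, 0, 1, 0, 0, 1, 0]

    def test_unknown_level_rejected(self):
        frame = pd.DataFrame({"sex": ["female", "robot"]})
        with pytest.raises(ValueError, match="unknown levels"):
            build_design(frame, ["sex"])
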