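"""Bivariate logistic regression: likelihood, fitting, odds-ratio tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from nutrilink import synthdata
from nutrilink.bivlogit import (
    DesignMatrix,
    adjusted_odds_ratios,
    fit,
    log_likelihood,
    marginal_probability,
    predict_joint,
)
from nutrilink.plackett import joint_cell_probabilities


class TestMarginalProbability:
    @pytest.mark.parametrize(
        "eta,expected",
        [(0.0, 0.5), (np.log(3), 0.75), (700.0, 1.0)],
    )
    def test_closed_forms(self, eta, expected):
        assert marginal_probability([eta], [1.0]) == pytest.approx(expected)

    def test_large_negative_predictor_does_not_underflow(self):
        p = marginal_probability([-50.0], [1.0])
        assert 0 < p < 1e-20
        # exp(-50)/(1+exp(-50)) to high precision
        assert p == pytest.approx(np.exp(-50) / (1 + np.exp(-50)), rel=1e-12)

    def test_logit_inverts(self):
        x = np.array([1.0, 2.0, -0.5])
        beta = np.array([0.3, -0.2, 1.1])
        assert logit(marginal_probability(x, beta)) == pytest.approx(x @ beta)


class TestLogLikelihood:
    def test_single_row_independent_half(self):
        d = DesignMatrix(np.ones((1, 1)), ["intercept"])
        for cell in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            ll = log_likelihood(np.zeros(3), d, np.array([cell]))
            assert ll == pytest.approx(np.log(0.25))

    def test_intercept_only_equals_multinomial(self, joint_outcomes, intercept_design):
        """At the empirical (pi1, pi2, OR) the joint log-likelihood equals
        the multinomial log-likelihood of the observed 2x2 counts."""
        y = joint_outcomes
        n = len(y)
        pi1, pi2 = y[:, 0].mean(), y[:, 1].mean()
        counts = {
            c: np.sum((y[:, 0] == c[0]) & (y[:, 1] == c[1]))
            for c in [(1, 1), (1, 0), (0, 1), (0, 0)]
        }
        or_hat = (
            counts[(1, 1)] * counts[(0, 0)] / (counts[(1, 0)] * counts[(0, 1)])
        )
        params = np.array([logit(pi1), logit(pi2), np.log(or_hat)])
        ll = log_likelihood(params, intercept_design, y)
        cells = joint_cell_probabilities(pi1, pi2, or_hat)
        labels = [(1, 1), (1, 0), (0, 1), (0, 0)]
        multinomial = sum(
            counts[lab] * np.log(p) for lab, p in zip(labels, cells)
        )
        assert ll == pytest.approx(multinomial, abs=1e-8)
        _ = n

    def test_duplicating_rows_doubles_loglik(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = np.column_stack([rng.integers(0, 2, 50), rng.integers(0, 2, 50)])
        d1 = DesignMatrix(x, ["intercept", "x"])
        d2 = DesignMatrix(np.vstack([x, x]), ["intercept", "x"])
        params = np.array([0.2, -0.4, 0.1, 0.3, 0.5])
        assert log_likelihood(params, d2, np.vstack([y, y])) == pytest.approx(
            2 * log_likelihood(params, d1, y)
        )


class TestFit:
    def test_saturated_intercept_only_reproduces_empirical_table(
        self, joint_outcomes, intercept_design
    ):
        """Intercept-only MLE equals empirical margins and count-based OR."""
        res = fit(intercept_design, joint_outcomes)
        assert res.converged
        assert expit(res.beta1[0]) == pytest.approx(1482 / 3206, abs=1e-6)
        assert expit(res.beta2[0]) == pytest.approx(651 / 3206, abs=1e-6)
        assert res.psi == pytest.approx((371 * 1444) / (1111 * 280), abs=1e-6)

    def test_independence_reduction_matches_univariate_glm(self):
        """With log psi frozen at 0 the betas equal separate univariate
        logistic MLEs (statsmodels as the independent oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        n = 3000
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        d = DesignMatrix(x, ["intercept", "a", "b"])
        y = synthdata.generate_outcomes(
            d, np.array([-0.4, 0.5, 0.2]), np.array([-1.0, 0.3, -0.4]), 1.6, seed=4
        )
        res = fit(d, y, fix_log_psi=0.0)
        for j, col in enumerate(["anemia", "undernutrition"]):
            glm = sm.GLM(y[col].to_numpy(), x, family=sm.families.Binomial()).fit()
            mine = res.beta1 if j == 0 else res.beta2
            assert np.allclose(mine, glm.params, atol=1e-6)

    def test_pattern_cell_probabilities_match_brute_force(self, two_covariate_design):
        """Fitted cell probabilities per covariate pattern agree with an
        independent brute-force maximization (scipy Nelder-Mead + BFGS) of
        the pattern-aggregated multinomial likelihood."""
        d = two_covariate_design
        b1 = np.array([logit(0.462), -0.29, 0.15])
        b2 = np.array([logit(0.205), -0.41, 0.51])
        y = synthdata.generate_outcomes(d, b1, b2, 1.729, seed=7)
        res = fit(d, y)
        assert res.converged

        df = pd.DataFrame(d.matrix[:, 1:], columns=["u", "v"])
        df["y1"], df["y2"] = y["anemia"], y["undernutrition"]
        agg = df.groupby(["u", "v", "y1", "y2"]).size()
        patterns = sorted({(u, v) for u, v, _, _ in agg.index})

        def negll(theta):
            t1, t2, lp = theta[:3], theta[3:6], theta[6]
            total = 0.0
            for u, v in patterns:
                xr = np.array([1.0, u, v])
                cells = joint_cell_probabilities(
                    expit(xr @ t1), expit(xr @ t2), np.exp(lp)
                )
                for lab, pc in zip([(1, 1), (1, 0), (0, 1), (0, 0)], cells):
                    c = agg.get((u, v) + lab, 0)
                    if c:
                        total -= c * np.log(pc)
            return total

        rough = minimize(negll, np.zeros(7), method="Nelder-Mead",
                         options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        oracle = minimize(negll, rough.x, method="BFGS", options={"gtol": 1e-10})
        for u, v in patterns:
            xr = np.array([1.0, u, v])
            mine = joint_cell_probabilities(
                expit(xr @ res.beta1), expit(xr @ res.beta2), res.psi
            )
            ref = joint_cell_probabilities(
                expit(xr @ oracle.x[:3]), expit(xr @ oracle.x[3:6]),
                np.exp(oracle.x[6]),
            )
            assert np.allclose(mine, ref, atol=1e-6)

    def test_weights_act_as_frequency_weights(self):
        """Duplicating a row is equivalent to doubling its weight."""
        rng = np.random.default_rng(8)
        n = 400
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = synthdata.generate_outcomes(
            DesignMatrix(x, ["intercept", "a"]),
            np.array([-0.2, 0.4]), np.array([-1.1, 0.5]), 1.5, seed=9,
        ).to_numpy()
        dup = DesignMatrix(np.vstack([x, x[:100]]), ["intercept", "a"])
        wts = np.ones(n)
        wts[:100] = 2.0
        weighted = DesignMatrix(x, ["intercept", "a"], weights=wts)
        res_dup = fit(dup, np.vstack([y, y[:100]]))
        res_w = fit(weighted, y)
        assert np.allclose(res_dup.params, res_w.params, atol=1e-6)

    def test_requires_both_outcome_levels(self):
        d = DesignMatrix(np.ones((50, 1)), ["intercept"])
        y = np.column_stack([np.ones(50), np.random.default_rng(0).integers(0, 2, 50)])
        with pytest.raises(ValueError, match="both levels"):
            fit(d, y)

    def test_likelihood_at_optimum_not_improvable(self, joint_outcomes, intercept_design):
        res = fit(intercept_design, joint_outcomes)
        base = log_likelihood(res.params, intercept_design, joint_outcomes)
        rng = np.random.default_rng(5)
        for _ in range(20):
            perturbed = res.params + rng.normal(scale=1e-3, size=3)
            assert log_likelihood(perturbed, intercept_design, joint_outcomes) <= base + 1e-9


class TestAdjustedOddsRatios:
    def test_zero_coefficient_gives_unit_aor(self, joint_outcomes, intercept_design):
        res = fit(intercept_design, joint_outcomes)
        table = adjusted_odds_ratios(res)
        assert set(table.columns) >= {"aor", "ci_low", "ci_high", "p_value"}
        assert ((table.ci_low <= table.aor + 1e-12)
                & (table.aor <= table.ci_high + 1e-12)).all()

    def test_published_ci_is_self_consistent(self):
        """Inverting a printed AOR row 0.751 (0.573, 0.984) to (beta, SE) and
        recomputing reproduces the interval."""
        beta = np.log(0.751)
        se = (np.log(0.984) - np.log(0.573)) / (2 * 1.959963984540054)
        assert beta == pytest.approx(-0.2864, abs=5e-4)
        assert se == pytest.approx(0.1380, abs=5e-4)
        lo, hi = np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se)
        assert np.exp(beta) == pytest.approx(0.751, abs=1e-3)
        assert lo == pytest.approx(0.573, abs=1e-3)
        assert hi == pytest.approx(0.984, abs=1e-3)


class TestPredictJoint:
    def test_intercept_only_constant_and_margin_consistent(
        self, joint_outcomes, intercept_design
    ):
        res = fit(intercept_design, joint_outcomes)
        cells = predict_joint(res, intercept_design)
        assert np.allclose(cells, cells[0])
        # MLE score equation: average p11 equals empirical joint frequency
        emp = np.mean((joint_outcomes[:, 0] == 1) & (joint_outcomes[:, 1] == 1))
        assert cells[:, 0].mean() == pytest.approx(emp, abs=1e-8)
        assert np.allclose(cells.sum(axis=1), 1.0, atol=1e-12)

    def test_psi_one_factorizes(self, two_covariate_design):
        d = two_covariate_design
        y = synthdata.generate_outcomes(
            d, np.array([0.0, 0.3, -0.2]), np.array([-1.0, 0.2, 0.4]), 1.0, seed=2
        )
        res = fit(d, y, fix_log_psi=0.0)
        cells = predict_joint(res, d)
        pi1 = expit(d.matrix @ res.beta1)
        pi2 = expit(d.matrix @ res.beta2)
        assert np.allclose(cells[:, 0], pi1 * pi2, atol=1e-12)

    def test_column_mismatch_raises(self, joint_outcomes, intercept_design):
        res = fit(intercept_design, joint_outcomes)
        other = DesignMatrix(np.ones((10, 1)), ["const"])
        with pytest.raises(ValueError, match="columns"):
            predict_joint(res, other)


class TestDesignMatrix:
    def test_dummy_coding_with_reference_levels(self):
        df = pd.DataFrame(
            {"residence": ["rural", "urban", "rural"], "sex": ["m", "f", "m"]}
        )
        d = DesignMatrix.from_dataframe(
            df, ["residence", "sex"], reference_levels={"sex": "f"}
        )
        assert d.column_names == ["intercept", "residence=urban", "sex=m"]
        assert d.reference_levels == {"residence": "rural", "sex": "f"}
        assert np.allclose(d.matrix[:, 1], [0, 1, 0])
        assert np.allclose(d.matrix[:, 2], [1, 0, 1])

    def test_weights_normalized_to_mean_one(self):
        d = DesignMatrix(
            np.ones((4, 1)), ["intercept"], weights=np.array([1.0, 2.0, 3.0, 2.0])
        )
        assert d.weights.sum() == pytest.approx(4.0)

    def test_intercept_required(self):
        with pytest.raises(ValueError, match="intercept"):
            DesignMatrix(np.zeros((3, 1)), ["x"])
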