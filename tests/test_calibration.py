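"""Regression families, error metrics, correlation matrix, model selection."""

import numpy as np
import pandas as pd
import pytest

from grasslidar.calibration import (RegressionModel, fit_model, fit_multiple,
                                    pearson_matrix, rmse, rrmse, select_best,
                                    train_test_split)


class TestSplit:
    def test_66_24_partition(self, rng):
        records = pd.DataFrame({"v": np.arange(90)})
        tr, te = train_test_split(records, n_train=66, seed=1)
        assert len(tr) == 66 and len(te) == 24
        union = sorted(tr["v"].tolist() + te["v"].tolist())
        assert union == list(range(90))

    def test_seed_reproducible(self):
        records = list(range(30))
        a = train_test_split(records, n_train=20, seed=7)
        b = train_test_split(records, n_train=20, seed=7)
        assert a == b

    def test_oversized_train_fails(self):
        with pytest.raises(ValueError):
            train_test_split(list(range(10)), n_train=10, seed=0)


class TestFitModel:
    def test_exact_line_recovered(self):
        x = np.arange(1.0, 11.0)
        m = fit_model(x, 2 * x + 1, "linear")
        assert m.coefficients == pytest.approx((2.0, 1.0), abs=1e-10)
        assert m.r_squared == pytest.approx(1.0)

    def test_constant_response_zero_r2(self):
        m = fit_model(np.arange(10.0), np.full(10, 3.0), "linear")
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert m.r_squared == 0.0

    @pytest.mark.parametrize("family,coef", [
        ("logarithmic", (2.0, 5.0)),
        ("power", (3.0, 0.7)),
        ("exponential", (10.0, 0.15)),
    ])
    def test_nonlinear_families_recover_exact_data(self, family, coef):
        x = np.linspace(1.0, 9.0, 25)
        m0 = RegressionModel(family=family, coefficients=coef, r_squared=1.0)
        m = fit_model(x, m0.predict(x), family)
        assert m.coefficients == pytest.approx(coef, rel=1e-6)

    def test_domain_violation_names_family(self):
        x = np.array([-1.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="power"):
            fit_model(x, x + 1, "power")
        with pytest.raises(ValueError, match="logarithmic"):
            fit_model(x, x + 1, "logarithmic")

    def test_slope_recovery_within_confidence_interval(self, rng):
        """Simulated biomass line (published slope/intercept) is recovered
        within the 95 % slope CI in nearly all of 20 replicates."""
        hits = 0
        for _ in range(20):
            x = rng.uniform(1, 12, 66)
            y = 34.785 * x + 7.081 + rng.normal(0, 20, 66)
            m = fit_model(x, y, "linear")
            # 95% CI from the standard OLS slope variance
            xc = x - x.mean()
            resid = y - m.predict(x)
            se = np.sqrt(resid @ resid / (66 - 2) / (xc @ xc))
            hits += int(abs(m.coefficients[0] - 34.785) < 1.96 * se)
        assert hits >= 17


class TestMultiple:
    def test_redundant_predictor_near_zero_coefficient(self, rng):
        x1 = rng.uniform(0, 10, 50)
        x2 = rng.normal(0, 1, 50)
        m = fit_multiple(x1, x2, x1)
        assert m.coefficients[0] == pytest.approx(1.0, abs=1e-8)
        assert m.coefficients[1] == pytest.approx(0.0, abs=1e-8)
        assert m.r_squared == pytest.approx(1.0)

    def test_collinear_predictors_warn(self, rng):
        x1 = rng.uniform(0, 10, 50)
        x2 = x1 * 1.0001 + rng.normal(0, 1e-4, 50)
        with pytest.warns(UserWarning, match="collinear"):
            fit_multiple(x1, x2, x1 + rng.normal(0, 1, 50))

    def test_correlated_predictor_adds_little(self, rng):
        """At the published MeanCH-FVC correlation (~0.96) the second
        predictor barely moves R^2."""
        n = 66
        z = rng.normal(0, 1, n)
        x1 = z + rng.normal(0, 0.29, n)          # corr(x1, x2) ~ 0.96
        x2 = z + rng.normal(0, 0.29, n)
        y = 3 * z + rng.normal(0, 1.0, n)
        single = fit_model(x1, y, "linear")
        multi = fit_multiple(x1, x2, y)
        assert np.corrcoef(x1, x2)[0, 1] > 0.9
        assert multi.r_squared - single.r_squared < 0.1


class TestErrorMetrics:
    def test_rmse_identity_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_closed_form(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_matches_enumeration(self, rng):
        y, yhat = rng.normal(0, 10, (2, 100))
        expect = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 100)
        assert rmse(y, yhat) == pytest.approx(expect, abs=1e-12)

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_rrmse_published_values(self):
        assert round(rrmse(81.89, 582.5), 1) == 14.1
        assert rrmse(0.0, 582.5) == 0.0
        assert rrmse(81.85, 582.5) == pytest.approx(14.06, abs=0.015)

    def test_rrmse_requires_positive_max(self):
        with pytest.raises(ValueError):
            rrmse(5.0, 0.0)

    def test_rrmse_linear_in_rmse(self, rng):
        r = rng.uniform(0, 100)
        assert rrmse(2 * r, 582.5) == pytest.approx(2 * rrmse(r, 582.5))


class TestPearson:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        t = pd.DataFrame({"a": x, "b": -x})
        m = pearson_matrix(t)
        assert m.loc["a", "a"] == pytest.approx(1.0)
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_definitional_computation(self, rng):
        t = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        m = pearson_matrix(t)
        for i in "abc":
            for j in "abc":
                xi, xj = t[i] - t[i].mean(), t[j] - t[j].mean()
                expect = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert m.loc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        t = pd.DataFrame({"a": rng.normal(0, 1, 10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            m = pearson_matrix(t)
        assert np.isnan(m.loc["a", "b"])


class TestSelectBest:
    def _model(self, rmse_v, r2, n_coef=2):
        return RegressionModel(family="linear", coefficients=(1.0,) * n_coef,
                               r_squared=r2, rmse=rmse_v)

    def test_single_candidate(self):
        m = self._model(10.0, 0.5)
        assert select_best([m])[0] is m

    def test_lower_test_rmse_wins(self):
        a, b = self._model(81.89, 0.340), self._model(87.96, 0.157)
        assert select_best([b, a])[0] is a

    def test_tie_breaks_on_r2_then_parameters(self):
        a, b = self._model(80.0, 0.341), self._model(80.0, 0.340)
        assert select_best([b, a])[0] is a
        c, d = self._model(80.0, 0.34, 2), self._model(80.0, 0.34, 3)
        assert select_best([d, c])[0] is c

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            select_best([])
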