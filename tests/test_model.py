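"""Logistic modelling: screening, VIF, fit identities, stepwise, ROC/AUC."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import auc_pair_count
from kounispv.errors import SeparationError
from kounispv.model import (
    FeatureMatrix,
    auc_mann_whitney,
    fit_logistic,
    model_metrics,
    roc_auc_trapezoid,
    roc_curve,
    select_candidates,
    stepwise_select,
    univariate_screen,
    vif_screen,
)


def _fm_from_table(a, b, c, d):
    """Rows for a 2x2 predictor-vs-label table: a/b = KS with/without the
    flag, c/d = non-KS with/without."""
    x = [1] * a + [0] * b + [1] * c + [0] * d
    y = [0] * (a + b) + [1] * (c + d)
    return FeatureMatrix(X=pd.DataFrame({"flag": x}), y=np.array(y, dtype=float))


class TestUnivariateScreen:
    def test_cardiac_table_screens_in(self):
        fm = _fm_from_table(41, 89, 54, 61)
        screen = dict(univariate_screen(fm))
        assert screen["flag"] < 0.05
        assert select_candidates(list(screen.items())) == ["flag"]

    def test_balanced_prevalence_is_null(self):
        fm = _fm_from_table(5, 15, 5, 15)
        assert dict(univariate_screen(fm))["flag"] == pytest.approx(1.0)

    def test_constant_column_excluded(self, caplog):
        fm = FeatureMatrix(
            X=pd.DataFrame({"const": [1, 1, 1, 1], "ok": [0, 1, 0, 1]}),
            y=np.array([0, 0, 1, 1.0]),
        )
        names = [n for n, _ in univariate_screen(fm)]
        assert names == ["ok"]

    def test_planted_association_screened_in(self):
        rng = np.random.default_rng(5)
        n = 2000
        y = rng.random(n) < 0.5
        x = np.where(y, rng.random(n) < 0.6, rng.random(n) < 0.3)
        noise = rng.random(n) < 0.4
        fm = FeatureMatrix(
            X=pd.DataFrame({"signal": x.astype(int), "noise": noise.astype(int)}),
            y=y.astype(float),
        )
        assert "signal" in select_candidates(univariate_screen(fm))


class TestVifScreen:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame(
            {
                "a": [1, 1, 0, 0, 1, 1, 0, 0],
                "b": [1, 0, 1, 0, 1, 0, 1, 0],
            }
        )
        fm = FeatureMatrix(X=X, y=np.zeros(8))
        retained, vifs = vif_screen(fm, ["a", "b"])
        assert retained == ["a", "b"]
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in vifs.values())

    def test_known_correlation_gives_closed_form_vif(self):
        """r = 0.6 between two columns implies VIF = 1/(1-0.36) = 1.5625."""
        n = 100
        t = np.arange(n)
        z1 = np.cos(2 * np.pi * t / n)
        z2 = np.sin(2 * np.pi * t / n)
        z1, z2 = z1 / np.linalg.norm(z1), z2 / np.linalg.norm(z2)
        X = pd.DataFrame({"x1": z1, "x2": 0.6 * z1 + 0.8 * z2})
        fm = FeatureMatrix(X=X, y=np.zeros(n))
        _, vifs = vif_screen(fm, ["x1", "x2"])
        assert vifs["x1"] == pytest.approx(1.5625, rel=1e-9)
        assert vifs["x2"] == pytest.approx(1.5625, rel=1e-9)

    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        X = pd.DataFrame({"a": a, "a_copy": a, "b": b})
        fm = FeatureMatrix(X=X, y=np.zeros(50))
        retained, vifs = vif_screen(fm, ["a", "a_copy", "b"])
        assert len(retained) == 2 and "b" in retained
        assert max(vifs.values()) < 5


class TestFitLogistic:
    def test_univariate_or_equals_cross_product_ratio(self):
        """Saturated 2x2 logistic MLE equals the sample odds ratio."""
        fm = _fm_from_table(41, 89, 54, 61)
        fit = fit_logistic(fm, ["flag"], ci="wald")
        assert fit.table[0].odds_ratio == pytest.approx(
            (54 * 89) / (41 * 61), rel=1e-6
        )

    def test_all_zero_predictor_raises(self):
        fm = FeatureMatrix(
            X=pd.DataFrame({"z": [0, 0, 0, 0]}), y=np.array([0, 1, 0, 1.0])
        )
        with pytest.raises(SeparationError, match="z"):
            fit_logistic(fm, ["z"])

    def test_complete_separation_raises_naming_column(self):
        fm = FeatureMatrix(
            X=pd.DataFrame({"sep": [0] * 20 + [1] * 20}),
            y=np.array([0.0] * 20 + [1.0] * 20),
        )
        with pytest.raises(SeparationError, match="sep"):
            fit_logistic(fm, ["sep"])

    def test_coefficient_recovery_from_known_model(self):
        rng = np.random.default_rng(21)
        n = 5000
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        x3 = rng.integers(0, 2, n).astype(float)
        eta = -0.5 + 1.0 * x1 - 1.0 * x2 + 0.0 * x3
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fm = FeatureMatrix(X=pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}), y=y)
        fit = fit_logistic(fm, ["x1", "x2", "x3"], ci="wald")
        for var, true_beta in zip(fit.table, (1.0, -1.0, 0.0)):
            assert abs(var.coef - true_beta) < 3 * var.se

    def test_profile_ci_contains_mle_and_not_narrower_than_wald(self):
        fm = _fm_from_table(12, 118, 24, 91)  # diabetes-style counts
        fit = fit_logistic(fm, ["flag"], ci="profile")
        v = fit.table[0]
        assert v.ci_low < v.odds_ratio < v.ci_high
        wald_width = math.log(v.wald_ci_high) - math.log(v.wald_ci_low)
        prof_width = math.log(v.ci_high) - math.log(v.ci_low)
        assert prof_width > 0.8 * wald_width


class TestStepwise:
    @staticmethod
    def _informative_plus_nulls(seed=3, n=2000, n_null=9):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        eta = -1.0 + 2.0 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cols = {"informative": x}
        for i in range(n_null):
            cols[f"null{i}"] = rng.integers(0, 2, n).astype(float)
        return FeatureMatrix(X=pd.DataFrame(cols), y=y)

    def test_recovers_informative_variable(self):
        fm = self._informative_plus_nulls()
        fit = stepwise_select(fm, list(fm.X.columns))
        assert "informative" in fit.variables
        assert len(fit.variables) <= 3  # AICc admits few null variables

    def test_zero_candidates_gives_intercept_only(self):
        fm = self._informative_plus_nulls()
        fit = stepwise_select(fm, [])
        assert fit.variables == []
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_candidate_retained_once(self):
        fm = self._informative_plus_nulls(n_null=2)
        X = fm.X.copy()
        X["informative_copy"] = X["informative"]
        fm2 = FeatureMatrix(X=X, y=fm.y)
        fit = stepwise_select(fm2, list(fm2.X.columns))
        assert not {"informative", "informative_copy"} <= set(fit.variables)
        assert {"informative", "informative_copy"} & set(fit.variables)

    def test_invariant_to_candidate_order(self):
        fm = self._informative_plus_nulls(seed=8, n=800, n_null=5)
        cols = list(fm.X.columns)
        fit1 = stepwise_select(fm, cols)
        fit2 = stepwise_select(fm, cols[::-1])
        assert fit1.variables == fit2.variables


class TestMetricsAndRoc:
    def test_perfect_separation_scores_auc_one(self):
        assert auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_worked_auc_example(self):
        assert auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_ties_get_half_credit(self):
        assert auc_mann_whitney([0.5, 0.5], [0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_roc_staircase_perfect(self):
        pts = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert roc_auc_trapezoid(pts) == 1.0

    def test_constant_scores_give_diagonal(self):
        pts = roc_curve([0.5] * 10, [0, 1] * 5)
        assert roc_auc_trapezoid(pts) == pytest.approx(0.5, abs=1e-12)

    def test_trapezoid_equals_mann_whitney_equals_pair_count(self):
        rng = np.random.default_rng(17)
        for n in (10, 57, 200):
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc = auc_mann_whitney(scores, labels)
            assert auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)
            assert auc == pytest.approx(
                roc_auc_trapezoid(roc_curve(scores, labels)), abs=1e-12
            )

    def test_null_model_metrics(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100).astype(float)
        fm = FeatureMatrix(X=pd.DataFrame({"x": rng.integers(0, 2, 100)}), y=y)
        fit = fit_logistic(fm, [], ci="none")
        m = model_metrics(fit, fm)
        assert m["pseudo_r2"] == pytest.approx(0.0, abs=1e-12)
        assert m["aicc"] > 0 and m["bic"] > 0
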