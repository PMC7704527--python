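"""Validation statistics, collinearity diagnostics and applicability domain."""

import numpy as np
import pandas as pd
import pytest

from qsarlab import (
    DomainError,
    LinearModel,
    adjusted_r2,
    correlation_matrix,
    evaluate_against_criteria,
    external_r2pred,
    fit_ols,
    leverage,
    mean_effect,
    q2_loo,
    r_squared,
    vif,
    warning_leverage,
    williams_data,
)
from qsarlab.validation import ExternalValidation, InternalValidation


class TestRSquared:
    def test_perfect(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_arithmetic(self):
        assert r_squared([1, 2, 3], [1, 2, 4], ref_mean=2.0) == pytest.approx(0.5)

    def test_printed_external_value(self, validation_set):
        r2 = r_squared(
            validation_set["pic50"],
            validation_set["y_pred_printed"],
            ref_mean=4.5364,
        )
        assert r2 == pytest.approx(0.5357, abs=1e-3)

    def test_zero_sst(self):
        with pytest.raises(DomainError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestAdjustedR2:
    def test_perfect_fit_unchanged(self):
        assert adjusted_r2(1.0, 27, 4) == 1.0

    def test_reproduces_printed_value(self):
        assert adjusted_r2(0.6981, 27, 4) == pytest.approx(0.6433, abs=1e-3)

    def test_hand_arithmetic(self):
        assert adjusted_r2(0.5, 12, 4) == pytest.approx(1 - 0.5 * 11 / 7)

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            adjusted_r2(0.9, 5, 4)


def naive_q2_loo(X, y):
    """Literally refit n times, once per held-out compound."""
    press = 0.0
    for cid in X.index:
        keep = X.index != cid
        model, _ = fit_ols(X.loc[keep], y.loc[keep])
        press += float(y[cid] - model.predict(X.loc[[cid]]).iloc[0]) ** 2
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / sst


class TestQ2Loo:
    def test_noiseless_is_one(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 2)), columns=["a", "b"])
        y = 1.0 + 2 * X["a"] - X["b"]
        assert q2_loo(X, y) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n,seed", [(6, 0), (15, 1), (30, 2)])
    def test_equals_naive_refit_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, 2)),
            columns=["a", "b"],
            index=[f"c{i}" for i in range(n)],
        )
        y = pd.Series(
            1 + X["a"] - 0.5 * X["b"] + rng.standard_normal(n) * 0.3,
            index=X.index,
        )
        assert q2_loo(X, y) == pytest.approx(naive_q2_loo(X, y), abs=1e-10)

    def test_constant_activity_errors(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        with pytest.raises(DomainError):
            q2_loo(X, pd.Series(np.ones(10), index=X.index))


class TestExternalR2Pred:
    def test_printed_sums(self, validation_set):
        ext = external_r2pred(
            validation_set["pic50"], validation_set["y_pred_printed"], 4.5364
        )
        assert ext.ss_res == pytest.approx(0.713008, abs=2e-4)
        assert ext.ss_tot == pytest.approx(1.535707, abs=2e-4)
        assert ext.r2_pred == pytest.approx(0.5357, abs=1e-3)
        # decomposition holds to machine precision
        assert ext.r2_pred == pytest.approx(
            1 - ext.ss_res / ext.ss_tot, rel=1e-15
        )

    def test_mean_predictions_score_zero(self):
        ext = external_r2pred([4.0, 5.0], [4.5, 4.5], 4.5)
        assert ext.r2_pred == pytest.approx(0.0)

    def test_perfect_predictions(self):
        ext = external_r2pred([4.0, 5.0], [4.0, 5.0], 4.5)
        assert ext.r2_pred == 1.0


class TestMeanEffect:
    def test_single_descriptor(self, rng):
        model = LinearModel(("a",), (2.5,), 0.0)
        D = pd.DataFrame({"a": rng.standard_normal(8)})
        assert mean_effect(model, D)["a"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        model = LinearModel(("a", "b"), (2.0, -1.0), 0.0)
        D = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 3.0]})
        me = mean_effect(model, D)
        assert me["a"] == pytest.approx(3.0)
        assert me["b"] == pytest.approx(-2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_sums_to_one_and_permutes(self, seed):
        rng = np.random.default_rng(seed)
        names = ("a", "b", "c")
        model = LinearModel(names, tuple(rng.standard_normal(3)), 0.5)
        D = pd.DataFrame(rng.standard_normal((10, 3)), columns=names)
        me = mean_effect(model, D)
        assert me.sum() == pytest.approx(1.0, abs=1e-9)
        perm = ("c", "a", "b")
        model_p = LinearModel(
            perm, tuple(dict(zip(names, model.coefficients))[d] for d in perm),
            0.5,
        )
        me_p = mean_effect(model_p, D)
        for d in names:
            assert me_p[d] == pytest.approx(me[d], rel=1e-12)


class TestVif:
    def test_orthogonal_pair(self):
        D = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]},
                         dtype=float)
        assert vif(D).tolist() == pytest.approx([1.0, 1.0])

    def test_closed_form_r08(self):
        # b = 0.8 a + 0.6 w with w orthogonal to a: sample correlation 0.8
        a = np.array([1.0, 1.0, -1.0, -1.0])
        w = np.array([1.0, -1.0, 1.0, -1.0])
        D = pd.DataFrame({"a": a, "b": 0.8 * a + 0.6 * w})
        expected = 1 / (1 - 0.64)
        assert vif(D).tolist() == pytest.approx([expected, expected])

    def test_duplicate_descriptor_is_inf(self, rng):
        a = rng.standard_normal(10)
        D = pd.DataFrame({"a": a, "b": a})
        assert np.isinf(vif(D)).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_never_below_one(self, seed):
        rng = np.random.default_rng(seed)
        D = pd.DataFrame(rng.standard_normal((15, 4)), columns=list("abcd"))
        assert (vif(D) >= 1 - 1e-12).all()


class TestCorrelationMatrix:
    def test_diagonal_and_antisymmetry(self, rng):
        x = rng.standard_normal(10)
        D = pd.DataFrame({"x": x, "neg": -x + 0.0, "y": rng.standard_normal(10)})
        corr = correlation_matrix(D)
        assert np.diag(corr) == pytest.approx([1.0, 1.0, 1.0])
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)
        assert corr.equals(corr.T)

    def test_matches_definition_oracle(self, rng):
        D = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        corr = correlation_matrix(D)
        V = D.values - D.values.mean(0)
        manual = (V.T @ V) / np.outer(
            np.sqrt((V**2).sum(0)), np.sqrt((V**2).sum(0))
        )
        np.testing.assert_allclose(corr.values, manual, atol=1e-12)

    def test_zero_variance_errors(self):
        D = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(DomainError, match="b"):
            correlation_matrix(D)


class TestLeverage:
    def test_closed_form_three_points(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        h = leverage(X)
        assert h.tolist() == pytest.approx([5 / 6, 1 / 3, 5 / 6])

    @pytest.mark.parametrize("seed,p", [(0, 2), (1, 4), (2, 3)])
    def test_trace_identity(self, seed, p):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((20, p)))
        h = leverage(X)
        assert h.sum() == pytest.approx(p + 1, abs=1e-8)
        assert ((h >= 0) & (h <= 1 + 1e-12)).all()

    def test_extreme_point_has_largest_leverage(self):
        X = pd.DataFrame({"x": [1.0, 1.001, 0.999, 1.0, 9.0]})
        h = leverage(X)
        assert h.idxmax() == 4

    def test_query_rows(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 2)), columns=["a", "b"])
        far = pd.DataFrame({"a": [50.0], "b": [-50.0]}, index=["far"])
        assert leverage(X, far)["far"] > 1.0


class TestWarningLeverage:
    @pytest.mark.parametrize(
        "k,n,expected", [(4, 27, 5 / 9), (1, 6, 1.0), (2, 18, 0.5)]
    )
    def test_values(self, k, n, expected):
        assert warning_leverage(k, n) == pytest.approx(expected)

    def test_printed_two_decimals(self):
        assert round(warning_leverage(4, 27), 2) == 0.56


class TestWilliams:
    def test_clean_data_unflagged(self):
        h = pd.Series([0.1, 0.2], index=["a", "b"])
        r = pd.Series([0.0, 0.0], index=["a", "b"])
        dom = williams_data(h, r, see=0.5, h_star=0.5)
        assert dom.table["in_domain"].all()

    def test_large_residual_flagged(self):
        h = pd.Series([0.1], index=["a"])
        r = pd.Series([3.5 * 0.2], index=["a"])
        dom = williams_data(h, r, see=0.2, h_star=0.5)
        assert dom.outliers == ["a"]

    def test_boundary_leverage_not_flagged(self):
        h = pd.Series([0.5], index=["a"])
        r = pd.Series([0.0], index=["a"])
        dom = williams_data(h, r, see=0.2, h_star=0.5)
        assert dom.high_leverage == []

    def test_zero_see_with_residuals_errors(self):
        h = pd.Series([0.1], index=["a"])
        r = pd.Series([0.3], index=["a"])
        with pytest.raises(DomainError):
            williams_data(h, r, see=0.0, h_star=0.5)


def _internal(r2, q2):
    return InternalValidation(
        r2=r2, r2_adj=r2 - 0.05, see=0.2, q2_loo=q2, n_train=27,
        n_descriptors=4,
    )


def _external(r2_pred, n_test=12):
    return ExternalValidation(
        y_mintrn=4.5, ss_res=1.0, ss_tot=2.0, r2_pred=r2_pred, n_test=n_test
    )


class TestCriteria:
    def test_study_values_pass(self):
        crit = evaluate_against_criteria(
            _internal(0.6981, 0.5460), _external(0.5357, 12)
        )
        assert crit.overall_pass
        assert "p_value" in crit.not_evaluated

    def test_gap_criterion_fails(self):
        crit = evaluate_against_criteria(
            _internal(0.9, 0.5), _external(0.6)
        )
        assert not crit.verdicts["r2_q2_gap"]
        assert not crit.overall_pass

    def test_small_test_set_fails(self):
        crit = evaluate_against_criteria(
            _internal(0.7, 0.6), _external(0.6, n_test=4)
        )
        assert not crit.verdicts["n_test"]

    def test_p_value_evaluated_when_given(self):
        crit = evaluate_against_criteria(
            _internal(0.7, 0.6), _external(0.6), p_value=0.01
        )
        assert crit.verdicts["p_value"]
        assert crit.not_evaluated == []
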