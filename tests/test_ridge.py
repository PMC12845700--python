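"""Closed-form ridge readout, metrics, McNemar and Holm adjustment."""

import numpy as np
import pytest
from scipy.sparse.linalg import lsqr

from frozenemg import (
    evaluate,
    fit_ridge,
    holm_adjust,
    mcnemar_exact,
    predict,
)


def lsqr_ridge_oracle(D, Y, alpha):
    """Iterative least-squares on the augmented system [D; sqrt(a) I]."""
    n, d = D.shape
    aug = np.vstack([D, np.sqrt(alpha) * np.eye(d)])
    W = np.column_stack([
        lsqr(aug, np.concatenate([Y[:, k], np.zeros(d)]),
             atol=1e-12, btol=1e-12, iter_lim=10000)[0]
        for k in range(Y.shape[1])
    ])
    return W


class TestFitRidge:
    def test_interpolation_with_invertible_square_design(self, rng):
        D = rng.standard_normal((6, 6)) + np.eye(6)
        y = np.array([0, 1, 2, 0, 1, 2])
        model = fit_ridge(D, y, alpha=0.0, standardize=False)
        np.testing.assert_array_equal(predict(model, D), y)

    def test_matches_iterative_least_squares_oracle(self, rng):
        D = rng.standard_normal((40, 8))
        y = rng.integers(0, 3, size=40)
        alpha = 0.5
        model = fit_ridge(D, y, alpha=alpha, standardize=False)
        classes = np.unique(y)
        Y = (y[:, None] == classes[None, :]).astype(float)
        W_oracle = lsqr_ridge_oracle(D, Y, alpha)
        np.testing.assert_allclose(model.W, W_oracle, atol=1e-8)

    def test_matches_sklearn_ridge(self, rng):
        """Independent closed-form cross-check against scikit-learn."""
        from sklearn.linear_model import Ridge
        D = rng.standard_normal((30, 5))
        y = rng.integers(0, 2, size=30)
        Y = np.column_stack([(y == 0).astype(float), (y == 1).astype(float)])
        model = fit_ridge(D, y, alpha=0.7, standardize=False)
        sk = Ridge(alpha=0.7, fit_intercept=False).fit(D, Y)
        np.testing.assert_allclose(model.W, sk.coef_.T, atol=1e-8)

    def test_normal_equations_residual(self, rng):
        """The invariant ||(D'D + aI)W - D'Y|| < 1e-8 ||D'Y|| holds for
        both the primal (n >= d) and dual (n < d) solve paths."""
        for n, d in [(50, 8), (8, 50)]:
            D = rng.standard_normal((n, d))
            y = rng.integers(0, 3, size=n)
            alpha = 0.039
            model = fit_ridge(D, y, alpha=alpha, standardize=False)
            classes = np.unique(y)
            Y = (y[:, None] == classes[None, :]).astype(float)
            resid = np.linalg.norm(
                (D.T @ D + alpha * np.eye(d)) @ model.W - D.T @ Y)
            assert resid < 1e-8 * np.linalg.norm(D.T @ Y)

    def test_shrinkage_monotone_in_alpha(self, rng):
        D = rng.standard_normal((20, 6))
        y = rng.integers(0, 2, size=20)
        norms = [np.linalg.norm(
            fit_ridge(D, y, alpha=a, standardize=False).W)
            for a in [0.01, 1.0, 100.0, 1e6, 1e9]]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-6

    def test_alpha_zero_singular_uses_pseudoinverse(self, rng):
        D = np.hstack([rng.standard_normal((10, 2))] * 2)  # rank 2 of 4
        y = rng.integers(0, 2, size=10)
        model = fit_ridge(D, y, alpha=0.0, standardize=False)
        assert np.all(np.isfinite(model.W))


class TestPredict:
    def test_all_zero_row_ties_to_lowest_class(self, rng):
        D = rng.standard_normal((9, 4))
        y = np.array([5, 7, 9] * 3)
        model = fit_ridge(D, y, alpha=1.0, standardize=False)
        model.W[:] = 0.0                     # force an exact tie
        assert predict(model, np.zeros((1, 4)))[0] == 5

    def test_permuting_columns_permutes_labels(self, rng):
        D = rng.standard_normal((30, 6))
        y = rng.integers(0, 3, size=30)
        model = fit_ridge(D, y, alpha=0.1, standardize=False)
        X = rng.standard_normal((12, 6))
        base = predict(model, X)
        perm = np.array([2, 0, 1])
        import copy
        shuffled = copy.deepcopy(model)
        shuffled.W = model.W[:, perm]
        shuffled.classes = model.classes[perm]
        np.testing.assert_array_equal(predict(shuffled, X), base)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_ridge(rng.standard_normal((10, 4)),
                          rng.integers(0, 2, 10), standardize=False)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 5)))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.arange(10) % 5
        rep = evaluate(y, y)
        assert rep.acc == 100.0
        assert rep.f1 == 100.0
        assert rep.mcc == pytest.approx(100.0)

    def test_binary_confusion_hand_formulas(self):
        """TP=3, FN=1, FP=2, TN=4 evaluated against the per-metric
        formulas worked by hand."""
        true = [1] * 4 + [0] * 6
        pred = [1, 1, 1, 0] + [1, 1, 0, 0, 0, 0]
        rep = evaluate(np.array(pred), np.array(true))
        tp, fn, fp, tn = 3, 1, 2, 4
        assert rep.acc == pytest.approx(100 * (tp + tn) / 10)
        prec_pos, prec_neg = tp / (tp + fp), tn / (tn + fn)
        rec_pos, rec_neg = tp / (tp + fn), tn / (tn + fp)
        assert rep.precision == pytest.approx(
            100 * (prec_pos + prec_neg) / 2)
        assert rep.recall == pytest.approx(100 * (rec_pos + rec_neg) / 2)
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert rep.mcc == pytest.approx(100 * mcc)

    def test_matches_sklearn_metrics(self, rng):
        from sklearn.metrics import (confusion_matrix, f1_score,
                                     matthews_corrcoef, precision_score,
                                     recall_score)
        true = rng.integers(0, 4, size=200)
        pred = rng.integers(0, 4, size=200)
        rep = evaluate(pred, true)
        np.testing.assert_array_equal(rep.confusion,
                                      confusion_matrix(true, pred))
        assert rep.precision == pytest.approx(
            100 * precision_score(true, pred, average="macro",
                                  zero_division=0))
        assert rep.recall == pytest.approx(
            100 * recall_score(true, pred, average="macro"))
        assert rep.f1 == pytest.approx(
            100 * f1_score(true, pred, average="macro"))
        assert rep.mcc == pytest.approx(100 * matthews_corrcoef(true, pred))

    def test_random_predictions_give_near_zero_mcc(self):
        """Null property: uniform predictions on balanced labels."""
        mccs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            true = np.repeat(np.arange(4), 50)
            pred = rng.integers(0, 4, size=200)
            mccs.append(evaluate(pred, true).mcc / 100.0)
        assert abs(np.mean(mccs)) < 0.1

    def test_sample_order_invariance(self, rng):
        true = rng.integers(0, 3, size=60)
        pred = rng.integers(0, 3, size=60)
        perm = rng.permutation(60)
        a, b = evaluate(pred, true), evaluate(pred[perm], true[perm])
        assert a.as_dict() == b.as_dict()

    def test_label_outside_declared_classes_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0, 3]), np.array([0, 1]),
                     classes=np.array([0, 1]))


class TestMcNemar:
    def test_no_discordant_pairs(self):
        t = np.zeros(5, int)
        assert mcnemar_exact(t, t, t) == 1.0

    def test_binomial_tail_example(self):
        """b=5, c=1 gives p = 2 * (1 + 6) / 2^6 = 0.21875."""
        true = np.zeros(6, int)
        pred_a = np.array([0, 0, 0, 0, 0, 1])   # right 5, wrong on last
        pred_b = np.array([1, 1, 1, 1, 1, 0])
        assert mcnemar_exact(pred_a, pred_b, true) == pytest.approx(0.21875)

    def test_symmetry(self, rng):
        true = rng.integers(0, 2, 40)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        assert mcnemar_exact(a, b, true) == pytest.approx(
            mcnemar_exact(b, a, true))

    def test_matches_statsmodels_exact(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mc
        true = rng.integers(0, 3, 120)
        a = np.where(rng.random(120) < 0.7, true, (true + 1) % 3)
        b = np.where(rng.random(120) < 0.6, true, (true + 2) % 3)
        ra, rb = a == true, b == true
        table = [[np.sum(ra & rb), np.sum(ra & ~rb)],
                 [np.sum(~ra & rb), np.sum(~ra & ~rb)]]
        expected = sm_mc(table, exact=True).pvalue
        assert mcnemar_exact(a, b, true) == pytest.approx(expected)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_hand_stepdown_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.random(20)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(15)
        expected = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])
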