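"""Regularized logistic regression: objectives, solver, prediction."""

import numpy as np
import pytest

from wavemri.classify import (LogisticModel, fit_logistic, load_model,
                              predict_class, regularized_cost, save_model)


def independent_objective(w, c, X, y, penalty, C, mix):
    """Objective written independently of the implementation."""
    w = np.atleast_1d(np.asarray(w, float))
    margins = y * (np.atleast_2d(X) @ w + c)
    loss = np.log1p(np.exp(-np.clip(margins, -500, 500))).sum()
    if penalty == "l2":
        pen = 0.5 * (w ** 2).sum()
    elif penalty == "l1":
        pen = np.abs(w).sum()
    else:
        pen = (1 - mix) / 2 * (w ** 2).sum() + mix * np.abs(w).sum()
    return pen + C * loss


def grid_search_1d(X, y, penalty, C, mix, span=10.0, steps=201):
    """Two-stage dense grid search over (w, c) in [-span, span]^2."""
    X = np.asarray(X, float).reshape(-1, 1)
    lo_w = lo_c = -span
    hi_w = hi_c = span
    best = (np.inf, 0.0, 0.0)
    for _ in range(3):  # successive refinement of the dense grid
        ws = np.linspace(lo_w, hi_w, steps)
        cs = np.linspace(lo_c, hi_c, steps)
        margins = y[None, None, :] * (X[:, 0][None, None, :] * ws[:, None, None]
                                      + cs[None, :, None])
        loss = np.log1p(np.exp(-np.clip(margins, -500, 500))).sum(axis=2)
        if penalty == "l2":
            pen = 0.5 * ws[:, None] ** 2
        elif penalty == "l1":
            pen = np.abs(ws)[:, None]
        else:
            pen = (1 - mix) / 2 * ws[:, None] ** 2 + mix * np.abs(ws)[:, None]
        F = pen + C * loss
        i, j = np.unravel_index(np.argmin(F), F.shape)
        best = (F[i, j], ws[i], cs[j])
        dw, dc = ws[1] - ws[0], cs[1] - cs[0]
        lo_w, hi_w = ws[i] - 2 * dw, ws[i] + 2 * dw
        lo_c, hi_c = cs[j] - 2 * dc, cs[j] + 2 * dc
    return best


class TestRegularizedCost:
    def test_zero_weights_cost_is_C_n_log2(self, rng):
        X = rng.normal(size=(7, 3))
        y = rng.choice([-1.0, 1.0], size=7)
        for penalty in ("l2", "l1", "elasticnet"):
            val = regularized_cost(np.zeros(3), 0.0, X, y, penalty, C=2.5)
            assert val == pytest.approx(2.5 * 7 * np.log(2), rel=1e-12)

    def test_single_sample_arithmetic(self):
        val = regularized_cost([1.0], 0.0, [[1.0]], [1.0], "l2", C=1.0)
        assert val == pytest.approx(0.5 + np.log(1 + np.exp(-1)), rel=1e-10)

    def test_elastic_net_endpoints(self, rng):
        w = rng.normal(size=4)
        X = rng.normal(size=(10, 4))
        y = rng.choice([-1.0, 1.0], size=10)
        c = 0.3
        assert regularized_cost(w, c, X, y, "elasticnet", 1.0, mix=1.0) == \
            pytest.approx(regularized_cost(w, c, X, y, "l1", 1.0), rel=1e-12)
        assert regularized_cost(w, c, X, y, "elasticnet", 1.0, mix=0.0) == \
            pytest.approx(regularized_cost(w, c, X, y, "l2", 1.0), rel=1e-12)

    def test_labels_outside_pm1_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            regularized_cost([0.0], 0.0, [[1.0]], [0.0])


class TestFitLogistic:
    def test_mirror_symmetric_data_zero_intercept(self):
        X = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        y = np.array([1, -1, 1, -1])
        model = fit_logistic(X, y, penalty="l2", standardize=False)
        assert abs(model.intercepts[1]) < 1e-4

    @pytest.mark.parametrize("penalty,mix", [("l2", 0.5), ("l1", 0.5),
                                             ("elasticnet", 0.3)])
    def test_objective_matches_dense_grid_search(self, rng, penalty, mix):
        X = rng.normal(size=8)
        y = np.where(X + 0.3 * rng.normal(size=8) > 0, 1.0, -1.0)
        model = fit_logistic(X.reshape(-1, 1), y, penalty=penalty, C=1.0,
                             mix=mix, standardize=False, tol=1e-10,
                             max_iter=5000)
        k = model.label_set.index(1.0)
        fitted = independent_objective(model.weights[k], model.intercepts[k],
                                       X.reshape(-1, 1), y, penalty, 1.0, mix)
        oracle, _, _ = grid_search_1d(X, y, penalty, 1.0, mix)
        assert fitted <= oracle + 1e-3

    def test_weight_norm_nondecreasing_in_C_on_separable_data(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([-1, -1, 1, 1])
        norms = []
        for C in (0.1, 1.0, 10.0):
            m = fit_logistic(X, y, penalty="l2", C=C, standardize=False)
            norms.append(np.linalg.norm(m.weights[m.label_set.index(1)]))
        assert norms[0] <= norms[1] + 1e-9 <= norms[2] + 1e-9

    def test_objective_history_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        for penalty in ("l2", "l1", "elasticnet"):
            m = fit_logistic(X, y, penalty=penalty)
            for hist in m.objective_histories:
                assert (np.diff(hist) <= 1e-12).all()

    def test_l1_small_C_gives_exact_zeros(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        m = fit_logistic(X, y, penalty="l1", C=1e-4)
        assert (m.weights == 0.0).all()

    def test_multinomial_scheme_fits_and_predicts(self, rng):
        X = np.vstack([rng.normal(loc=c * 3, size=(15, 2))
                       for c in range(3)])
        y = np.repeat([0, 1, 2], 15)
        m = fit_logistic(X, y, scheme="multinomial")
        preds = [p.label for p in predict_class(m, X)]
        assert np.mean(np.asarray(preds) == y) > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_logistic(np.ones((3, 1)), np.zeros(3))

    def test_nonconvergence_warns_and_flags(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        with pytest.warns(RuntimeWarning, match="converged=False"):
            m = fit_logistic(X, y, tol=1e-14, max_iter=3)
        assert not m.converged

    def test_matches_sklearn_l2_solution(self, rng):
        """Cross-check against an independent l2 solver on the same objective."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=60) > 0, 1, 0)
        ours = fit_logistic(X, y, penalty="l2", C=0.7, standardize=False,
                            tol=1e-12, max_iter=20000)
        ref = sklearn.LogisticRegression(C=0.7, tol=1e-10,
                                         solver="lbfgs", max_iter=5000).fit(X, y)
        k = ours.label_set.index(1)
        assert np.allclose(ours.weights[k], ref.coef_[0], atol=2e-3)
        assert abs(ours.intercepts[k] - ref.intercept_[0]) < 2e-3


class TestPredict:
    def _mirror_binary(self, w, c):
        return LogisticModel(
            weights=np.array([[-w], [w]]), intercepts=np.array([-c, c]),
            penalty="l2", C=1.0, mix=0.5, scheme="one-vs-rest",
            label_set=["neg", "pos"], feature_mean=np.zeros(1),
            feature_scale=np.ones(1))

    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 3, size=20)
        m = fit_logistic(X, y)
        for p in predict_class(m, X):
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p.probabilities >= 0).all()

    def test_zero_margin_gives_half(self):
        m = self._mirror_binary(1.0, 0.0)
        p = predict_class(m, np.array([[0.0]]))[0]
        assert p.probabilities == pytest.approx([0.5, 0.5])

    def test_sigmoid_arithmetic(self):
        m = self._mirror_binary(2.0, -1.0)
        p = predict_class(m, np.array([[1.0]]))[0]
        assert p.probabilities[1] == pytest.approx(1 / (1 + np.exp(-1)), rel=1e-9)

    def test_tie_broken_by_label_order(self):
        m = self._mirror_binary(0.0, 0.0)
        assert predict_class(m, np.array([[3.0]]))[0].label == "neg"

    def test_dimension_mismatch_rejected(self):
        m = self._mirror_binary(1.0, 0.0)
        with pytest.raises(ValueError, match="dimension"):
            predict_class(m, np.ones((1, 2)))

    def test_digest_mismatch_refused(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.integers(0, 2, size=10)
        m = fit_logistic(X, y, config_digest="abc123")
        with pytest.raises(ValueError, match="digest"):
            predict_class(m, X, config_digest="different")
        predict_class(m, X, config_digest="abc123")

    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 3, size=20)
        m = fit_logistic(X, y, penalty="elasticnet", mix=0.4,
                         config_digest="deadbeef")
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        assert np.allclose(m.weights, m2.weights)
        assert np.allclose(m.intercepts, m2.intercepts)
        assert m2.config_digest == "deadbeef"
        p1 = predict_class(m, X)
        p2 = predict_class(m2, X)
        assert [a.label for a in p1] == [str(b.label) for b in p2] or \
            [str(a.label) for a in p1] == [str(b.label) for b in p2]
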