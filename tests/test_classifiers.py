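import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffgf.classifiers import (
    ELMClassifier,
    KNNClassifier,
    LinearDiscriminant,
    LinearSVM,
    OPELMClassifier,
    knn_predict,
    ld_fit,
    ld_predict,
    minkowski_distance,
    press_loo_error,
    svm_fit,
    svm_predict,
)
from ffgf.classifiers.elm import _expand_node_types, _lars_order, elm_fit, op_elm_fit
from ffgf.data import LabeledDataset
from ffgf.exceptions import ContractError

from conftest import random_labeled


# ---------------------------------------------------------------- KNN


class TestMinkowski:
    def test_identity(self, rng):
        a = rng.normal(size=3)
        for p in (1, 1.5, 2, 3):
            assert minkowski_distance(a, a, p) == 0.0

    def test_euclidean_hand(self):
        assert minkowski_distance((1, 2, 3), (4, 6, 3), 2) == pytest.approx(5.0)

    def test_cityblock_hand(self):
        assert minkowski_distance((1, 2, 3), (4, 6, 3), 1) == pytest.approx(7.0)

    def test_p_below_one(self):
        with pytest.raises(ContractError):
            minkowski_distance((1, 2), (3, 4), 0.5)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.sampled_from([1.0, 2.0, 3.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_nonnegative(self, a, b, p):
        d_ab = minkowski_distance(a, b, p)
        d_ba = minkowski_distance(b, a, p)
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= 0


class TestKNN:
    def test_self_match(self, rng):
        data = random_labeled(rng, n=10)
        model = KNNClassifier(k=1).fit(data)
        for i in range(10):
            label, _ = knn_predict(model, data.X[i])
            assert label == data.t[i]

    def test_three_neighbor_vote(self):
        X = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0], [9.0, 0, 0]])
        t = np.array([1, 1, -1, -1])
        model = KNNClassifier(k=3).fit(LabeledDataset(X, t))
        label, score = knn_predict(model, np.zeros(3))
        assert label == 1
        assert score == pytest.approx(1 / 3)

    def test_global_vote(self, rng):
        data = random_labeled(rng, n=15)
        majority = 1 if np.sum(data.t == 1) >= np.sum(data.t == -1) else -1
        model = KNNClassifier(k=15).fit(data)
        preds = model.predict(rng.normal(size=(5, 3)))
        assert np.all(preds == majority)

    def test_matches_bruteforce_enumeration(self, rng):
        data = random_labeled(rng, n=25)
        queries = rng.normal(size=(10, 3))
        for k, p in [(1, 2), (3, 1), (5, 2)]:
            model = KNNClassifier(k=k, p=p).fit(data)
            scores = model.decision_function(queries)
            for qi, x in enumerate(queries):
                dists = [minkowski_distance(x, xi, p) for xi in data.X]
                order = sorted(range(25), key=lambda i: (dists[i], i))
                votes = data.t[order[:k]]
                assert scores[qi] == pytest.approx(votes.sum() / k)

    def test_distance_tie_lower_index(self):
        X = np.array([[1.0, 0, 0], [-1.0, 0, 0], [2.0, 0, 0]])
        t = np.array([1, -1, 1])
        model = KNNClassifier(k=1).fit(LabeledDataset(X, t))
        # query equidistant from rows 0 and 1; row 0 wins
        label, _ = knn_predict(model, np.zeros(3))
        assert label == 1

    def test_k_too_large(self, rng):
        data = random_labeled(rng, n=5)
        with pytest.raises(ContractError):
            KNNClassifier(k=6).fit(data)


# ---------------------------------------------------------------- LD


class TestLinearDiscriminant:
    def test_two_point_exact(self):
        data = LabeledDataset(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        model = ld_fit(data)
        assert model.w0_ == pytest.approx(0.0, abs=1e-12)
        assert model.w_[0] == pytest.approx(1.0)

    def test_duplication_invariance(self, rng):
        data = random_labeled(rng, n=12)
        doubled = LabeledDataset(
            np.vstack([data.X, data.X]), np.concatenate([data.t, data.t])
        )
        m1, m2 = ld_fit(data), ld_fit(doubled)
        assert m1.w0_ == pytest.approx(m2.w0_, abs=1e-10)
        np.testing.assert_allclose(m1.w_, m2.w_, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        data = random_labeled(rng, n=20)
        model = ld_fit(data)
        A = np.column_stack([np.ones(20), data.X])
        w = np.linalg.solve(A.T @ A, A.T @ data.t.astype(float))
        np.testing.assert_allclose(np.r_[model.w0_, model.w_], w, atol=1e-8)

    def test_normal_equation_residual(self, rng):
        for seed in range(3):
            data = random_labeled(np.random.default_rng(seed), n=15)
            model = ld_fit(data)
            A = np.column_stack([np.ones(15), data.X])
            resid = A.T @ (A @ np.r_[model.w0_, model.w_] - data.t)
            assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(data.t)

    def test_predict_rules(self):
        model = LinearDiscriminant()
        model.w0_, model.w_ = 0.0, np.array([1.0, 0.0, 0.0])
        label, score = ld_predict(model, np.array([2.0, 5.0, -1.0]))
        assert (label, score) == (1, pytest.approx(2.0))
        label0, score0 = ld_predict(model, np.zeros(3))
        assert (label0, score0) == (1, 0.0)  # tie rule

    def test_sign_agrees_with_affine(self, rng):
        model = LinearDiscriminant()
        model.w0_ = rng.normal()
        model.w_ = rng.normal(size=3)
        for _ in range(20):
            x = rng.normal(size=3)
            label, score = ld_predict(model, x)
            direct = model.w0_ + float(model.w_ @ x)
            assert score == pytest.approx(direct)
            assert label == (1 if direct >= 0 else -1)


# ---------------------------------------------------------------- SVM


def qp_dual_oracle(X, t, C, iters=200000, lr=None):
    """Projected-gradient solver for the SVM dual (independent oracle)."""
    n = len(t)
    K = (t[:, None] * t[None, :]) * (X @ X.T)
    if lr is None:
        lr = 1.0 / (np.linalg.eigvalsh(K).max() + 1e-9)
    alpha = np.zeros(n)
    for _ in range(iters):
        grad = K @ alpha - 1.0
        alpha -= lr * grad
        # project onto {0 <= a <= C, sum a_i t_i = 0}
        for _ in range(50):
            alpha = np.clip(alpha, 0, C)
            corr = (alpha @ t) / n
            alpha -= corr * t
        alpha = np.clip(alpha, 0, C)
    w = (alpha * t) @ X
    sv = (alpha > 1e-6) & (alpha < C - 1e-6)
    if sv.any():
        b = np.mean(t[sv] - X[sv] @ w)
    else:
        b = 0.0
    return w, b


class TestSVM:
    def test_two_point_analytic(self):
        data = LabeledDataset(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        model = svm_fit(data, trainer="smo", C=1e6)
        assert model.w_[0] == pytest.approx(1.0, abs=1e-3)
        assert model.b_ == pytest.approx(0.0, abs=1e-3)
        scores = model.decision_function(data.X)
        np.testing.assert_allclose(scores, [-1.0, 1.0], atol=2e-3)

    def test_dual_constraint(self, rng):
        data = random_labeled(rng, n=20)
        model = svm_fit(data, trainer="smo", C=1.0)
        assert abs(float(model.alpha_ @ data.t)) <= 1e-6

    def test_separable_matches_qp_oracle(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(10, 3)) + 4, rng.normal(size=(10, 3)) - 4])
        t = np.array([1] * 10 + [-1] * 10)
        data = LabeledDataset(X, t)
        model = svm_fit(data, trainer="smo", C=1e3)
        w, b = qp_dual_oracle(X, t.astype(float), 1e3, iters=5000)
        np.testing.assert_array_equal(
            model.predict(X), np.sign(X @ w + b).astype(int)
        )

    def test_separable_margins(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(size=(10, 3)) + 4, rng.normal(size=(10, 3)) - 4])
        t = np.array([1] * 10 + [-1] * 10)
        model = svm_fit(LabeledDataset(X, t), trainer="smo", C=1e4)
        margins = t * model.decision_function(X)
        assert np.all(margins >= 1 - 1e-3)

    def test_kkt_conditions(self, rng):
        data = random_labeled(rng, n=30)
        model = svm_fit(data, trainer="smo", C=2.0, tol=1e-3)
        margins = data.t * model.decision_function(data.X)
        C, tol = 2.0, 1e-3
        for a, m in zip(model.alpha_, margins):
            if a <= 1e-9:
                assert m >= 1 - tol - 1e-9
            elif a >= C - 1e-9:
                assert m <= 1 + tol + 1e-9
            else:
                assert abs(m - 1) <= tol + 1e-9

    def test_ls_trainer_separable(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(size=(10, 3)) + 4, rng.normal(size=(10, 3)) - 4])
        t = np.array([1] * 10 + [-1] * 10)
        model = svm_fit(LabeledDataset(X, t), trainer="ls", C=10.0)
        assert np.array_equal(model.predict(X), t)

    def test_predict_rules(self):
        model = LinearSVM()
        model.w_, model.b_ = np.array([1.0, 0.0, 0.0]), -2.0
        label, score = svm_predict(model, np.array([3.0, 0.0, 0.0]))
        assert (label, score) == (1, pytest.approx(1.0))
        label0, score0 = svm_predict(model, np.array([2.0, 0.0, 0.0]))
        assert (label0, score0) == (1, pytest.approx(0.0))

    def test_bad_params(self):
        with pytest.raises(ContractError):
            LinearSVM(trainer="qp")
        with pytest.raises(ContractError):
            LinearSVM(C=0.0)


# ---------------------------------------------------------------- ELM


class TestELM:
    def test_exact_interpolation(self, rng):
        data = random_labeled(rng, n=20)
        model = elm_fit(data, m_hidden=20, node_types=("sigmoid",), seed=1)
        resid = np.abs(model.decision_function(data.X) - data.t).sum()
        assert resid <= 1e-6

    def test_linear_nodes_match_ld(self, rng):
        data = random_labeled(rng, n=30)
        elm = elm_fit(data, m_hidden=8, node_types=("linear",), seed=2)
        ld = ld_fit(data)
        np.testing.assert_allclose(
            elm.decision_function(data.X),
            ld.decision_function(data.X),
            atol=1e-8,
        )

    def test_seed_determinism(self, rng):
        data = random_labeled(rng, n=15)
        m1 = elm_fit(data, m_hidden=10, seed=5)
        m2 = elm_fit(data, m_hidden=10, seed=5)
        np.testing.assert_array_equal(m1.beta_, m2.beta_)
        np.testing.assert_array_equal(m1.hidden_.W, m2.hidden_.W)
        np.testing.assert_array_equal(m1.hidden_.b, m2.hidden_.b)

    def test_zero_hidden_rejected(self):
        with pytest.raises(ContractError):
            ELMClassifier(m_hidden=0)

    def test_zero_beta_tie_rule(self, rng):
        data = random_labeled(rng, n=10)
        model = elm_fit(data, m_hidden=4, seed=0)
        model.beta_ = np.zeros_like(model.beta_)
        assert np.all(model.predict(data.X) == 1)

    def test_training_predictions_equal_hb(self, rng):
        data = random_labeled(rng, n=12)
        model = elm_fit(data, m_hidden=6, node_types=("gaussian",), seed=3)
        H = model.hidden_.transform(model._scale(data.X))
        np.testing.assert_allclose(
            model.decision_function(data.X), H @ model.beta_, atol=1e-12
        )

    def test_mixed_node_allocation(self):
        assert _expand_node_types(("linear", "sigmoid", "gaussian"), 10) == (
            ["linear"] * 4 + ["sigmoid"] * 3 + ["gaussian"] * 3
        )
        assert _expand_node_types(("linear", "sigmoid"), 5) == (
            ["linear"] * 3 + ["sigmoid"] * 2
        )


class TestPress:
    def test_intercept_closed_form(self, rng):
        n = 9
        t = rng.normal(size=n)
        H = np.ones((n, 1))
        expected = np.mean(((t - t.mean()) / (1 - 1 / n)) ** 2)
        assert press_loo_error(H, t) == pytest.approx(expected, rel=1e-12)

    def test_matches_explicit_loo(self, rng):
        for n, m in [(8, 3), (12, 5), (10, 1)]:
            H = rng.normal(size=(n, m))
            t = rng.normal(size=n)
            press = press_loo_error(H, t)
            errs = []
            for i in range(n):
                idx = np.delete(np.arange(n), i)
                beta = np.linalg.pinv(H[idx]) @ t[idx]
                errs.append((t[i] - H[i] @ beta) ** 2)
            assert press == pytest.approx(np.mean(errs), abs=1e-8)

    def test_perfect_fit_zero(self, rng):
        H = rng.normal(size=(12, 3))
        beta = rng.normal(size=3)
        t = H @ beta
        assert press_loo_error(H, t) == pytest.approx(0.0, abs=1e-16)

    def test_n_not_greater_than_m(self, rng):
        with pytest.raises(ContractError):
            press_loo_error(rng.normal(size=(5, 5)), rng.normal(size=5))


class TestOPELM:
    def test_exact_first_column_selects_k1(self, rng):
        t = np.where(rng.uniform(size=20) < 0.5, 1.0, -1.0)
        H = np.column_stack([t, rng.normal(size=(20, 6))])
        order = _lars_order(H, t)
        assert order[0] == 0
        press = [press_loo_error(H[:, order[:k]], t) for k in range(1, 8)]
        assert int(np.argmin(press)) + 1 == 1

    def test_selected_press_is_prefix_minimum(self, rng):
        data = random_labeled(rng, n=30)
        model = op_elm_fit(data, m_init=15, seed=4)
        k = model.n_hidden_
        assert model.press_path_[k - 1] == pytest.approx(model.press_path_.min())
        # ties resolve to the smaller prefix
        assert np.all(model.press_path_[: k - 1] > model.press_path_[k - 1])

    def test_refit_uses_kept_nodes(self, rng):
        data = random_labeled(rng, n=25)
        model = op_elm_fit(data, m_init=12, seed=9)
        assert len(model.hidden_.types) == model.n_hidden_
        H = model.hidden_.transform(model._scale(data.X))
        np.testing.assert_allclose(
            model.decision_function(data.X), H @ model.beta_, atol=1e-12
        )

    def test_noise_target_prunes_hard(self):
        ks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 3))
            t = np.where(rng.uniform(size=60) < 0.5, 1, -1)
            t[0], t[1] = 1, -1
            model = op_elm_fit(LabeledDataset(X, t), m_init=40, seed=seed)
            ks.append(model.n_hidden_)
        assert np.median(ks) <= 10  # M_init / 4

    def test_cap_at_n_minus_two(self, rng):
        data = random_labeled(rng, n=10)
        model = op_elm_fit(data, m_init=100, seed=0)
        assert model.n_hidden_ <= 8

    def test_seed_determinism(self, rng):
        data = random_labeled(rng, n=20)
        m1 = op_elm_fit(data, m_init=15, seed=7)
        m2 = op_elm_fit(data, m_init=15, seed=7)
        assert m1.n_hidden_ == m2.n_hidden_
        np.testing.assert_array_equal(m1.beta_, m2.beta_)
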