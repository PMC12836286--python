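"""SMO-trained Gaussian SVM against analytic and QP oracles."""

import numpy as np
import pytest

import _oracles as oracles
from noderad.core import ValidationError
from noderad.svm import (
    SVMConfig,
    decision_function,
    gaussian_kernel,
    kernel_matrix,
    platt_calibrate,
    predict_probability,
    smo_train,
    TrainedSVM,
)


class TestKernel:
    def test_zero_distance(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], 0.7) == 1.0

    def test_half_height_distance(self):
        sigma = 1.3
        d = sigma * np.sqrt(2 * np.log(2))
        assert gaussian_kernel([0.0], [d], sigma) == pytest.approx(0.5)

    def test_decay_to_zero(self):
        assert gaussian_kernel([0.0], [1e4], 1.0) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            gaussian_kernel([0.0], [1.0], 0.0)


def kkt_audit(model: TrainedSVM, X, y, tol):
    """alpha=0 => y f >= 1-tol; 0<alpha<C => |y f - 1| <= tol; alpha=C => y f <= 1+tol."""
    f = decision_function(model, X)
    alpha = model.alpha_full
    C = model.C
    margin = y * f
    assert np.all(alpha >= 0) and np.all(alpha <= C)
    assert abs((alpha * y).sum()) <= 1e-9
    free = (alpha > 1e-9) & (alpha < C - 1e-9)
    assert np.all(margin[alpha <= 1e-9] >= 1 - tol - 1e-9)
    assert np.all(np.abs(margin[free] - 1) <= tol + 1e-9)
    assert np.all(margin[alpha >= C - 1e-9] <= 1 + tol + 1e-9)


class TestSmo:
    def test_two_point_symmetric_problem(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        m = smo_train(X, y, SVMConfig(C=10, sigma=1, tol=1e-6, max_passes=20, seed=0))
        # symmetric dual solution: equal multipliers, correct signs
        assert len(m.dual_coef) == 2
        assert abs(m.dual_coef).max() == pytest.approx(abs(m.dual_coef).min())
        assert np.sign(decision_function(m, [[0.0]])[0]) == -1
        assert np.sign(decision_function(m, [[1.0]])[0]) == 1
        # midpoint lies on the decision boundary by symmetry
        assert decision_function(m, [[0.5]])[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_pattern_separated(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        m = smo_train(X, y, SVMConfig(C=10, sigma=1, tol=1e-5, max_passes=20, seed=0))
        assert np.all(np.sign(decision_function(m, X)) == y)

    def test_duplicated_dataset_same_decision_function(self):
        # equivalence requires an interior solution (no alpha at the box
        # bound): duplicating rows otherwise acts like doubling C
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        y = np.where(X[:, 0] + X[:, 1] > 0, 1.0, -1.0)
        cfg = SVMConfig(C=50, sigma=1.5, tol=1e-8, max_passes=30, seed=1)
        m1 = smo_train(X, y, cfg)
        m2 = smo_train(np.vstack([X, X]), np.r_[y, y], cfg)
        grid = rng.normal(size=(20, 2))
        assert np.allclose(
            decision_function(m1, grid), decision_function(m2, grid), atol=1e-4
        )

    def test_far_point_decays_to_bias(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 2))
        y = np.array([1.0, -1.0] * 4)
        m = smo_train(X, y, SVMConfig(C=1, sigma=1, seed=0))
        far = decision_function(m, [[1e3, 1e3]])[0]
        assert far == pytest.approx(m.bias)

    def test_support_vector_margin_condition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        tol = 1e-4
        m = smo_train(X, y, SVMConfig(C=3, sigma=1, tol=tol, max_passes=20, seed=2))
        kkt_audit(m, X, y, tol)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            smo_train(np.zeros((3, 1)), np.ones(3), SVMConfig())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 2))
        y = np.where(rng.random(15) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        cfg = SVMConfig(C=2, sigma=1, seed=11)
        m1, m2 = smo_train(X, y, cfg), smo_train(X, y, cfg)
        assert np.array_equal(m1.alpha_full, m2.alpha_full)
        assert m1.bias == m2.bias

    @pytest.mark.parametrize("seed", range(10))
    def test_dual_objective_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 13))
        d = int(rng.integers(1, 5))
        X = rng.normal(size=(n, d))
        y = np.ones(n)
        y[: n // 2] = -1
        rng.shuffle(y)
        C = float(rng.choice([0.5, 1.0, 10.0]))
        sigma = float(rng.choice([0.5, 1.0, 2.0]))
        m = smo_train(X, y, SVMConfig(C=C, sigma=sigma, tol=1e-8, max_passes=20, seed=seed))
        w_star = oracles.qp_dual_oracle(kernel_matrix(X, X, sigma), y, C)
        assert m.dual_objective_value == pytest.approx(
            w_star, rel=1e-6, abs=1e-9
        )

    def test_agrees_with_reference_svc(self):
        """Cross-check decision agreement with an independent SVC fit."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] ** 2 + X[:, 1] ** 2 > 1.5, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        sigma = 1.0
        m = smo_train(X, y, SVMConfig(C=10, sigma=sigma, tol=1e-6, max_passes=30, seed=3))
        ref = SVC(C=10, kernel="rbf", gamma=1.0 / (2 * sigma**2)).fit(X, y)
        grid = rng.normal(size=(50, 2))
        assert (
            np.sign(decision_function(m, grid)) == np.sign(ref.decision_function(grid))
        ).mean() > 0.95


class TestPlatt:
    def test_symmetric_scores_give_half_at_zero(self):
        scores = np.array([-1.0, 1.0] * 10)
        labels = np.array([-1.0, 1.0] * 10)
        a, b = platt_calibrate(scores, labels)
        p0 = 1 / (1 + np.exp(b))  # probability at score 0
        assert p0 == pytest.approx(0.5, abs=1e-6)
        assert a < 0  # higher score -> higher probability

    def test_shuffled_labels_flatten_the_slope(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=400)
        labels = np.where(rng.random(400) < 0.5, 1.0, -1.0)
        a, _ = platt_calibrate(scores, labels)
        assert abs(a) < 0.25

    def test_probabilities_monotone_in_score(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        m = smo_train(X, y, SVMConfig(C=5, sigma=1, seed=4))
        m.platt_a, m.platt_b = platt_calibrate(decision_function(m, X), y)
        s = decision_function(m, X)
        p = predict_probability(m, X)
        order = np.argsort(s)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            platt_calibrate(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


def test_model_json_round_trip():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(10, 2))
    y = np.where(rng.random(10) < 0.5, 1.0, -1.0)
    y[:2] = [1.0, -1.0]
    m = smo_train(X, y, SVMConfig(C=1, sigma=1, seed=5))
    m2 = TrainedSVM.from_dict(m.to_dict())
    grid = rng.normal(size=(5, 2))
    assert np.allclose(decision_function(m, grid), decision_function(m2, grid))
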