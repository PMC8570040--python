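import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erdnet.losses import (
    SmoothingConfig,
    LossWeights,
    CenterBank,
    epsilon_from_alpha,
    smooth_labels,
    one_hot,
    cross_entropy,
    lsr_term,
    smoothed_cross_entropy,
    center_loss,
    center_loss_grad,
    update_centers,
    combined_loss,
)


def random_simplex(rng, n, m):
    q = rng.dirichlet(np.ones(m), size=n)
    return np.clip(q, 1e-9, None) / np.clip(q, 1e-9, None).sum(axis=1, keepdims=True)


class TestEpsilonAlpha:
    @pytest.mark.parametrize(
        "alpha,expected", [(0.0, 0.0), (0.5, 1.0 / 3.0), (1.0, 0.5), (3.0, 0.75)]
    )
    def test_inverse_of_relative_weight(self, alpha, expected):
        # eps solves eps/(1-eps) = alpha
        eps = epsilon_from_alpha(alpha)
        assert eps == pytest.approx(expected)
        if alpha > 0:
            assert eps / (1 - eps) == pytest.approx(alpha)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            epsilon_from_alpha(-0.1)
        with pytest.raises(ValueError):
            SmoothingConfig(alpha_lsr=-1)

    def test_config_derives_epsilon(self):
        assert SmoothingConfig(alpha_lsr=1.0).epsilon == pytest.approx(0.5)


class TestSmoothLabels:
    def test_zero_epsilon_is_one_hot(self):
        out = smooth_labels(np.array([0, 2, 1]), 3, 0.0)
        np.testing.assert_array_equal(out, one_hot(np.array([0, 2, 1]), 3))

    def test_full_epsilon_is_uniform(self):
        out = smooth_labels(np.array([1, 0]), 4, 1.0)
        np.testing.assert_allclose(out, np.full((2, 4), 0.25))

    def test_hand_computed_mixture(self):
        # M=4, eps=0.25, y=2: (1-eps) + eps/M = 0.8125 on the true class
        out = smooth_labels(np.array([2]), 4, 0.25)
        np.testing.assert_allclose(out[0], [0.0625, 0.0625, 0.8125, 0.0625])

    @settings(max_examples=50, deadline=None)
    @given(eps=st.floats(0, 1), m=st.integers(2, 6), seed=st.integers(0, 1000))
    def test_rows_on_simplex(self, eps, m, seed):
        labels = np.random.default_rng(seed).integers(0, m, 7)
        out = smooth_labels(labels, m, eps)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert out.min() >= 0

    def test_epsilon_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(np.array([0]), 2, 1.5)


class TestCrossEntropy:
    def test_uniform_prediction_gives_log_m(self):
        target = one_hot(np.array([0, 1, 3]), 4)
        q = np.full((3, 4), 0.25)
        assert cross_entropy(target, q) == pytest.approx(np.log(4))
        assert cross_entropy(target, q, reduction="sum") == pytest.approx(3 * np.log(4))

    def test_perfect_prediction_near_zero(self):
        target = one_hot(np.array([1]), 3)
        assert cross_entropy(target, target) == pytest.approx(0.0, abs=1e-9)

    def test_gibbs_inequality_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = random_simplex(rng, 5, 4)
            q = random_simplex(rng, 5, 4)
            entropy = -(p * np.log(p)).sum(axis=1).mean()
            assert cross_entropy(p, q) >= entropy - 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 3)) / 3, np.ones((2, 4)) / 4)


class TestLsrTerm:
    def test_uniform_prediction_gives_log_m(self):
        q = np.full((5, 3), 1 / 3)
        assert lsr_term(q) == pytest.approx(np.log(3))

    def test_minimized_at_uniform_on_simplex_grid(self):
        # H(u, q) over the 2-simplex grid is smallest at q = (1/3, 1/3, 1/3)
        best, best_val = None, np.inf
        grid = np.linspace(0.01, 0.98, 30)
        for a in grid:
            for b in grid:
                if a + b >= 0.99:
                    continue
                q = np.array([[a, b, 1 - a - b]])
                v = lsr_term(q)
                if v < best_val:
                    best, best_val = q, v
        np.testing.assert_allclose(best, 1 / 3, atol=0.05)

    def test_confident_prediction_penalized(self):
        uniform = np.full((1, 4), 0.25)
        confident = np.array([[0.997, 0.001, 0.001, 0.001]])
        assert lsr_term(confident) > lsr_term(uniform)


class TestSmoothedCrossEntropy:
    def test_zero_alpha_reduces_to_standard(self):
        rng = np.random.default_rng(1)
        q = random_simplex(rng, 6, 4)
        y = rng.integers(0, 4, 6)
        assert smoothed_cross_entropy(y, q, 0.0) == pytest.approx(
            cross_entropy(one_hot(y, 4), q), abs=1e-12
        )

    def test_decomposition_identity(self):
        # CE(p', q) == (1-eps) CE(p, q) + eps H(u, q), 1000 random draws
        rng = np.random.default_rng(2)
        for _ in range(1000):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(1, 8))
            q = random_simplex(rng, n, m)
            y = rng.integers(0, m, n)
            eps = float(rng.uniform(0, 1))
            lhs = cross_entropy(smooth_labels(y, m, eps), q)
            rhs = (1 - eps) * cross_entropy(one_hot(y, m), q) + eps * lsr_term(q, m)
            assert abs(lhs - rhs) <= 1e-10

    def test_alpha_form_consistency(self):
        # CE(p', q) == (1-eps) * [CE(p, q) + alpha_lsr * L_lsr(q)]
        rng = np.random.default_rng(3)
        q = random_simplex(rng, 10, 4)
        y = rng.integers(0, 4, 10)
        alpha = 0.5
        cfg = SmoothingConfig(alpha)
        lhs = smoothed_cross_entropy(y, q, cfg)
        rhs = (1 - cfg.epsilon) * (
            cross_entropy(one_hot(y, 4), q) + alpha * lsr_term(q, 4)
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_uniform_prediction_gives_log_m_regardless_of_smoothing(self):
        q = np.full((1, 2), 0.5)
        assert smoothed_cross_entropy(np.array([0]), q, 0.5) == pytest.approx(np.log(2))


class TestCenterLoss:
    def test_zero_when_features_sit_on_centers(self):
        bank = CenterBank(np.array([[1.0, 2.0], [3.0, 4.0]]))
        feats = np.array([[1.0, 2.0], [3.0, 4.0], [1.0, 2.0]])
        assert center_loss(feats, np.array([0, 1, 0]), bank) == 0.0

    def test_three_four_five(self):
        bank = CenterBank(np.zeros((1, 2)))
        assert center_loss(np.array([[3.0, 4.0]]), np.array([0]), bank) == pytest.approx(12.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        feats = rng.standard_normal((20, 7))
        labels = rng.integers(0, 3, 20)
        bank = CenterBank(rng.standard_normal((3, 7)))
        brute = 0.0
        for i in range(20):
            for k in range(7):
                brute += 0.5 * (feats[i, k] - bank.centers[labels[i], k]) ** 2
        assert center_loss(feats, labels, bank, reduction="sum") == pytest.approx(
            brute, abs=1e-12
        )
        assert center_loss(feats, labels, bank) == pytest.approx(brute / 20, abs=1e-12)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(5)
        feats = rng.standard_normal((4, 3))
        labels = rng.integers(0, 2, 4)
        bank = CenterBank(rng.standard_normal((2, 3)))
        grad = center_loss_grad(feats, labels, bank)
        eps = 1e-6
        for i in range(4):
            for k in range(3):
                fp = feats.copy()
                fp[i, k] += eps
                fm = feats.copy()
                fm[i, k] -= eps
                num = (
                    center_loss(fp, labels, bank, "sum")
                    - center_loss(fm, labels, bank, "sum")
                ) / (2 * eps)
                assert num == pytest.approx(grad[i, k], abs=1e-4)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            center_loss(np.zeros((2, 3)), np.array([0, 1]), CenterBank(np.zeros((2, 4))))


class TestUpdateCenters:
    def test_zero_step_leaves_centers(self):
        bank = CenterBank(np.array([[1.0, 1.0]]), center_step=0.0)
        out = update_centers(bank, np.array([[5.0, 5.0]]), np.array([0]))
        np.testing.assert_array_equal(out.centers, bank.centers)

    def test_single_sample_full_step_moves_to_midpoint(self):
        bank = CenterBank(np.array([[0.0, 0.0]]), center_step=1.0)
        out = update_centers(bank, np.array([[4.0, 2.0]]), np.array([0]))
        np.testing.assert_allclose(out.centers[0], [2.0, 1.0])

    def test_absent_class_untouched(self):
        bank = CenterBank(np.array([[0.0], [7.0]]), center_step=1.0)
        out = update_centers(bank, np.array([[2.0], [4.0]]), np.array([0, 0]))
        assert out.centers[1, 0] == 7.0
        assert out.centers[0, 0] != 0.0

    def test_repeated_updates_converge_to_class_means(self):
        rng = np.random.default_rng(6)
        feats = rng.standard_normal((30, 4))
        labels = rng.integers(0, 3, 30)
        bank = CenterBank(np.zeros((3, 4)), center_step=1.0)
        for _ in range(200):
            bank = update_centers(bank, feats, labels)
        means = np.stack([feats[labels == j].mean(axis=0) for j in range(3)])
        np.testing.assert_allclose(bank.centers, means, atol=1e-8)

    def test_single_step_contraction_rate(self):
        # one full-class batch with step 1 shrinks the gap to the class mean
        # by exactly the factor n_j / (1 + n_j)
        rng = np.random.default_rng(7)
        feats = rng.standard_normal((10, 2))
        labels = np.zeros(10, dtype=int)
        c0 = np.array([[5.0, -3.0]])
        bank = update_centers(CenterBank(c0.copy(), center_step=1.0), feats, labels)
        mean = feats.mean(axis=0)
        expected = c0[0] - (10.0 / 11.0) * (c0[0] - mean)
        np.testing.assert_allclose(bank.centers[0], expected, atol=1e-12)


class TestCombinedLoss:
    def test_zero_weights_is_standard_cross_entropy(self):
        rng = np.random.default_rng(8)
        q = random_simplex(rng, 5, 3)
        y = rng.integers(0, 3, 5)
        feats = rng.standard_normal((5, 4))
        bank = CenterBank(rng.standard_normal((3, 4)))
        assert combined_loss(y, q, feats, bank, LossWeights(0, 0)) == pytest.approx(
            cross_entropy(one_hot(y, 3), q), abs=1e-12
        )

    def test_additivity_in_the_weights(self):
        rng = np.random.default_rng(9)
        q = random_simplex(rng, 6, 4)
        y = rng.integers(0, 4, 6)
        feats = rng.standard_normal((6, 5))
        bank = CenterBank(rng.standard_normal((4, 5)))
        a_lsr, a_ct = 0.7, 0.3
        total = combined_loss(y, q, feats, bank, LossWeights(a_lsr, a_ct))
        base = combined_loss(y, q, feats, bank, LossWeights(0, 0))
        expected = a_lsr * lsr_term(q, 4) + a_ct * center_loss(feats, y, bank)
        assert total - base == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(eps=st.floats(0, 0.999), seed=st.integers(0, 10_000))
    def test_decomposition_identity_property(self, eps, seed):
        rng = np.random.default_rng(seed)
        q = random_simplex(rng, 4, 3)
        y = rng.integers(0, 3, 4)
        lhs = cross_entropy(smooth_labels(y, 3, eps), q)
        rhs = (1 - eps) * cross_entropy(one_hot(y, 3), q) + eps * lsr_term(q, 3)
        assert abs(lhs - rhs) <= 1e-10
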