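import numpy as np
import pytest

from sparsevda.encoding import nearest_vertex_index
from sparsevda.simulation import (SimulationScenario, apply_shift,
                                  assign_labels, noise_sigma_from_snr,
                                  per_class_support_metrics,
                                  sample_true_slopes, simulate_classification,
                                  support_metrics, toeplitz_gaussian_design,
                                  toy_nonlinear)


def one_hot(labels, c):
    Y = np.zeros((len(labels), c))
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


class TestToeplitzDesign:
    def test_independent_columns_at_zero_corr(self):
        X = toeplitz_gaussian_design(4000, 6, 0.0, rng=1)
        cov = np.cov(X.T)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 3 / np.sqrt(4000))

    def test_adjacent_correlation_matches_parameter(self):
        X = toeplitz_gaussian_design(10000, 8, 0.9, rng=2)
        for j in range(7):
            r = np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
            assert r == pytest.approx(0.9, abs=0.03)

    def test_lag_two_correlation_is_squared(self):
        X = toeplitz_gaussian_design(10000, 8, 0.7, rng=3)
        r = np.corrcoef(X[:, 0], X[:, 2])[0, 1]
        assert r == pytest.approx(0.49, abs=0.04)

    def test_seeded_reproducibility(self):
        A = toeplitz_gaussian_design(50, 5, 0.5, rng=9)
        B = toeplitz_gaussian_design(50, 5, 0.5, rng=9)
        assert np.array_equal(A, B)

    def test_invalid_corr_rejected(self):
        with pytest.raises(ValueError):
            toeplitz_gaussian_design(10, 3, 1.0, rng=0)


class TestTrueSlopes:
    def test_homogeneous_row_count(self):
        B, support, per_class = sample_true_slopes(100, 3, 30,
                                                   "homogeneous", rng=1)
        norms = np.linalg.norm(B, axis=1)
        assert np.count_nonzero(norms) == 30
        assert np.array_equal(np.flatnonzero(norms), support)
        assert per_class is None
        assert set(np.unique(B[support])) == {-1.0, 1.0}

    def test_heterogeneous_disjoint_per_class_supports(self):
        B, support, per_class = sample_true_slopes(100, 3, 30,
                                                   "heterogeneous", rng=2)
        assert len(per_class) == 3
        all_idx = np.concatenate(per_class)
        assert len(all_idx) == 30
        assert len(np.unique(all_idx)) == 30  # disjoint
        for j, idx in enumerate(per_class):
            assert len(idx) == 10
            assert np.all(B[idx, j] != 0)
            others = np.setdiff1d(np.arange(100), idx)
            assert np.all(B[others, j] == 0)

    def test_restricted_slopes_have_full_column_rank(self):
        for seed in range(100):
            B, support, _ = sample_true_slopes(60, 3, 12, "homogeneous",
                                               rng=seed)
            assert np.linalg.matrix_rank(B[support]) == 3


class TestLabelsAndNoise:
    def test_labels_match_decision_rule(self, rng):
        B, _, _ = sample_true_slopes(20, 3, 6, "homogeneous", rng=4)
        X = rng.standard_normal((50, 20))
        labels = assign_labels(X, B)
        assert np.array_equal(labels, nearest_vertex_index(X @ B))

    def test_zero_slopes_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_labels(rng.standard_normal((5, 4)), np.zeros((4, 3)))

    def test_balanced_binary_sigma(self):
        # balanced 2-class one-hot columns have variance 1/4 each
        labels = np.tile([0, 1], 5000)
        Y = one_hot(labels, 2)
        assert noise_sigma_from_snr(Y, 1.0) == pytest.approx(0.25, rel=1e-9)
        assert noise_sigma_from_snr(Y, 10.0) == pytest.approx(0.025,
                                                              rel=1e-9)

    def test_sigma_vanishes_at_infinite_snr(self):
        Y = one_hot(np.array([0, 1, 1, 0]), 2)
        assert noise_sigma_from_snr(Y, 1e12) < 1e-12

    def test_single_class_warns_and_returns_zero(self):
        Y = one_hot(np.zeros(5, dtype=int), 1)
        with pytest.warns(UserWarning):
            assert noise_sigma_from_snr(Y, 1.0) == 0.0


class TestShift:
    def test_shift_zero_when_already_consistent(self, rng):
        # contrive X so that X B* = Y exactly and E = 0
        B = np.zeros((4, 2))
        B[[0, 2]] = [[1.0, 0.0], [0.0, 1.0]]
        support = np.array([0, 2])
        labels = np.array([0, 1, 0])
        Y = one_hot(labels, 2)
        X = np.zeros((3, 4))
        X[:, 0] = Y[:, 0]
        X[:, 2] = Y[:, 1]
        X_s, shift = apply_shift(X, B, Y, np.zeros((3, 2)), support)
        assert np.allclose(shift, 0.0, atol=1e-12)
        assert np.allclose(X_s, X)

    def test_defining_identity_on_random_instances(self, rng):
        for seed in range(10):
            B, support, _ = sample_true_slopes(40, 3, 9, "homogeneous",
                                               rng=seed)
            X = rng.standard_normal((25, 40))
            labels = assign_labels(X, B)
            Y = one_hot(labels, 3)
            E = rng.standard_normal((25, 3)) * 0.1
            X_s, shift = apply_shift(X, B, Y, E, support)
            assert np.max(np.abs(X_s @ B + E - Y)) < 1e-9

    def test_shift_supported_only_on_informative_columns(self, rng):
        B, support, _ = sample_true_slopes(30, 2, 6, "homogeneous", rng=5)
        X = rng.standard_normal((15, 30))
        Y = one_hot(assign_labels(X, B), 2)
        _, shift = apply_shift(X, B, Y, np.zeros((15, 2)), support)
        outside = np.setdiff1d(np.arange(30), support)
        assert np.all(shift[:, outside] == 0.0)

    def test_rank_deficient_slopes_rejected(self):
        B = np.zeros((4, 2))
        B[0] = [1.0, 1.0]  # rank 1 on its support
        with pytest.raises(ValueError):
            apply_shift(np.ones((3, 4)), B, np.ones((3, 2)),
                        np.zeros((3, 2)), np.array([0]))


class TestFullPipeline:
    @pytest.mark.parametrize("regime", ["homogeneous", "heterogeneous"])
    def test_generator_identity_both_regimes(self, regime):
        scenario = SimulationScenario(n=80, p=60, c=3, k_star=9,
                                      toeplitz_corr=0.5, snr=2.0,
                                      n_test=50, regime=regime, seed=3)
        data = simulate_classification(scenario)
        Y = one_hot(data.y_train, 3)
        resid = data.X_train @ data.truth.B_star + data.truth.noise - Y
        assert np.max(np.abs(resid)) < 1e-9

    def test_default_test_size_is_one_thousand(self):
        assert SimulationScenario().n_test == 1000

    def test_empirical_noise_variance_matches_sigma2(self):
        scenario = SimulationScenario(n=2000, p=30, c=3, k_star=6,
                                      snr=1.0, n_test=10, seed=8)
        data = simulate_classification(scenario)
        assert np.var(data.truth.noise) == pytest.approx(
            data.truth.sigma2, rel=0.1)

    def test_oracle_error_vanishes_at_high_snr(self):
        scenario = SimulationScenario(n=100, p=40, c=3, k_star=6,
                                      snr=1e6, n_test=500, seed=4)
        data = simulate_classification(scenario)
        pred = nearest_vertex_index(data.X_test @ data.truth.B_star)
        assert np.mean(pred != data.y_test) < 0.01

    def test_fixed_seed_reproduces_every_array(self):
        a = simulate_classification(SimulationScenario(n=40, p=20, c=3,
                                                       k_star=6, seed=42))
        b = simulate_classification(SimulationScenario(n=40, p=20, c=3,
                                                       k_star=6, seed=42))
        for attr in ("X_train", "y_train", "X_test", "y_test"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert np.array_equal(a.truth.B_star, b.truth.B_star)
        assert np.array_equal(a.truth.shift, b.truth.shift)

    def test_heterogeneous_requires_divisible_k(self):
        with pytest.raises(ValueError):
            SimulationScenario(c=3, k_star=10, regime="heterogeneous")


class TestSupportMetrics:
    def test_perfect_recovery(self):
        assert support_metrics([1, 2, 3], [1, 2, 3]) == (1.0, 1.0)

    def test_extras_halve_ppv(self):
        true = list(range(30))
        est = true + list(range(100, 130))
        tpr, ppv = support_metrics(est, true)
        assert tpr == 1.0
        assert ppv == 0.5

    def test_empty_estimate_conventions(self):
        assert support_metrics([], []) == (1.0, 1.0)
        assert support_metrics([], [1]) == (0.0, 0.0)

    def test_per_class_averaging_by_hand(self):
        est = [[0, 1], [2, 9], [4, 5]]
        true = [[0, 1], [2, 3], [6, 7]]
        tpr, ppv = per_class_support_metrics(est, true)
        assert tpr == pytest.approx((1.0 + 0.5 + 0.0) / 3)
        assert ppv == pytest.approx((1.0 + 0.5 + 0.0) / 3)


class TestNonlinearToys:
    def test_circles_without_flips_are_radius_separable(self):
        X, y = toy_nonlinear("circles", 2000, seed=1, flip=0.0)
        pred = (np.linalg.norm(X, axis=1) > 1.5).astype(int)
        assert np.mean(pred != y) < 0.01

    def test_circles_flip_rate_sets_irreducible_error(self):
        # the radius rule is the generating rule; flipped labels are exactly
        # the samples it cannot recover
        X, y = toy_nonlinear("circles", 100000, seed=2, flip=0.20)
        pred = (np.linalg.norm(X, axis=1) > 1.5).astype(int)
        assert np.mean(pred != y) == pytest.approx(0.20, abs=0.01)

    def test_clouds_and_spirals_shapes(self):
        for name in ("clouds", "spirals", "spirals-hard"):
            X, y = toy_nonlinear(name, 300, seed=3, n_classes=3)
            assert X.shape == (300, 2)
            assert set(np.unique(y)) <= {0, 1, 2}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            toy_nonlinear("donuts", 10)
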