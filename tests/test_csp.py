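import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roicsp.csp import (OneVsRestCSP, apply_csp, class_covariances,
                        csp_multiclass_ovr, csp_two_class,
                        log_variance_features, trial_covariances)
from conftest import random_spd


class TestClassCovariances:
    def test_single_trial_white_rows_near_scaled_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1, 4, 20_000))
        covs = class_covariances(np.concatenate([X, X]), [1, 2])
        C = covs.covariances[1]
        np.testing.assert_allclose(C, np.eye(4) / 4, atol=0.01)

    def test_identical_trials_average_to_single_trial(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((1, 3, 50))
        single = class_covariances(np.concatenate([X, X]), [1, 2])
        double = class_covariances(np.concatenate([X, X, X, X]),
                                   [1, 1, 2, 2])
        np.testing.assert_allclose(single.covariances[1],
                                   double.covariances[1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_unit_trace_up_to_ridge(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 5, 30))
        covs = class_covariances(X, [1, 1, 2, 2, 3, 3, 4, 4])
        for C in covs.covariances.values():
            assert abs(np.trace(C) - 1.0) < 1e-6

    def test_missing_class_rejected(self):
        X = np.random.default_rng(2).standard_normal((2, 3, 10))
        with pytest.raises(ValueError):
            class_covariances(X, [1, 1])


class TestTwoClassCSP:
    def test_equal_covariances_give_half_eigenvalues(self):
        C = random_spd(np.random.default_rng(0), 4)
        model = csp_two_class(C, C, n_filters=4)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_diagonal_closed_form(self):
        model = csp_two_class(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]),
                              n_filters=2)
        np.testing.assert_allclose(sorted(model.eigenvalues, reverse=True),
                                   [0.8, 0.2], atol=1e-12)
        # first filter along axis 0, last along axis 1 (up to sign/scale)
        w_top, w_bot = model.W
        assert abs(w_top[1]) < 1e-10 * abs(w_top[0])
        assert abs(w_bot[0]) < 1e-10 * abs(w_bot[1])

    def test_top_filter_matches_rayleigh_search(self):
        rng = np.random.default_rng(3)
        cov_a, cov_b = random_spd(rng, 6), random_spd(rng, 6)
        model = csp_two_class(cov_a, cov_b, n_filters=2)
        w = model.W[0]
        best = w @ cov_a @ w / (w @ (cov_a + cov_b) @ w)
        dirs = rng.standard_normal((100_000, 6))
        num = np.einsum("ki,ij,kj->k", dirs, cov_a, dirs)
        den = np.einsum("ki,ij,kj->k", dirs, cov_a + cov_b, dirs)
        assert best >= (num / den).max() - 1e-3

    def test_swap_reflects_eigenvalues(self):
        rng = np.random.default_rng(4)
        cov_a, cov_b = random_spd(rng, 5), random_spd(rng, 5)
        ab = csp_two_class(cov_a, cov_b, n_filters=4)
        ba = csp_two_class(cov_b, cov_a, n_filters=4)
        np.testing.assert_allclose(sorted(ab.eigenvalues),
                                   sorted(1.0 - ba.eigenvalues), atol=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        cov_a, cov_b = random_spd(rng, 4), random_spd(rng, 4)
        m1 = csp_two_class(cov_a, cov_b, n_filters=2)
        m2 = csp_two_class(7.3 * cov_a, 7.3 * cov_b, n_filters=2)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-10)
        for w1, w2 in zip(m1.W, m2.W):
            cos = abs(w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2)))
            assert cos > 1.0 - 1e-9

    def test_composite_whitening_scale(self):
        rng = np.random.default_rng(6)
        cov_a, cov_b = random_spd(rng, 5), random_spd(rng, 5)
        model = csp_two_class(cov_a, cov_b, n_filters=4)
        gram = model.W @ (cov_a + cov_b) @ model.W.T
        np.testing.assert_allclose(np.diag(gram), 1.0, atol=1e-9)

    def test_empirical_variance_ratio_converges_to_eigenvalue(self):
        rng = np.random.default_rng(7)
        S1, S2 = random_spd(rng, 4), random_spd(rng, 4)
        model = csp_two_class(S1, S2, n_filters=2)
        w = model.W[0]
        n = 200_000
        x1 = rng.multivariate_normal(np.zeros(4), S1, size=n)
        x2 = rng.multivariate_normal(np.zeros(4), S2, size=n)
        v1, v2 = (x1 @ w).var(), (x2 @ w).var()
        lam = model.eigenvalues[0]
        assert abs(v1 / (v1 + v2) - lam) < 0.01


class TestMulticlassOVR:
    def test_four_classes_give_eight_filters(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 10, 60))
        y = np.repeat([1, 2, 3, 4], 10)
        model = csp_multiclass_ovr(class_covariances(X, y))
        assert model.W.shape == (8, 10)
        assert model.class_order == [1, 2, 3, 4]

    def test_two_class_reduction(self):
        rng = np.random.default_rng(1)
        cov_a, cov_b = random_spd(rng, 6), random_spd(rng, 6)
        from roicsp.csp import ClassCovariances
        covs = ClassCovariances(covariances={1: cov_a, 2: cov_b}, n=6)
        ovr = csp_multiclass_ovr(covs, filters_per_class=2)
        two = csp_two_class(cov_a, cov_b, n_filters=2)
        # class-1 rows of the OVR stack are the extreme two-class filters
        np.testing.assert_allclose(ovr.W[0], two.W[0], atol=1e-9)
        np.testing.assert_allclose(ovr.W[1], two.W[1], atol=1e-9)

    def test_identical_covariances_all_half(self):
        C = random_spd(np.random.default_rng(2), 5)
        from roicsp.csp import ClassCovariances
        covs = ClassCovariances(covariances={k: C.copy() for k in range(1, 5)},
                                n=5)
        model = csp_multiclass_ovr(covs)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-9)

    def test_tiny_dimension_reduces_filter_count(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 2, 60))
        y = np.repeat([1, 2, 3, 4], 10)
        model = csp_multiclass_ovr(class_covariances(X, y))
        assert 2 <= model.L <= 3  # n(n+1)/2 cap for n = 2


class TestApplyAndFeatures:
    def test_identity_projection(self):
        from roicsp.csp import CSPModel
        X = np.random.default_rng(0).standard_normal((4, 10))
        model = CSPModel(W=np.eye(4), class_order=[1, 2])
        np.testing.assert_array_equal(apply_csp(model, X), X)

    def test_linearity_and_shape(self):
        from roicsp.csp import CSPModel
        rng = np.random.default_rng(1)
        W = rng.standard_normal((8, 30))
        model = CSPModel(W=W, class_order=[1, 2, 3, 4])
        X = rng.standard_normal((30, 300))
        Z = apply_csp(model, X)
        assert Z.shape == (8, 300)
        np.testing.assert_allclose(apply_csp(model, 3.0 * X), 3.0 * Z)

    def test_dimension_mismatch_rejected(self):
        from roicsp.csp import CSPModel
        model = CSPModel(W=np.eye(4), class_order=[1, 2])
        with pytest.raises(ValueError):
            apply_csp(model, np.zeros((5, 10)))

    def test_uniform_variances(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(100)
        Z = np.stack([base * s for s in [1, -1, 1, -1, 1, -1, 1, -1]])
        v = log_variance_features(Z)
        np.testing.assert_allclose(v, np.log(1 / 8), atol=1e-12)

    def test_known_variance_ratio(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(50_000)
        Z = np.stack([np.sqrt(3.0) * z, z])
        v = log_variance_features(Z)
        np.testing.assert_allclose(v, [np.log(3 / 4), np.log(1 / 4)],
                                   atol=1e-12)

    def test_zero_variance_row_rejected(self):
        Z = np.vstack([np.ones(10), np.random.default_rng(4).standard_normal(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            log_variance_features(Z)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), L=st.integers(2, 10),
           scale=st.floats(0.01, 100.0))
    def test_normalization_identity_and_scale_invariance(self, seed, L, scale):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((L, 64))
        v = log_variance_features(Z)
        assert abs(np.exp(v).sum() - 1.0) < 1e-9
        assert np.all(v <= 1e-12)
        np.testing.assert_allclose(log_variance_features(scale * Z), v,
                                   atol=1e-9)


class TestOneVsRestCSPEstimator:
    def test_fit_transform_shapes_and_agreement_with_ops(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 6, 80))
        y = np.repeat([1, 2, 3, 4], 6)
        est = OneVsRestCSP(filters_per_class=2).fit(X, y)
        F = est.transform(X)
        assert F.shape == (24, 8)
        # feature path through the public ops gives identical numbers
        manual = np.stack([
            log_variance_features(apply_csp(est.model_, X[t] -
                                            X[t].mean(axis=1, keepdims=True)))
            for t in range(24)])
        np.testing.assert_allclose(F, manual, atol=1e-9)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = OneVsRestCSP(filters_per_class=4)
        assert clone(est).get_params() == est.get_params()
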