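"""Gaussian class models, target-point mapping, and the closed-form solver."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sstmis.data import FeatureMatrix
from sstmis.sstm import (
    AffineMap,
    ClassStatistics,
    apply_inverse,
    class_statistics,
    confidence_weights,
    fit_style_map,
    gaussian_map,
    mahalanobis,
    solve_affine,
    sstm_objective,
)


class TestClassStatistics:
    def test_two_point_hand_case_full_shrinkage(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        stats = class_statistics(X, np.array([1, 1]), shrinkage=1.0)[1]
        np.testing.assert_allclose(stats.mu, [1.0, 1.0])
        # S (MLE) has diag 1; tr(S)/m = 1 -> Sigma = I
        np.testing.assert_allclose(stats.sigma, np.eye(2))

    def test_identical_points_without_shrinkage_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="positive definite"):
            class_statistics(X, np.ones(5, int), shrinkage=0.0)

    def test_shrinkage_guarantees_positive_definite(self, rng):
        X = rng.standard_normal((50, 5))
        stats = class_statistics(X, np.ones(50, int), shrinkage=0.1)[1]
        assert np.linalg.eigvalsh(stats.sigma).min() > 0

    def test_class_below_two_instances_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="need >= 2"):
            class_statistics(X, np.array([1, 1, 2]))

    def test_high_dim_small_class_stays_pd(self, rng):
        # m > class size: raw covariance is singular, shrinkage rescues it
        X = rng.standard_normal((8, 20))
        stats = class_statistics(X, np.ones(8, int), shrinkage=0.1)[1]
        assert np.linalg.eigvalsh(stats.sigma).min() > 0


class TestMahalanobis:
    def stats(self, mu, sigma):
        return ClassStatistics(label=1, mu=np.asarray(mu, float),
                               sigma=np.asarray(sigma, float), shrinkage=0.0)

    def test_distance_at_mean_is_zero(self):
        s = self.stats([1.0, -2.0], np.diag([2.0, 3.0]))
        assert mahalanobis(np.array([1.0, -2.0]), s) == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        s = self.stats(np.zeros(4), np.eye(4))
        t = rng.standard_normal(4)
        assert mahalanobis(t, s) == pytest.approx(np.linalg.norm(t))

    def test_hand_case_diag_covariance(self):
        s = self.stats([0.0, 0.0], np.diag([4.0, 1.0]))
        assert mahalanobis(np.array([2.0, 1.0]), s) == pytest.approx(np.sqrt(2.0))

    def test_batch_matches_single(self, rng):
        s = self.stats(rng.standard_normal(3), np.eye(3) * 2)
        T = rng.standard_normal((6, 3))
        batch = mahalanobis(T, s)
        for i in range(6):
            assert batch[i] == pytest.approx(mahalanobis(T[i], s))


class TestGaussianMap:
    def make_stats(self, m=2):
        return {
            1: ClassStatistics(label=1, mu=np.zeros(m), sigma=np.eye(m), shrinkage=0.0)
        }

    def test_sample_at_mean_stays_put(self):
        stats = self.make_stats()
        out = gaussian_map(np.zeros((1, 2)), np.array([1]), stats, "fixed", rho=1.0)
        np.testing.assert_allclose(out.O[0], [0.0, 0.0])
        assert out.factor[0] == 1.0

    def test_distance_twice_rho_lands_at_midpoint(self):
        stats = self.make_stats()
        t = np.array([[4.0, 0.0]])  # d = 4 with identity covariance
        out = gaussian_map(t, np.array([1]), stats, "fixed", rho=2.0)
        np.testing.assert_allclose(out.O[0], [2.0, 0.0])

    def test_infinite_rho_is_identity(self, rng):
        stats = self.make_stats()
        T = rng.standard_normal((10, 2))
        out = gaussian_map(T, np.ones(10, int), stats, "fixed", rho=1e12)
        np.testing.assert_allclose(out.O, T)

    def test_near_samples_kept_far_samples_on_rho_ellipsoid(self):
        stats = self.make_stats()
        T = np.array([[0.5, 0.0], [8.0, 0.0]])
        out = gaussian_map(T, np.ones(2, int), stats, "fixed", rho=1.0)
        np.testing.assert_allclose(out.O[0], [0.5, 0.0])  # d < rho: unchanged
        np.testing.assert_allclose(out.O[1], [1.0, 0.0])  # pulled to the shell

    def test_class_mean_distance_rho_equals_mean_d(self, rng):
        stats = self.make_stats()
        T = rng.standard_normal((50, 2)) * 3
        out = gaussian_map(T, np.ones(50, int), stats, "class_mean_distance")
        assert out.rho[1] == pytest.approx(np.linalg.norm(T, axis=1).mean())

    def test_unknown_label_rejected(self):
        stats = self.make_stats()
        with pytest.raises(ValueError, match=r"\[2\]"):
            gaussian_map(np.zeros((1, 2)), np.array([2]), stats, "fixed", rho=1.0)


class TestConfidenceWeights:
    def test_unit_mode_all_ones(self, rng):
        d = rng.uniform(0, 5, 20)
        f = confidence_weights(d, mode="unit").f
        np.testing.assert_array_equal(f, 1.0)

    def test_gaussian_mode_decreases_with_distance(self):
        d = np.array([0.0, 1.0, 3.0])
        f = confidence_weights(d, mode="gaussian", m=4).f
        assert f[0] == pytest.approx(1.0)
        assert f[0] > f[1] > f[2] > 0


def numeric_minimizer(O, T, f, beta, gamma):
    """Generic oracle: gradient-based minimization of the raw objective."""
    n, m = O.shape

    def obj_grad(p):
        A = p[: m * m].reshape(m, m)
        b = p[m * m :]
        resid = O @ A.T + b - T
        val = (
            float(np.sum(f * np.einsum("ij,ij->i", resid, resid)))
            + beta * np.sum((A - np.eye(m)) ** 2)
            + gamma * np.sum(b**2)
        )
        gA = 2 * (resid * f[:, None]).T @ O + 2 * beta * (A - np.eye(m))
        gb = 2 * (f @ resid) + 2 * gamma * b
        return val, np.concatenate([gA.ravel(), gb])

    x0 = np.concatenate([np.eye(m).ravel(), np.zeros(m)])
    res = minimize(obj_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun


class TestSolveAffine:
    def test_identity_fixed_point(self, rng):
        O = rng.standard_normal((20, 3))
        amap = solve_affine(O, O.copy(), beta=0.5, gamma=1.0)
        np.testing.assert_allclose(amap.A, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(amap.b, 0.0, atol=1e-12)

    def test_exact_recovery_unregularized(self, rng):
        m, n = 5, 40
        O = rng.standard_normal((n, m))
        A0 = rng.standard_normal((m, m)) + 2 * np.eye(m)
        b0 = rng.standard_normal(m)
        amap = solve_affine(O, O @ A0.T + b0, beta=0.0, gamma=0.0)
        assert np.linalg.norm(amap.A - A0) < 1e-8
        assert np.linalg.norm(amap.b - b0) < 1e-8

    @pytest.mark.parametrize("beta, gamma", [(0.01, 0.01), (0.2, 2.0), (10.0, 10.0)])
    def test_matches_numerical_minimizer(self, rng, beta, gamma):
        m, n = 4, 30
        O = rng.standard_normal((n, m))
        T = O @ (np.eye(m) + 0.3 * rng.standard_normal((m, m))) + rng.standard_normal(m)
        f = rng.uniform(0.2, 2.0, n)
        amap = solve_affine(O, T, f, beta, gamma)
        closed = sstm_objective(amap.A, amap.b, O, T, f, beta, gamma)
        numeric = numeric_minimizer(O, T, f, beta, gamma)
        assert closed <= numeric * (1 + 1e-6)
        assert abs(closed - numeric) / abs(numeric) < 1e-6

    def test_beats_random_perturbations(self, rng):
        m, n = 4, 30
        O = rng.standard_normal((n, m))
        T = O @ (np.eye(m) + 0.2 * rng.standard_normal((m, m))) + 1.0
        amap = solve_affine(O, T, beta=0.2, gamma=2.0)
        best = sstm_objective(amap.A, amap.b, O, T, None, 0.2, 2.0)
        for _ in range(1000):
            dA = amap.A + 1e-3 * rng.standard_normal((m, m))
            db = amap.b + 1e-3 * rng.standard_normal(m)
            assert sstm_objective(dA, db, O, T, None, 0.2, 2.0) >= best

    def test_non_transfer_limit(self, rng):
        m, n = 6, 50
        O = rng.standard_normal((n, m))
        T = rng.standard_normal((n, m)) * 3 + 5
        amap = solve_affine(O, T, beta=1e8, gamma=1e8)
        assert np.linalg.norm(amap.A - np.eye(m)) < 1e-3
        assert np.linalg.norm(amap.b) < 1e-3

    def test_centered_data_without_regularization_gives_zero_offset(self, rng):
        m, n = 3, 25
        O = rng.standard_normal((n, m))
        T = rng.standard_normal((n, m))
        O -= O.mean(axis=0)
        T -= T.mean(axis=0)
        amap = solve_affine(O, T, beta=0.0, gamma=0.0)
        np.testing.assert_allclose(amap.b, 0.0, atol=1e-10)

    def test_p_positive_definite_for_any_positive_beta(self, rng):
        # degenerate o-points: rank-1 scatter, still solvable with beta > 0
        o = np.outer(rng.standard_normal(30), rng.standard_normal(4))
        amap = solve_affine(o, rng.standard_normal((30, 4)), beta=0.05, gamma=0.0)
        assert np.all(np.isfinite(amap.A))

    def test_degenerate_data_without_beta_rejected(self, rng):
        o = np.outer(rng.standard_normal(30), rng.standard_normal(4))
        with pytest.raises(ValueError, match="positive definite"):
            solve_affine(o, rng.standard_normal((30, 4)), beta=0.0, gamma=0.0)

    def test_nonpositive_weights_rejected(self, rng):
        O = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="positive"):
            solve_affine(O, O, f=np.array([1.0, 0.0, 1, 1, 1]))


class TestApplyInverse:
    def test_identity_map_is_noop(self, rng):
        amap = AffineMap(A=np.eye(3), b=np.zeros(3))
        T = rng.standard_normal((7, 3))
        np.testing.assert_array_equal(apply_inverse(amap, T), T)

    def test_round_trip(self, rng):
        m = 4
        amap = AffineMap(A=np.eye(m) + 0.2 * rng.standard_normal((m, m)),
                         b=rng.standard_normal(m))
        T = rng.standard_normal((10, m))
        np.testing.assert_allclose(amap.forward(apply_inverse(amap, T)), T, atol=1e-9)

    def test_hand_arithmetic(self):
        amap = AffineMap(A=2 * np.eye(3), b=np.ones(3))
        out = apply_inverse(amap, np.full((1, 3), 3.0))
        np.testing.assert_allclose(out, 1.0)

    def test_ill_conditioned_map_refused_with_advice(self):
        A = np.diag([1.0, 1e-14])
        amap = AffineMap(A=A, b=np.zeros(2))
        with pytest.raises(ValueError, match="beta"):
            apply_inverse(amap, np.zeros((1, 2)))

    def test_feature_matrix_metadata_preserved(self, rng):
        amap = AffineMap(A=np.eye(2) * 2, b=np.zeros(2))
        fm = FeatureMatrix(X=rng.standard_normal((4, 2)), y=np.array([1, 1, 2, 2]),
                           subject="T", session=np.array([1, 1, 2, 2]))
        out = apply_inverse(amap, fm)
        assert out.subject == "T"
        np.testing.assert_array_equal(out.y, fm.y)
        np.testing.assert_allclose(out.X, fm.X / 2)


class TestAffineMapSerialization:
    def test_json_round_trip(self, rng):
        amap = AffineMap(A=rng.standard_normal((3, 3)) + 3 * np.eye(3),
                         b=rng.standard_normal(3))
        back = AffineMap.from_json(amap.to_json(beta=0.2))
        np.testing.assert_array_equal(back.A, amap.A)
        np.testing.assert_array_equal(back.b, amap.b)


def test_fit_style_map_end_to_end(small_cohort):
    from sstmis.evaluation import calibration_split, loso_split
    from sstmis.instance_selection import SelectedInstances

    ds, _ = small_cohort
    pool, target = loso_split(ds, "S01")
    T_L, _ = calibration_split(target)
    sel = SelectedInstances(X=pool.fm.X, y=pool.fm.y, k=0,
                            scores=np.ones(pool.fm.n),
                            origin_subject=pool.row_subject,
                            origin_index=pool.row_index)
    amap, stats, mapped = fit_style_map(sel, T_L)
    assert amap.m == ds.m
    assert set(stats) == set(ds.classes.tolist())
    assert mapped.O.shape == T_L.X.shape
    # clamped samples (factor 1) keep their position
    keep = mapped.factor >= 1.0
    np.testing.assert_allclose(mapped.O[keep], T_L.X[keep])
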