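"""Spatial constraints, loss, d-prime, SOM training and gradient ascent."""
import numpy as np
import pytest
import scipy.ndimage as ndi

from cortexmap import models
from cortexmap.exceptions import ArgumentError, DegenerateDataError


class TestConstraints:
    @pytest.mark.parametrize("kind", ["reciprocal", "laplacian_of_gaussian", "gaussian"])
    def test_unity_at_zero(self, kind):
        assert models.constraint_value(models.SpatialConstraint(kind, 1.3), 0.0) == 1.0

    def test_reciprocal_closed_form(self):
        c = models.SpatialConstraint("reciprocal", 1.0)
        assert models.constraint_value(c, 1.0) == 0.5
        assert models.constraint_value(c, 3.0) == 0.25

    def test_gaussian_point_spread_anchor(self):
        """sigma = 1.25 mm puts the neighborhood at 10% of peak 2.7 mm out,
        the measured cortical point-spread scale."""
        c = models.SpatialConstraint("gaussian", 1.25)
        assert models.constraint_value(c, 2.7) == pytest.approx(0.097, abs=0.0005)

    def test_log_zero_crossing_at_sqrt2_s(self):
        c = models.SpatialConstraint("laplacian_of_gaussian", 2.0)
        assert models.constraint_value(c, 2.0 * np.sqrt(2)) == pytest.approx(0.0, abs=1e-12)

    def test_bad_scale_rejected(self):
        with pytest.raises(ArgumentError):
            models.SpatialConstraint("gaussian", 0.0)


class TestProfileCorrelation:
    def test_exact_values(self, rng):
        r = rng.normal(size=100)
        assert models.profile_correlation(r, r) == pytest.approx(1.0)
        assert models.profile_correlation(r, -r) == pytest.approx(-1.0)

    def test_null_bound_for_random_profiles(self, rng):
        hits = 0
        for _ in range(100):
            a, b = rng.normal(size=(2, 2500))
            hits += abs(models.profile_correlation(a, b)) < 0.07
        assert hits >= 95

    def test_constant_profile_rejected(self):
        with pytest.raises(DegenerateDataError):
            models.profile_correlation(np.ones(10), np.arange(10.0))


class TestSpatialLoss:
    def test_two_unit_closed_form(self):
        """Identical profiles (C = 1) against f(d) = 0.5 cost (0.5)^2."""
        R = np.tile(np.arange(5.0), (2, 1))
        P = np.array([[0.0, 0.0], [1.0, 0.0]])
        c = models.SpatialConstraint("reciprocal", 1.0)  # f(1) = 0.5
        assert models.spatial_loss(R, P, c) == pytest.approx(0.25)

    def test_engineered_zero_loss(self):
        """Two anticorrelated profile pairs at the distance where f = -? No:
        place both units at distance 0-ish so f ~ 1 and C = 1."""
        R = np.tile(np.arange(6.0), (2, 1))
        P = np.zeros((2, 2))
        c = models.SpatialConstraint("gaussian", 1.0)
        assert models.spatial_loss(R, P, c) == pytest.approx(0.0)

    def test_matches_bruteforce_double_loop(self, rng):
        R = rng.normal(size=(20, 40))
        P = rng.uniform(0, 10, size=(20, 2))
        c = models.SpatialConstraint("laplacian_of_gaussian", 4.0)
        loss = models.spatial_loss(R, P, c)
        acc = []
        for i in range(20):
            for j in range(i + 1, 20):
                cij = np.corrcoef(R[i], R[j])[0, 1]
                fij = models.constraint_value(c, np.linalg.norm(P[i] - P[j]))
                acc.append((cij - fij) ** 2)
        assert loss == pytest.approx(np.mean(acc), rel=1e-12)

    def test_permutation_invariance(self, rng):
        R = rng.normal(size=(15, 30))
        P = rng.uniform(0, 8, size=(15, 2))
        c = models.SpatialConstraint("reciprocal", 1.0)
        perm = rng.permutation(15)
        assert models.spatial_loss(R, P, c) == pytest.approx(
            models.spatial_loss(R[perm], P[perm], c), rel=1e-12
        )


class TestDPrime:
    def test_equal_means_none(self, rng):
        x = rng.normal(size=50)
        res = models.dprime(x, x)
        assert res.d_prime == pytest.approx(0.0) and res.label == "none"

    def test_unit_dprime_closed_form(self, rng):
        f = rng.normal(loc=2.0, scale=1.0, size=100000)
        o = rng.normal(loc=1.0, scale=1.0, size=100000)
        res = models.dprime(f, o)
        assert res.d_prime == pytest.approx(1.0, abs=0.02)
        assert res.label == "face"

    def test_threshold_boundary_inclusive(self):
        """Exactly d' = 0.85 labels the unit face-selective."""
        base = np.array([-1.0, 1.0])  # variance 2 (ddof=1)
        shift = 0.85 * np.sqrt(2.0)
        res = models.dprime(base + shift, base)
        assert res.d_prime == pytest.approx(0.85)
        assert res.label == "face"
        res2 = models.dprime(base, base + shift)
        assert res2.label == "object"


class TestSOM:
    def _cluster_inputs(self, rng, n=400, noise=0.15):
        e = np.eye(25)
        X = np.vstack([np.tile(e[0], (n // 2, 1)), np.tile(-e[0], (n // 2, 1))])
        X = X + noise * rng.normal(size=X.shape)
        return X / np.linalg.norm(X, axis=1, keepdims=True)

    def test_schedule_endpoint(self):
        c = models.SpatialConstraint("gaussian", 1.25)
        st = models.SOMState(np.zeros((1, 2)), np.ones((1, 25)), np.ones((1, 1), bool),
                             2.0, c, T=1000, t=0)
        assert st.learning_rate() == 1.0
        st.t = 1000
        assert st.learning_rate() == pytest.approx(1 / 3)

    def test_weights_unit_norm_after_training(self, rng):
        X = self._cluster_inputs(rng)
        st = models.som_train(X, np.ones((6, 6), bool),
                              models.SpatialConstraint("gaussian", 2.5), T=2000, seed=0)
        np.testing.assert_allclose(np.linalg.norm(st.weights, axis=1), 1.0, atol=1e-12)

    def test_seed_determinism(self, rng):
        X = self._cluster_inputs(rng)
        c = models.SpatialConstraint("gaussian", 2.5)
        a = models.som_train(X, np.ones((5, 5), bool), c, T=1000, seed=7)
        b = models.som_train(X, np.ones((5, 5), bool), c, T=1000, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_antipodal_clusters_form_contiguous_domains(self, rng):
        X = self._cluster_inputs(rng, n=600)
        st = models.som_train(X, np.ones((10, 10), bool),
                              models.SpatialConstraint("gaussian", 2.5),
                              T=30000, seed=3)
        pref = (st.weights @ np.eye(25)[0] > 0).reshape(10, 10)
        for side in (pref, ~pref):
            lab, n = ndi.label(side)
            sizes = np.bincount(lab.ravel())[1:]
            assert sizes.max() / sizes.sum() >= 0.8

    def test_longer_training_does_not_hurt_quantization(self, rng):
        """Statistically over seeds, doubling T never increases the final
        quantization error."""
        X = self._cluster_inputs(rng)
        c = models.SpatialConstraint("gaussian", 2.0)
        diffs = []
        for s in range(20):
            a = models.som_train(X, np.ones((6, 6), bool), c, T=500, seed=s)
            b = models.som_train(X, np.ones((6, 6), bool), c, T=1000, seed=s)
            diffs.append(
                models.som_quantization_error(b, X) - models.som_quantization_error(a, X)
            )
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        # longer training must not significantly increase quantization error
        assert diffs.mean() <= 3 * se

    def test_feature_map_equals_weights_one_unit_per_cell(self, rng):
        X = self._cluster_inputs(rng)
        mask = np.zeros((4, 5), bool)
        mask[1:3, 1:4] = True
        st = models.som_train(X, mask, models.SpatialConstraint("gaussian", 2.0),
                              T=500, seed=0)
        fmap = models.som_feature_map(st)
        np.testing.assert_allclose(fmap.vectors(), st.weights, atol=1e-12)
        assert not fmap.mask[0, 0]

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ArgumentError):
            models.som_train(self._cluster_inputs(rng), np.zeros((3, 3), bool),
                             models.SpatialConstraint("gaussian", 1.0), T=10)


class TestFiniteDifferenceAscent:
    def test_paired_differences_cancel_curvature_exactly(self, rng):
        """For f = w.x + x.A.x the paired differences depend only on the
        gradient at x, so the estimate equals that of the pure linear part."""
        w = rng.normal(size=10)
        A = rng.normal(size=(10, 10))

        def quad(x):
            return float(w @ x + x @ A @ x)

        seed_state = rng.bit_generator.state
        g_quad, ok = models.fd_gradient_estimate(quad, np.zeros(10), 20, 0.1, rng)
        rng.bit_generator.state = seed_state
        g_lin, ok2 = models.fd_gradient_estimate(lambda x: float(w @ x), np.zeros(10), 20, 0.1, rng)
        assert ok and ok2
        np.testing.assert_allclose(g_quad, g_lin, atol=1e-10)
        # and the positive alignment with the true gradient direction
        assert g_lin @ w > 0

    def test_unbiased_direction_on_quadratic(self, rng):
        """Mean estimate over resamples aligns with the analytic gradient."""
        A = np.diag(rng.uniform(0.5, 2.0, 6))
        x0 = rng.normal(size=6)
        true_grad = -2 * A @ x0

        def obj(x):
            return -float(x @ A @ x)

        n = 2000
        ests = np.array(
            [models.fd_gradient_estimate(obj, x0, 5, 0.1, rng)[0] for _ in range(n)]
        )
        mean = ests.mean(axis=0)
        se = ests.std(axis=0, ddof=1) / np.sqrt(n)
        scale = (mean @ true_grad) / (true_grad @ true_grad)
        assert scale > 0
        assert np.all(np.abs(mean - scale * true_grad) < 4 * se + 1e-9)

    def test_quadratic_convergence(self, rng):
        target = rng.normal(size=25)
        res = models.finite_difference_ascent(
            lambda x: -np.sum((x - target) ** 2), np.zeros(25), steps=500, seed=0
        )
        assert not res.aborted
        assert np.linalg.norm(res.x - target) < 0.05

    def test_cosine_to_axis_objective(self, rng):
        """The synthesis-style objective: maximize cosine to a target axis."""
        u = rng.normal(size=25)
        u /= np.linalg.norm(u)

        def obj(x):
            n = np.linalg.norm(x)
            return float(x @ u / n) if n > 0 else 0.0

        res = models.finite_difference_ascent(obj, rng.normal(size=25), steps=400, seed=1)
        assert res.trajectory[-1] > 0.99

    def test_nonfinite_objective_aborts_with_trajectory(self):
        calls = {"n": 0}

        def obj(x):
            calls["n"] += 1
            return float("nan") if calls["n"] > 30 else float(x.sum())

        res = models.finite_difference_ascent(obj, np.zeros(4), K=5, steps=50, seed=0)
        assert res.aborted and len(res.trajectory) >= 1
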