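import numpy as np
import pytest

from mvfcm.core import FitConfig, MultiViewData
from mvfcm.fcm import fcm_fit, fcm_objective, fcm_update_centers, init_memberships
from mvfcm.imvfcm import (imv_ensemble, imv_fit, imv_objective,
                          imv_update_centers, imv_update_memberships,
                          imv_update_weights, initial_weights,
                          partition_scatter, weights_from_scatter)
from mvfcm.phantom import MixtureSpec, generate_mixture_mvd


def _random_state(rng, n=6, c=2, v=2, dims=(1, 2)):
    data = MultiViewData([rng.normal(size=(n, p)) for p in dims])
    u = init_memberships(rng, c, n, v)
    w = rng.dirichlet(np.ones(v), size=v)
    return data, u, w


class TestObjective:
    def test_entropy_term_only_with_points_on_centers(self):
        # two identical samples per cluster sitting exactly on the centers
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        u = np.array([[1.0, 1, 0, 0], [0, 0, 1, 1]])
        data = MultiViewData([x, x.copy()])
        centers = [np.array([[0.0], [5.0]])] * 2
        v = 2
        gamma = 3.0
        j = imv_objective(data, centers, np.stack([u, u]),
                          np.full((v, v), 1 / v), 2.0, gamma)
        assert j == pytest.approx(-gamma * v * np.log(v), abs=1e-12)

    def test_single_view_reduces_to_fcm_objective(self, rng):
        x = rng.normal(size=(7, 2))
        z = rng.normal(size=(3, 2))
        u = init_memberships(rng, 3, 7, 1)[0]
        j = imv_objective(MultiViewData([x]), [z], u[None], np.array([[1.0]]),
                          2.0, 4.0)
        assert j == pytest.approx(fcm_objective(x, z, u, 2.0), rel=1e-12)

    def test_one_hot_weight_rows_kill_entropy_term(self, rng):
        data, u, _ = _random_state(rng)
        z = imv_update_centers(data, u, np.eye(2), 2.0)
        d2 = np.stack([((zz[:, None, :] - xx[None]) ** 2).sum(-1)
                       for zz, xx in zip(z, data.views)])
        s = partition_scatter(d2, u, 2.0)
        # gamma should not matter when every row of W is one-hot
        j1 = imv_objective(data, z, u, np.eye(2), 2.0, 1.0)
        j2 = imv_objective(data, z, u, np.eye(2), 2.0, 100.0)
        assert j1 == pytest.approx(float(np.trace(s)), rel=1e-12)
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_nonpositive_gamma_rejected(self, rng):
        data, u, w = _random_state(rng)
        z = imv_update_centers(data, u, w, 2.0)
        with pytest.raises(ValueError, match="gamma"):
            imv_objective(data, z, u, w, 2.0, 0.0)


class TestCenterUpdate:
    def test_single_view_equals_fcm_centers(self, rng):
        x = rng.normal(size=(9, 2))
        u = init_memberships(rng, 3, 9, 1)
        z = imv_update_centers(MultiViewData([x]), u, np.array([[1.0]]), 2.0)
        assert np.allclose(z[0], fcm_update_centers(x, u[0], 2.0))

    def test_uniform_weights_and_equal_memberships_match_fcm(self, rng):
        data = MultiViewData([rng.normal(size=(8, 1)), rng.normal(size=(8, 2))])
        one = init_memberships(rng, 2, 8, 1)[0]
        z = imv_update_centers(data, np.stack([one, one]),
                               np.full((2, 2), 0.5), 2.0)
        for v in range(2):
            assert np.allclose(z[v], fcm_update_centers(data.views[v], one, 2.0))

    def test_hand_evaluated_blended_center(self):
        data = MultiViewData([np.array([[0.0], [6.0]]), np.array([[0.0], [6.0]])])
        u = np.array([[[0.8, 0.2], [0.2, 0.8]], [[0.6, 0.4], [0.4, 0.6]]])
        w = np.array([[0.75, 0.25], [0.5, 0.5]])
        z = imv_update_centers(data, u, w, 2.0)
        assert z[0][0, 0] == pytest.approx(0.65625, abs=1e-12)


class TestMembershipUpdate:
    def test_single_view_reduces_to_fcm_update(self, rng):
        from mvfcm.fcm import fcm_update_memberships
        d2 = rng.uniform(0.1, 5, size=(1, 3, 6))
        u = imv_update_memberships(d2, np.array([[1.0]]), 2.0)
        assert np.allclose(u[0], fcm_update_memberships(d2[0], 2.0))

    def test_equal_aggregated_distances_uniform(self):
        d2 = np.full((2, 4, 5), 2.0)
        u = imv_update_memberships(d2, np.full((2, 2), 0.5), 2.0)
        assert np.allclose(u, 0.25)

    def test_hand_evaluated_aggregate_split(self):
        # aggregates 1 vs 4 for the single sample, m=2 -> (0.8, 0.2)
        d2 = np.stack([np.array([[1.0], [4.0]]), np.array([[1.0], [4.0]])])
        u = imv_update_memberships(d2, np.full((2, 2), 0.5), 2.0)
        for t in range(2):
            assert np.allclose(u[t][:, 0], [0.8, 0.2], atol=1e-12)


class TestWeightUpdate:
    def test_equal_scatter_gives_uniform_rows(self):
        w = weights_from_scatter(np.full((3, 3), 5.0), 1.0)
        assert np.allclose(w, 1 / 3)

    def test_huge_gamma_flattens_to_uniform(self, rng):
        s = rng.uniform(1, 10, size=(3, 3))
        w = weights_from_scatter(s, 1e9 * s.max())
        assert np.max(np.abs(w - 1 / 3)) < 1e-6

    def test_tiny_gamma_concentrates_on_row_argmin(self, rng):
        s = rng.uniform(1, 10, size=(4, 4))
        w = weights_from_scatter(s, 1e-4)
        assert (w.max(axis=1) >= 1 - 1e-6).all()
        assert (w.argmax(axis=1) == s.argmin(axis=1)).all()

    def test_hand_evaluated_softmax(self):
        w = weights_from_scatter(np.array([[1.0, 2.0]]), 1.0)
        assert np.allclose(w, [[0.7310585786300049, 0.2689414213699951]],
                           atol=1e-12)

    def test_invariant_to_row_shifts(self, rng):
        """Log-sum-exp contract: adding a per-row constant to S changes nothing."""
        s = rng.uniform(0, 5, size=(3, 4))
        shifted = s + rng.uniform(-100, 100, size=(3, 1))
        assert np.allclose(weights_from_scatter(s, 2.0),
                           weights_from_scatter(shifted, 2.0), atol=1e-12)

    def test_overflow_safe_for_extreme_scatter(self):
        s = np.array([[0.0, 1e8], [1e8, 0.0]])
        w = weights_from_scatter(s, 1.0)
        assert np.isfinite(w).all()
        assert np.allclose(w.sum(axis=1), 1.0)

    def test_full_update_from_distances(self, rng):
        d2 = rng.uniform(0, 3, size=(2, 3, 5))
        u = init_memberships(rng, 3, 5, 2)
        w = imv_update_weights(d2, u, 2.0, 1.0)
        s = partition_scatter(d2, u, 2.0)
        assert np.allclose(w, weights_from_scatter(s, 1.0), atol=1e-15)


class TestEnsemble:
    def test_single_view_identity(self, rng):
        u = init_memberships(rng, 3, 6, 1)
        fused, labels = imv_ensemble(u, np.array([[1.0]]))
        assert np.allclose(fused, u[0])
        assert (labels == u[0].argmax(axis=0)).all()

    def test_uniform_weights_give_arithmetic_mean(self, rng):
        u = init_memberships(rng, 2, 5, 3)
        fused, _ = imv_ensemble(u, np.full((3, 3), 1 / 3))
        assert np.allclose(fused, u.mean(axis=0))

    def test_hand_evaluated_fusion_and_label(self):
        u = np.stack([np.array([[0.6], [0.4]]), np.array([[0.3], [0.7]])])
        fused, labels = imv_ensemble(u, np.full((2, 2), 0.5))
        assert np.allclose(fused.ravel(), [0.45, 0.55], atol=1e-12)
        assert labels[0] == 1

    def test_fused_matrix_column_stochastic(self, rng):
        u = init_memberships(rng, 4, 10, 3)
        w = rng.dirichlet(np.ones(3), size=3)
        fused, _ = imv_ensemble(u, w)
        assert np.allclose(fused.sum(axis=0), 1.0, atol=1e-9)


class TestInitialWeights:
    def test_schemes_are_row_stochastic(self, rng):
        for scheme in ("diagonal", "uniform", "random"):
            w = initial_weights(4, scheme, rng=rng)
            assert np.allclose(w.sum(axis=1), 1.0)
            assert (w >= 0).all()

    def test_diagonal_scheme_anchors_own_view(self):
        w = initial_weights(3, "diagonal")
        assert (np.diag(w) > w.max(axis=1) - 1e-12).all()


class TestFit:
    def test_single_view_run_equals_fcm_from_same_seed(self):
        data, _ = generate_mixture_mvd(MixtureSpec(n_samples=100, n_views=1, seed=3))
        cfg = FitConfig(n_clusters=3, seed=3)
        a = fcm_fit(data, cfg)
        b = imv_fit(data, cfg)
        assert np.max(np.abs(a.fused_membership.values
                             - b.fused_membership.values)) < 1e-12
        assert np.allclose(a.objective_trace, b.objective_trace)

    def test_deterministic_given_seed(self):
        data, _ = generate_mixture_mvd(MixtureSpec(n_samples=80, seed=11))
        cfg = FitConfig(n_clusters=3, seed=11)
        a, b = imv_fit(data, cfg), imv_fit(data, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.weights.values, b.weights.values, atol=0)
        assert a.objective_trace == b.objective_trace

    def test_view_permutation_equivariance(self, rng):
        data, _ = generate_mixture_mvd(MixtureSpec(n_samples=60, seed=9))
        u0 = init_memberships(rng, 3, 60, 2)
        w0 = initial_weights(2, "diagonal")
        cfg = FitConfig(n_clusters=3, gamma=5.0, max_iter=15)
        res = imv_fit(data, cfg, init_membership=u0, init_weight=w0)
        swapped = MultiViewData([data.views[1], data.views[0]])
        res_s = imv_fit(swapped, cfg, init_membership=u0[::-1].copy(),
                        init_weight=w0[::-1, ::-1].copy())
        assert np.allclose(res.weights.values, res_s.weights.values[::-1, ::-1])
        for v in range(2):
            assert np.allclose(res.per_view_membership[v].values,
                               res_s.per_view_membership[1 - v].values)

    def test_constraints_hold_every_iteration(self):
        data, _ = generate_mixture_mvd(MixtureSpec(n_samples=70, seed=4))
        checks = []

        def hook(it, u, z, w):
            checks.append((np.abs(u.sum(axis=1) - 1).max(),
                           np.abs(w.sum(axis=1) - 1).max()))

        imv_fit(data, FitConfig(n_clusters=3, seed=4), iteration_hook=hook)
        assert checks
        assert max(c[0] for c in checks) < 1e-9
        assert max(c[1] for c in checks) < 1e-9

    def test_auto_gamma_recorded_and_positive(self):
        data, _ = generate_mixture_mvd(MixtureSpec(n_samples=50, seed=6))
        res = imv_fit(data, FitConfig(n_clusters=3, seed=6))
        assert res.params["gamma"] > 0

    def test_objective_trace_non_increasing(self, rng):
        data = MultiViewData([rng.normal(size=(90, 2)), rng.normal(size=(90, 1))])
        res = imv_fit(data, FitConfig(n_clusters=3, seed=8, gamma=2.0, max_iter=40))
        t = np.asarray(res.objective_trace)
        assert np.all(np.diff(t) <= 1e-10)
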