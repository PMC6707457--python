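import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from alstructure import (
    cals,
    fit_alstructure,
    project_to_simplex,
    tals,
    truncate_unit_interval,
)
from alstructure.factorization import project_columns_to_simplex

real_vectors = arrays(
    np.float64,
    st.integers(1, 8),
    elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
)


class TestSimplexProjection:
    def test_point_on_simplex_is_fixed(self):
        np.testing.assert_allclose(project_to_simplex(np.array([0.5, 0.5])), [0.5, 0.5])

    def test_dominant_coordinate_saturates(self):
        np.testing.assert_allclose(project_to_simplex(np.array([2.0, 0.0, 0.0])), [1.0, 0.0, 0.0])

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            project_to_simplex(np.array([]))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(real_vectors)
    def test_output_on_simplex_and_idempotent(self, v):
        w = project_to_simplex(v)
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(project_to_simplex(w), w, atol=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(real_vectors)
    def test_is_closest_point_kkt(self, v):
        # Euclidean optimality: moving mass between any two coordinates
        # of the projection cannot reduce the distance to v
        w = project_to_simplex(v)
        grad = w - v
        active = w > 1e-12
        if active.any():
            lam = grad[active]
            assert lam.max() - lam.min() < 1e-9  # equal multipliers on support
            assert np.all(grad[~active] >= lam.max() - 1e-9)

    def test_columnwise_matches_vector_version(self, rng):
        V = rng.standard_normal((5, 40))
        cols = project_columns_to_simplex(V)
        for j in range(40):
            np.testing.assert_allclose(cols[:, j], project_to_simplex(V[:, j]), atol=1e-12)


class TestTruncation:
    @pytest.mark.parametrize("x,expected", [(1.3, 1.0), (-0.2, 0.0), (0.42, 0.42)])
    def test_entrywise(self, x, expected):
        assert truncate_unit_interval(np.array([x]))[0] == expected


def _noiseless_instance(seed=5, m=1000, n=100, d=3):
    """Exact F = PQ on a strongly identifiable instance.

    Anchor individuals are planted in Q, and P is drawn Balding-Nichols
    with high F_ST (well-differentiated populations, entries spread toward
    0/1) so the constrained factorization is unique up to permutation and
    ALS converges to it quickly.  Weakly differentiated P gives a nearly
    flat objective where ALS approaches the optimum only very slowly.
    """
    from alstructure import sample_balding_nichols

    rng = np.random.default_rng(seed)
    fst = rng.uniform(0.1, 0.5, size=m)
    maf = rng.uniform(0.1, 0.9, size=m)
    P = sample_balding_nichols(fst[:, None], maf[:, None], (m, d), rng)
    Q = rng.dirichlet(np.ones(d), size=n).T
    Q[:, :d] = np.eye(d)  # plant one anchor individual per population
    return P, Q, P @ Q


class TestALS:
    def test_d1_simplex_is_a_point(self, rng):
        F = rng.uniform(0, 1, size=(50, 8))
        res = tals(F, d=1, seed=0)
        np.testing.assert_allclose(res.Q, np.ones((1, 8)), atol=1e-12)
        assert res.P.min() >= 0 and res.P.max() <= 1

    @pytest.mark.parametrize("algorithm", [tals, cals])
    def test_noiseless_exact_recovery(self, algorithm):
        from alstructure import rmse

        P, Q, F = _noiseless_instance()
        res = algorithm(F, d=3, tol=1e-8, max_iter=5000, seed=1)
        assert rmse(res.Q, Q) < 1e-3
        assert res.objective_trace[-1] < 1e-6 * np.linalg.norm(F)

    @pytest.mark.parametrize("algorithm", [tals, cals])
    def test_constraints_hold_exactly(self, small_psd, algorithm):
        from alstructure import estimate_subspace, project_frequencies

        fhat = project_frequencies(small_psd.X, estimate_subspace(small_psd.X, 3))
        res = algorithm(fhat, d=3, max_iter=60, seed=2)
        assert res.P.min() >= 0.0 and res.P.max() <= 1.0
        assert res.Q.min() >= 0.0
        np.testing.assert_allclose(res.Q.sum(axis=0), 1.0, atol=1e-10)

    def test_cals_objective_monotone(self):
        P, Q, F = _noiseless_instance(seed=9, m=300, n=60)
        noisy = np.clip(F + np.random.default_rng(2).normal(0, 0.05, F.shape), 0, 1)
        res = cals(noisy, d=3, tol=1e-7, max_iter=200, seed=3)
        steps = np.diff(res.objective_trace)
        assert steps.max() < 1e-9

    def test_same_seed_is_bit_identical(self, small_psd):
        a = fit_alstructure(small_psd.X, d=3, seed=7, max_iter=40)
        b = fit_alstructure(small_psd.X, d=3, seed=7, max_iter=40)
        np.testing.assert_array_equal(a.Q, b.Q)
        np.testing.assert_array_equal(a.P, b.P)

    def test_sample_relabeling_equivariance(self):
        from alstructure import align_factors

        P, Q, F = _noiseless_instance(seed=11)
        perm = np.random.default_rng(1).permutation(F.shape[1])
        res = tals(F, d=3, tol=1e-7, max_iter=500, seed=4)
        res_perm = tals(F[:, perm], d=3, tol=1e-7, max_iter=500, seed=4)
        # align population labels, then the permuted fit must match columnwise
        rows = align_factors(res_perm.Q, res.Q[:, perm])
        np.testing.assert_allclose(res_perm.Q[rows], res.Q[:, perm], atol=5e-3)

    def test_invalid_inputs(self):
        F = np.full((10, 4), 0.5)
        with pytest.raises(ValueError, match="non-finite"):
            tals(np.full((4, 4), np.nan), d=2)
        with pytest.raises(ValueError, match="tol"):
            tals(F, d=2, tol=0.0)
        with pytest.raises(ValueError, match="d must"):
            tals(F, d=5)


class TestFitPipeline:
    def test_output_contracts(self, small_psd):
        fit = fit_alstructure(small_psd.X, d=3, seed=0, max_iter=80)
        assert fit.F.shape == small_psd.X.shape
        assert fit.P.shape == (small_psd.X.m, 3)
        assert fit.Q.shape == (3, small_psd.X.n)
        assert 0.0 <= fit.clamped_fraction < 0.5
        np.testing.assert_allclose(fit.Q.sum(axis=0), 1.0, atol=1e-10)
        assert fit.eigenvalues.shape == (small_psd.X.n,)

    def test_components_ordered_by_variation_explained(self, small_psd):
        from alstructure import variation_explained

        fit = fit_alstructure(small_psd.X, d=3, seed=0, max_iter=80)
        s2 = variation_explained(small_psd.X, fit.Q)
        assert np.all(np.diff(s2) <= 0)

    def test_unknown_algorithm(self, small_psd):
        with pytest.raises(ValueError, match="algorithm"):
            fit_alstructure(small_psd.X, d=3, algorithm="em")
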