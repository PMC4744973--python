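"""Bray-Curtis, NMDS wrapper, envfit, CCA partitioning and PERMANOVA."""

import itertools
import warnings

import numpy as np
import pytest

from diazobloom import (
    bray_curtis,
    cca,
    fit_external_vector,
    nmds,
    permanova,
)
from diazobloom.ordination import _chi_square_matrix, _gower_center, _permanova_f


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 5.0], [3.0, 0.0]])
        d = bray_curtis(X)
        assert d[0, 1] == 0.0
        assert d[2, 3] == 1.0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_hand_arithmetic(self):
        d = bray_curtis(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_pair_flagged(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        assert d[0, 1] == 0.0


class TestNmds:
    def test_embeddable_configuration_low_stress(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = nmds(d, n_restarts=4, seed=0)
        assert res.stress < 0.05
        assert res.coordinates.shape == (10, 2)

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        a = nmds(d, seed=3)
        b = nmds(d, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_stress_non_increasing_in_restarts(self, rng):
        d = np.abs(rng.normal(size=(20, 20)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        s1 = nmds(d, n_restarts=1, seed=0).stress
        s20 = nmds(d, n_restarts=20, seed=0).stress
        assert s20 <= s1 + 1e-12

    def test_degenerate_distances_flagged(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = nmds(d, seed=0)
        assert res.degenerate


class TestEnvfit:
    def test_axis_variable_r2_one(self, rng):
        coords = rng.normal(size=(30, 2))
        res = fit_external_vector(coords, coords[:, 0], n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_r2_equals_normal_equations_oracle(self, rng):
        coords = rng.normal(size=(6, 2))
        v = rng.normal(size=6)
        res = fit_external_vector(coords, v, n_perm=49, seed=0)
        X = np.column_stack([np.ones(6), coords])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        resid = v - X @ beta
        r2 = 1 - resid @ resid / ((v - v.mean()) ** 2).sum()
        assert res.r2 == pytest.approx(r2, rel=1e-10)
        assert np.linalg.norm(res.direction) == pytest.approx(1.0)

    def test_independent_variable_small_r2(self, rng):
        coords = rng.normal(size=(100, 2))
        res = fit_external_vector(coords, rng.normal(size=100), n_perm=199, seed=1)
        assert res.r2 < 0.15
        assert res.p > 0.01

    def test_constant_variable_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_external_vector(rng.normal(size=(10, 2)), np.ones(10))


class TestCca:
    def test_constant_constraint_zero_inertia(self, rng):
        Y = rng.poisson(5, size=(8, 5)) + 1.0
        res = cca(Y, np.ones(8), n_perm=99, seed=0)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-12)

    def test_saturated_constraints_explain_everything(self, rng):
        n = 6
        Y = rng.poisson(5, size=(n, 4)) + 1.0
        X = rng.normal(size=(n, n - 1))
        res = cca(Y, X, n_perm=49, seed=0)
        assert res.constrained_inertia == pytest.approx(res.total_inertia, rel=1e-8)

    def test_toy_matrix_against_projection_oracle(self):
        Y = np.array([[4.0, 1.0, 0.0], [2.0, 3.0, 1.0], [0.0, 1.0, 5.0], [1.0, 1.0, 1.0]])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        res = cca(Y, x, n_perm=99, seed=0)
        # explicit weighted projection oracle (hat matrix via pinv)
        Q, r = _chi_square_matrix(Y)
        total = (Q**2).sum()
        xc = x - (r * x).sum() / r.sum()
        Xs = (np.sqrt(r) * xc)[:, None]
        H = Xs @ np.linalg.pinv(Xs.T @ Xs) @ Xs.T
        constrained = ((H @ Q) ** 2).sum()
        assert res.total_inertia == pytest.approx(total, rel=1e-12)
        assert res.constrained_fraction == pytest.approx(constrained / total, rel=1e-10)

    def test_inertia_conservation_with_conditions(self, rng):
        Y = rng.poisson(4, size=(12, 6)) + 1.0
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        res = cca(Y, x, conditions=z, n_perm=49, seed=0)
        # constrained + conditioned <= total, all nonnegative
        assert res.constrained_inertia >= -1e-12
        assert res.conditioned_inertia >= -1e-12
        assert res.constrained_inertia + res.conditioned_inertia <= res.total_inertia + 1e-8


class TestPermanova:
    def test_line_instance_hand_oracle(self):
        # points {0, 1, 10, 11}, Euclidean, balanced groups:
        # SS_total = 101, SS_model = 100, F = (100/1)/(1/2) = 200
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = permanova(D, np.array(["a", "a", "b", "b"]), n_perm=199, seed=0)
        assert res.r2 == pytest.approx(100 / 101, rel=1e-10)
        assert res.pseudo_f == pytest.approx(200.0, rel=1e-10)
        assert res.df_model == 1 and res.df_resid == 2

    def test_exact_enumeration_p_one_third(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        D = np.abs(pts[:, None] - pts[None, :])
        G = _gower_center(D)
        labels = np.array([0, 0, 1, 1])
        f_obs, *_ = _permanova_f(G, labels[:, None].astype(float))
        hits = 0
        for perm in itertools.permutations(range(4)):
            f_p, *_ = _permanova_f(G, labels[list(perm)][:, None].astype(float))
            hits += f_p >= f_obs - 1e-9
        assert hits / 24 == pytest.approx(1 / 3)

    def test_r2_invariant_under_consistent_permutation(self, rng):
        X = rng.poisson(4, size=(15, 6)) + 0.5
        cov = rng.normal(size=15)
        D = bray_curtis(X)
        res = permanova(D, cov, n_perm=49, seed=0)
        perm = rng.permutation(15)
        res2 = permanova(D[np.ix_(perm, perm)], cov[perm], n_perm=49, seed=0)
        assert res.r2 == pytest.approx(res2.r2, rel=1e-10)

    def test_constant_covariate_errors(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            permanova(D, np.full(4, 2.0))

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            permanova(np.zeros((2, 2)), np.array([1.0, 2.0]))
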