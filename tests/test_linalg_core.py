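"""Covariance construction, whitening and the coupled eigensolver."""

import numpy as np
import pytest
import scipy.linalg

from deepida.linalg_core import (
    build_system,
    class_statistics,
    covariances_from_representations,
    cross_covariance,
    inv_sqrt_psd,
    solve_gamma,
    system_objective,
)


class TestClassStatistics:
    def test_hand_computed_between_class_scatter(self):
        # two identical rows per class: class 1 at (0,0), class 2 at (2,2)
        H = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0], [2.0, 2.0]])
        labels = np.array([1, 1, 2, 2])
        covs = class_statistics(H, labels)
        np.testing.assert_allclose(covs.view_means[0], [1.0, 1.0])
        np.testing.assert_allclose(covs.between[0], np.full((2, 2), 4.0 / 3.0))
        np.testing.assert_allclose(covs.total[0], np.full((2, 2), 4.0 / 3.0))

    def test_constant_matrix_gives_zero_scatter(self):
        H = np.ones((6, 3)) * 2.5
        covs = class_statistics(H, np.repeat([0, 1], 3))
        np.testing.assert_allclose(covs.between[0], 0.0, atol=1e-14)
        np.testing.assert_allclose(covs.total[0], 0.0, atol=1e-14)

    def test_balanced_classes_mean_of_class_means_is_grand_mean(self, rng):
        H = rng.standard_normal((10, 3))
        labels = np.repeat([0, 1], 5)
        covs = class_statistics(H, labels)
        np.testing.assert_allclose(covs.view_means[0], H.mean(axis=0))

    def test_unbalanced_classes_mean_differs_from_grand_mean(self, rng):
        H = rng.standard_normal((9, 3)) + np.repeat([0, 3], [6, 3])[:, None]
        covs = class_statistics(H, np.repeat([0, 1], [6, 3]))
        assert not np.allclose(covs.view_means[0], H.mean(axis=0))

    @pytest.mark.parametrize("H,labels,msg", [
        (np.zeros((1, 2)), np.array([0]), "degenerate"),
        (np.zeros((4, 2)), np.zeros(4), "two classes"),
        (np.full((4, 2), np.nan), np.repeat([0, 1], 2), "missing"),
    ])
    def test_invalid_inputs(self, H, labels, msg):
        with pytest.raises(ValueError, match=msg):
            class_statistics(H, labels)


class TestCrossCovariance:
    def test_self_cross_equals_total(self, rng):
        H = rng.standard_normal((8, 3))
        labels = np.repeat([0, 1], 4)
        covs = class_statistics(H, labels)
        mu = covs.view_means[0]
        np.testing.assert_allclose(cross_covariance(H, H, mu, mu),
                                   covs.total[0])

    def test_sign_flip(self, rng):
        H = rng.standard_normal((8, 3))
        mu = H.mean(axis=0)
        np.testing.assert_allclose(cross_covariance(H, -H, mu, -mu),
                                   -cross_covariance(H, H, mu, mu))

    def test_matches_brute_force_double_loop(self, rng):
        Hd = rng.standard_normal((6, 2))
        Hj = rng.standard_normal((6, 3))
        mu_d, mu_j = Hd.mean(axis=0), Hj.mean(axis=0)
        expected = np.zeros((2, 3))
        for i in range(6):
            expected += np.outer(Hd[i] - mu_d, Hj[i] - mu_j)
        expected /= 5
        np.testing.assert_allclose(
            cross_covariance(Hd, Hj, mu_d, mu_j), expected)

    def test_transpose_symmetry_and_row_mismatch(self, rng):
        Hd = rng.standard_normal((6, 2))
        Hj = rng.standard_normal((6, 3))
        mu_d, mu_j = Hd.mean(axis=0), Hj.mean(axis=0)
        np.testing.assert_allclose(
            cross_covariance(Hd, Hj, mu_d, mu_j),
            cross_covariance(Hj, Hd, mu_j, mu_d).T)
        with pytest.raises(ValueError, match="row-aligned"):
            cross_covariance(Hd, Hj[:5], mu_d, mu_j)


class TestInvSqrt:
    def test_identity(self):
        np.testing.assert_allclose(inv_sqrt_psd(np.eye(3)), np.eye(3),
                                   atol=1e-12)

    def test_diagonal_closed_form(self):
        np.testing.assert_allclose(inv_sqrt_psd(np.diag([4.0, 9.0])),
                                   np.diag([0.5, 1.0 / 3.0]), atol=1e-12)

    def test_random_spd_reconstruction(self, rng):
        A = rng.standard_normal((5, 5))
        S = A @ A.T + 0.5 * np.eye(5)
        R = inv_sqrt_psd(S)
        np.testing.assert_allclose(R @ S @ R, np.eye(5), atol=1e-8)
        np.testing.assert_allclose(R, R.T, atol=1e-10)

    def test_rejects_bad_inputs(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            inv_sqrt_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="positive definite"):
            inv_sqrt_psd(np.diag([1.0, -2.0]))


class TestBuildSystem:
    @pytest.mark.parametrize("rho,D,c1,c2", [
        (0.5, 2, 0.25, 0.5),
        (1.0, 3, 1.0 / 3.0, 0.0),
        (0.0, 2, 0.0, 1.0),
    ])
    def test_mixing_weights(self, two_view_instance, rho, D, c1, c2):
        Hs, labels = two_view_instance
        if D == 3:
            Hs = Hs + [Hs[0] + 0.1]
        covs = covariances_from_representations(Hs, labels)
        system = build_system(covs, rho=rho, l=1)
        assert system.c1 == pytest.approx(c1)
        assert system.c2 == pytest.approx(c2)

    def test_invalid_l_and_rho(self, two_view_instance):
        Hs, labels = two_view_instance
        covs = covariances_from_representations(Hs, labels)
        with pytest.raises(ValueError, match="exceeds"):
            build_system(covs, rho=0.5, l=5)
        with pytest.raises(ValueError, match="rho"):
            build_system(covs, rho=1.5, l=1)

    def test_whitened_M_is_symmetric(self, two_view_instance):
        Hs, labels = two_view_instance
        covs = covariances_from_representations(Hs, labels)
        system = build_system(covs, rho=0.5, l=2)
        for M in system.M:
            np.testing.assert_allclose(M, M.T, atol=1e-10)


def _random_system(rng, dims=(3, 3), l=1, rho=0.5, n=20, K=2):
    labels = np.repeat(np.arange(K), n // K)
    Hs = [rng.standard_normal((n, o)) for o in dims]
    for d, H in enumerate(Hs):
        H[labels == 1, : min(2, H.shape[1])] += 0.8
    covs = covariances_from_representations(Hs, labels)
    return build_system(covs, rho=rho, l=l, ridge_scale=0.0), covs, Hs, labels


class TestSolveGamma:
    def test_rho_one_decouples_to_per_view_eigenproblems(self, rng):
        system, _, _, _ = _random_system(rng, rho=1.0, l=1)
        sol = solve_gamma(system, init_seed=0)
        for d, M in enumerate(system.M):
            w, V = scipy.linalg.eigh(M)
            top = V[:, np.argmax(w)]
            top = top * np.sign(top[np.argmax(np.abs(top))])
            np.testing.assert_allclose(sol.gammas[d][:, 0], top, atol=1e-8)
            assert sol.eigenvalues[d][0] == pytest.approx(
                system.c1 * w.max(), abs=1e-10)

    def test_matches_grid_search_on_2d_instance(self, rng):
        system, _, _, _ = _random_system(rng, dims=(2, 2), l=1)
        sol = solve_gamma(system, init_seed=3)
        thetas = np.linspace(0, np.pi, 1441)
        G = np.vstack([np.cos(thetas), np.sin(thetas)])  # 2 x T unit vectors
        sep1 = np.einsum("it,ij,jt->t", G, system.M[0], G)
        sep2 = np.einsum("it,ij,jt->t", G, system.M[1], G)
        C = G.T @ system.N[(0, 1)] @ G  # T x T inner products
        grid = (system.c1 * (sep1[:, None] + sep2[None, :])
                + 2.0 * system.c2 * C**2)
        assert sol.objective_value == pytest.approx(grid.max(), abs=5e-3)

    def test_objective_invariant_to_orthogonal_rotation(self, rng):
        system, _, _, _ = _random_system(rng, dims=(4, 3), l=2, K=4, n=24)
        sol = solve_gamma(system, init_seed=0)
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = [G @ Q for G in sol.gammas]
        assert system_objective(system, rotated) == pytest.approx(
            sol.objective_value, rel=1e-10)

    def test_orthonormality_and_monotone_objective(self, rng):
        system, _, _, _ = _random_system(rng, dims=(4, 3), l=2, K=4, n=24)
        sol = solve_gamma(system, init_seed=1)
        for G in sol.gammas:
            np.testing.assert_allclose(G.T @ G, np.eye(G.shape[1]),
                                       atol=1e-8)
        diffs = np.diff(sol.objective_trace)
        assert (diffs >= -1e-9).all()

    def test_eigenvalues_sorted_and_converged(self, rng):
        system, _, _, _ = _random_system(rng, dims=(4, 4), l=2, K=3, n=24)
        sol = solve_gamma(system, init_seed=0)
        assert sol.converged
        for vals in sol.eigenvalues:
            assert (np.diff(vals) <= 1e-12).all()

    def test_association_term_bounded_by_singular_values(self, rng):
        system, _, _, _ = _random_system(rng, dims=(3, 3), l=1)
        sol = solve_gamma(system, init_seed=0)
        for (d, j), N in system.N.items():
            smax = np.linalg.svd(N, compute_uv=False)[0]
            B = sol.gammas[d].T @ N @ sol.gammas[j]
            assert np.sum(B * B) <= system.l * smax**2 + 1e-10


class TestFormulationEquivalence:
    def test_whitened_objective_equals_original_parameterization(self, rng):
        """The trace objective over orthonormal Gamma equals the original
        objective evaluated at A_d = S_t^{-1/2} Gamma_d."""
        for trial in range(3):
            system, covs, _, _ = _random_system(
                rng, dims=(3, 4), l=2, K=3, n=21, rho=0.4)
            sol = solve_gamma(system, init_seed=trial)
            R = [inv_sqrt_psd(S) for S in covs.total]
            A = [R[d] @ sol.gammas[d] for d in range(2)]
            direct = 0.0
            D = 2
            for d in range(D):
                direct += system.c1 * np.trace(
                    A[d].T @ covs.between[d] @ A[d])
                for j in range(D):
                    if j == d:
                        continue
                    B = A[d].T @ covs.cross[(d, j)] @ A[j]
                    direct += system.c2 * np.sum(B * B)
            assert direct == pytest.approx(sol.objective_value, rel=1e-8)
            # the constraint tr[A^T S_t A] = l holds at A = S_t^{-1/2} Gamma
            for d in range(D):
                assert np.trace(A[d].T @ covs.total[d] @ A[d]) == \
                    pytest.approx(system.l, rel=1e-8)
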