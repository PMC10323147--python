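import numpy as np
import pytest

from dynblup import (
    GeneticParams,
    band_relatedness,
    build_gtilde,
    build_incidence,
    build_residual,
    fit_blup,
    identity_relatedness,
)
from dynblup.popmodel import RelMatrix

from conftest import no_plasticity_params, random_instance


def gls_oracle(y, u, gp, rel):
    """Independent conditional-expectation/GLS solution.

    Builds V = Z~ G~ Z~' + R~ explicitly (no Henderson system, no matrix
    reduction: a singular G is fine here) and returns the GLS fixed
    effects and x_hat = G~ Z~' V^-1 (y_vec - X ybar_hat).
    """
    n, p = y.shape
    q = gp.q
    k = gp.k
    # hand-built incidence: row j has 1 in intercept j, u in trait-j slopes
    Zt = np.zeros((p, k))
    for j in range(p):
        Zt[j, j] = 1.0
        Zt[j, p + j * q: p + (j + 1) * q] = u
    Ztil = np.kron(Zt, np.eye(n))
    X = np.kron(np.eye(p), np.ones((n, 1)))
    r = gp.sigma_v2 + (gp.sigma_eta2 * np.atleast_1d(u)[None, :] ** 2).sum(axis=1)
    Rtil = np.kron(np.diag(r), np.eye(n))
    Gtil = np.kron(gp.G, rel.A)
    V = Ztil @ Gtil @ Ztil.T + Rtil
    Vinv = np.linalg.inv(V)
    yvec = y.T.ravel()
    ybar = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ yvec)
    xhat = Gtil @ Ztil.T @ Vinv @ (yvec - X @ ybar)
    return ybar, xhat.reshape(k, n).T


class TestIncidence:
    def test_two_trait_two_cue_structure(self):
        u = np.array([0.7, -1.3])
        inc = build_incidence(u, p=2, q=2, n=3)
        expected = np.array(
            [[1, 0, 0.7, -1.3, 0, 0], [0, 1, 0, 0, 0.7, -1.3]]
        )
        np.testing.assert_array_equal(inc.Zt, expected)
        np.testing.assert_array_equal(inc.Ztilde, np.kron(expected, np.eye(3)))
        assert inc.X.shape == (6, 2)

    def test_zero_cues_degenerate_to_no_plasticity_design(self):
        inc = build_incidence(np.zeros(2), p=2, q=2, n=2)
        np.testing.assert_array_equal(inc.Zt[:, :2], np.eye(2))
        assert np.all(inc.Zt[:, 2:] == 0)

    def test_single_trait_single_cue(self):
        inc = build_incidence(np.array([2.5]), p=1, q=1, n=4)
        np.testing.assert_array_equal(inc.Zt, [[1.0, 2.5]])


class TestResidual:
    def test_zero_cues_give_nonadditive_intercept_variances(self, toy_gp):
        res = build_residual(np.zeros(2), toy_gp, 5)
        np.testing.assert_allclose(res.r, [0.2, 0.2])

    def test_toy_values_at_unit_cues(self, toy_gp):
        # only cue 1 feeds trait 1 (sigma_eta2[0,1] = 0): r1 = 0.2 + 0.05
        res = build_residual(np.array([1.0, 1.0]), toy_gp, 5)
        np.testing.assert_allclose(res.r, [0.25, 0.25])

    def test_monotone_in_cue_magnitude(self, toy_gp):
        r1 = build_residual(np.array([1.0, 1.0]), toy_gp, 2).r
        r2 = build_residual(np.array([2.0, 2.0]), toy_gp, 2).r
        assert np.all(r2 >= r1)

    def test_zero_variance_rejected(self, toy_gp):
        toy_gp.sigma_v2[:] = 0
        with pytest.raises(ValueError, match="unidentifiable"):
            build_residual(np.zeros(2), toy_gp, 5)


class TestGtilde:
    def test_kronecker_spectral_identity(self):
        G = np.array([[0.2, 0.1], [0.1, 0.2]])
        rel = band_relatedness(4)
        Gt = build_gtilde(G, rel)
        np.testing.assert_allclose(Gt, np.kron(G, rel.A))
        eig = np.sort(np.linalg.eigvalsh(Gt))
        outer = np.sort(np.outer(np.linalg.eigvalsh(G), np.linalg.eigvalsh(rel.A)).ravel())
        np.testing.assert_allclose(eig, outer, atol=1e-10)


class TestHendersonSolve:
    def test_constant_phenotypes_give_zero_random_effects(self, toy_gp):
        y = np.tile([1.5, -0.5], (8, 1))
        fit = fit_blup(y, np.array([0.3, 0.3]), toy_gp)
        np.testing.assert_allclose(fit.ybar_hat, [1.5, -0.5], atol=1e-10)
        np.testing.assert_allclose(fit.xhat, 0, atol=1e-10)

    def test_univariate_heritability_formula(self, rng):
        # p=1, q=0, A=I: a_hat_i = h^2 (y_i - mean), h^2 = G/(G+sigma_v2)
        gp = GeneticParams(
            p=1, q=0, Gaa=[[0.3]], Gab=np.zeros((1, 0)), Gbb=np.zeros((0, 0)),
            sigma_v2=[0.2], sigma_eta2=np.zeros((1, 0)),
        )
        y = rng.standard_normal((12, 1))
        fit = fit_blup(y, np.zeros(0), gp)
        h2 = 0.3 / 0.5
        np.testing.assert_allclose(fit.ybar_hat, y.mean(axis=0))
        np.testing.assert_allclose(fit.xhat[:, 0], h2 * (y[:, 0] - y.mean()), atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_gls_oracle_on_random_instances(self, seed):
        gp, u, y, _ = random_instance(seed)
        rel = identity_relatedness(y.shape[0])
        fit = fit_blup(y, u, gp, rel)
        ybar, xhat = gls_oracle(y, u, gp, rel)
        np.testing.assert_allclose(fit.ybar_hat, ybar, atol=1e-8)
        np.testing.assert_allclose(fit.xhat, xhat, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_gls_oracle_under_relatedness(self, seed):
        gp, u, y, _ = random_instance(seed + 100)
        rel = band_relatedness(y.shape[0])
        fit = fit_blup(y, u, gp, rel)
        ybar, xhat = gls_oracle(y, u, gp, rel)
        np.testing.assert_allclose(fit.ybar_hat, ybar, atol=1e-8)
        np.testing.assert_allclose(fit.xhat, xhat, atol=1e-8)

    def test_singular_toy_G_handled_via_reduction(self, toy_gp, rng):
        # the toy G has zero-variance slope columns; the solve must still
        # agree with the (reduction-free) GLS oracle, with zeros there
        y = rng.standard_normal((15, 2))
        u = np.array([1.0, -0.5])
        rel = band_relatedness(15)
        fit = fit_blup(y, u, toy_gp, rel)
        ybar, xhat = gls_oracle(y, u, toy_gp, rel)
        np.testing.assert_allclose(fit.ybar_hat, ybar, atol=1e-8)
        np.testing.assert_allclose(fit.xhat, xhat, atol=1e-8)
        assert np.all(fit.xhat[:, [3, 4]] == 0)  # inactive slopes b12, b21

    def test_fast_identity_path_equals_dense_path(self, toy_gp, rng):
        n = 20
        y = rng.standard_normal((n, 2))
        u = np.array([0.4, 1.1])
        dense_rel = RelMatrix(A=np.eye(n), A_M=np.eye(n), kind="custom")
        fast = fit_blup(y, u, toy_gp, identity_relatedness(n))
        dense = fit_blup(y, u, toy_gp, dense_rel)
        np.testing.assert_allclose(fast.ybar_hat, dense.ybar_hat, atol=1e-10)
        np.testing.assert_allclose(fast.xhat, dense.xhat, atol=1e-10)

    def test_translation_equivariance(self, toy_gp, rng):
        y = rng.standard_normal((10, 2))
        u = np.array([0.5, -0.5])
        base = fit_blup(y, u, toy_gp)
        shifted = fit_blup(y + np.array([3.0, 0.0]), u, toy_gp)
        np.testing.assert_allclose(shifted.ybar_hat, base.ybar_hat + [3.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(shifted.xhat, base.xhat, atol=1e-9)

    def test_random_effect_columns_have_zero_mean_when_unrelated(self, toy_gp, rng):
        y = rng.standard_normal((30, 2))
        fit = fit_blup(y, np.array([1.0, 1.0]), toy_gp)
        assert np.abs(fit.xhat.mean(axis=0)).max() < 1e-8

    def test_no_plasticity_shrinkage_of_estimates(self, rng):
        gp = no_plasticity_params(p=1)
        y = rng.standard_normal((2000, 1))
        fit = fit_blup(y, np.zeros(0), gp)
        # estimated effects are strictly shrunken relative to phenotypes
        assert fit.xhat[:, 0].var() < y.var()
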