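import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import random_correlation
from owc.ld import LDMatrix, regularized_inverse
from owc.stats import (
    MixtureSpec,
    RhoWeights,
    burden_LB,
    combination_matrix,
    lrho_statistic,
    mixture_eigenvalues,
    mixture_sf,
    score_SS,
    ssu_SQ,
    wss_LW,
    wss_weights,
)

#: exact tail of 1.5*chi2_1 + 0.5*chi2_1 at 5, from a smooth one-dimensional
#: integral over the first chi-square (independent of the inversion code)
MIX_3HALF_HALF_SF5 = 0.08963067855173448


class TestBurden:
    def test_hand_example_with_correlation(self, r_half):
        stat, p = burden_LB([1, 2], r_half)
        assert stat == 3.0
        assert p == pytest.approx(0.0832645, abs=1e-6)

    def test_zero_vector(self, r_half):
        assert burden_LB([0, 0], r_half) == (0.0, 1.0)

    def test_single_snp_reduces_to_two_sided_normal(self):
        R1 = LDMatrix(["a"], np.eye(1))
        _, p = burden_LB([1.7], R1)
        assert p == pytest.approx(2 * sps.norm.sf(1.7), rel=1e-12)

    def test_invalid_variance_errors(self):
        R = LDMatrix(["a", "b"], np.array([[1.0, -1.0], [-1.0, 1.0]]))
        with pytest.raises(ValueError, match="1'R1"):
            burden_LB([1, 2], R)


class TestWss:
    def test_equal_mafs_match_burden(self, r_half):
        _, p_b = burden_LB([1, 2], r_half)
        _, p_w = wss_LW([1, 2], [0.3, 0.3], r_half)
        assert p_w == pytest.approx(p_b, rel=1e-12)

    def test_maf_half_gets_minimum_weight_two(self):
        assert wss_weights([0.5])[0] == pytest.approx(2.0)

    def test_hand_arithmetic_identity_R(self):
        R = LDMatrix(["a", "b"], np.eye(2))
        stat, p = wss_LW([1, 2], [0.1, 0.4], R)
        assert stat == pytest.approx(7.41582, abs=1e-5)
        var = 1 / 0.09 + 1 / 0.24
        assert p == pytest.approx(float(sps.chi2.sf(stat**2 / var, 1)), rel=1e-12)

    def test_missing_maf_is_explicit(self, r_half):
        with pytest.raises(ValueError, match="unavailable"):
            wss_LW([1, 2], None, r_half)


class TestScore:
    def test_identity_R_equals_ssu_statistic(self):
        stat, _ = score_SS([1.0, 2.0], np.eye(2))
        assert stat == pytest.approx(5.0)

    def test_hand_example(self, r_half):
        stat, p = score_SS([1, 2], regularized_inverse(r_half))
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(np.exp(-2), rel=1e-10)

    def test_supremum_over_random_weights(self):
        # S_S is the max of (W'Z)^2/(W'RW): random search never exceeds it
        rng = np.random.default_rng(5)
        R = random_correlation(6, rng)
        z = rng.standard_normal(6)
        Rinv = regularized_inverse(R)
        s_max, _ = score_SS(z, Rinv)
        W = rng.standard_normal((10_000, 6))
        ratios = (W @ z) ** 2 / np.einsum("ni,ij,nj->n", W, R.values, W)
        assert np.all(ratios <= s_max + 1e-10)
        w_hat = Rinv @ z
        attained = (w_hat @ z) ** 2 / (w_hat @ R.values @ w_hat)
        assert attained == pytest.approx(s_max, rel=1e-10)


class TestSsu:
    def test_identity_R_ordinary_chi_square(self):
        R = LDMatrix(["a", "b", "c"], np.eye(3))
        z = [1.0, -1.0, 2.0]
        stat, p = ssu_SQ(z, R)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(float(sps.chi2.sf(6.0, 3)), abs=1e-7)

    def test_hand_example_matches_exact_mixture(self, r_half):
        stat, p = ssu_SQ([1, 2], r_half)
        assert stat == pytest.approx(5.0)
        lam = np.linalg.eigvalsh(r_half.values)
        assert sorted(lam) == pytest.approx([0.5, 1.5])
        assert p == pytest.approx(MIX_3HALF_HALF_SF5, abs=1e-6)

    def test_diagonal_weights_mask_snps(self, r_half):
        stat, p = ssu_SQ([1.0, 2.0], r_half, diag_weights=[1.0, 0.0])
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(2 * sps.norm.sf(1.0), abs=1e-7)

    def test_negative_weight_errors(self, r_half):
        with pytest.raises(ValueError, match="non-negative"):
            ssu_SQ([1, 2], r_half, diag_weights=[-1, 1])


class TestCombination:
    def test_vertices(self, r_half):
        Rinv = regularized_inverse(r_half)
        A = combination_matrix(RhoWeights(0, 0, 0, 1), None, None, 2)
        assert np.allclose(A.values, np.eye(2))
        A = combination_matrix(RhoWeights(1, 0, 0, 0), None, None, 2)
        assert np.allclose(A.values, np.ones((2, 2)))
        A = combination_matrix(RhoWeights(0, 0, 1, 0), None, Rinv, 2)
        assert np.allclose(A.values, Rinv)

    def test_burden_vertex_squares_the_sum(self):
        A = combination_matrix(RhoWeights(1, 0, 0, 0), None, None, 3)
        z = np.array([1.0, -2.0, 0.5])
        assert lrho_statistic(z, A) == pytest.approx(z.sum() ** 2)

    def test_rho2_without_weights_is_config_error(self):
        with pytest.raises(ValueError, match="W"):
            combination_matrix(RhoWeights(0, 1, 0, 0), None, None, 2)

    def test_rho_weights_validated(self):
        with pytest.raises(ValueError):
            RhoWeights(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            RhoWeights(0.3, 0.3, 0.3, 0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_quadratic_form_equals_component_sum(self, seed):
        # Z'AZ == rho1*LB^2 + rho2*LW^2 + rho3*S_S + rho4*S_Q (algebraic identity)
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 9))
        R = random_correlation(M, rng)
        z = rng.standard_normal(M)
        maf = rng.uniform(0.05, 0.5, M)
        rho = rng.dirichlet(np.ones(4))
        Rinv = regularized_inverse(R)
        w = wss_weights(maf)
        A = combination_matrix(RhoWeights(*rho), w, Rinv, M)
        expected = (
            rho[0] * burden_LB(z, R)[0] ** 2
            + rho[1] * wss_LW(z, maf, R)[0] ** 2
            + rho[2] * score_SS(z, Rinv)[0]
            + rho[3] * ssu_SQ(z, R)[0]
        )
        assert lrho_statistic(z, A) == pytest.approx(expected, abs=1e-8)


class TestMixtureEigenvalues:
    def test_identity_A_recovers_R_spectrum(self, ar1_ld):
        A = combination_matrix(RhoWeights(0, 0, 0, 1), None, None, ar1_ld.M)
        lam = mixture_eigenvalues(ar1_ld, A).eigenvalues
        assert np.allclose(np.sort(lam), np.sort(np.linalg.eigvalsh(ar1_ld.values)))

    def test_inverse_A_gives_unit_spectrum(self, ar1_ld):
        Rinv = regularized_inverse(ar1_ld)
        A = combination_matrix(RhoWeights(0, 0, 1, 0), None, Rinv, ar1_ld.M)
        lam = mixture_eigenvalues(ar1_ld, A).eigenvalues
        assert np.allclose(lam, 1.0, atol=1e-8)

    def test_trace_identity(self):
        rng = np.random.default_rng(11)
        R = random_correlation(5, rng)
        Rinv = regularized_inverse(R)
        maf = rng.uniform(0.05, 0.5, 5)
        A = combination_matrix(RhoWeights(0.3, 0.0, 0.3, 0.4), wss_weights(maf), Rinv, 5)
        lam = mixture_eigenvalues(R, A).eigenvalues
        assert lam.sum() == pytest.approx(np.trace(R.values @ A.values), abs=1e-8)

    def test_descending_order(self, ar1_ld):
        A = combination_matrix(RhoWeights(0.5, 0, 0, 0.5), None, None, ar1_ld.M)
        lam = mixture_eigenvalues(ar1_ld, A).eigenvalues
        assert np.all(np.diff(lam) <= 0)


class TestMixtureSf:
    @pytest.mark.parametrize("method", ["liu", "davies"])
    def test_chi2_closed_forms(self, method):
        assert mixture_sf(4.0, np.array([1.0, 1.0]), method) == pytest.approx(
            np.exp(-2), abs=1e-7
        )
        for y in (0.5, 2.0, 6.0):
            assert mixture_sf(2 * y, np.array([2.0]), method) == pytest.approx(
                float(sps.chi2.sf(y, 1)), abs=1e-7
            )

    def test_davies_matches_independent_exact_value(self):
        assert mixture_sf(5.0, np.array([1.5, 0.5]), "davies") == pytest.approx(
            MIX_3HALF_HALF_SF5, abs=1e-7
        )

    def test_degenerate_all_zero(self):
        assert mixture_sf(-1.0, np.zeros(3)) == 1.0
        assert mixture_sf(0.5, np.zeros(3)) == 0.0

    def test_at_zero_is_one(self):
        assert mixture_sf(0.0, np.array([1.0, 0.5])) == 1.0

    @given(st.lists(st.floats(min_value=0.01, max_value=5), min_size=1, max_size=6),
           st.floats(min_value=0, max_value=30), st.floats(min_value=0, max_value=5))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_nonincreasing(self, lam, x, dx):
        lam = np.array(lam)
        assert mixture_sf(x + dx, lam) <= mixture_sf(x, lam) + 1e-12

    def test_large_imaginary_part_guard(self):
        with pytest.raises(ValueError):
            MixtureSpec(np.array([1.0, -0.5]))


def test_null_pvalues_uniform(ar1_ld):
    """Burden/score p-values (exact chi-square) and ssu p-values (accurate
    mixture tail) are uniform under Z ~ MVN(0, R)."""
    from owc.simulate import sample_z

    n = 100_000
    Z = sample_z(ar1_ld, None, n, seed=21)
    var = ar1_ld.values.sum()
    p_burden = sps.chi2.sf(Z.sum(axis=1) ** 2 / var, 1)
    Rinv = regularized_inverse(ar1_ld)
    p_score = sps.chi2.sf(np.einsum("ni,ij,nj->n", Z, Rinv, Z), ar1_ld.M)
    crit = 1.9495 / np.sqrt(n)  # 0.001-level Kolmogorov critical value
    for p in (p_burden, p_score):
        assert sps.kstest(p, "uniform").statistic < crit
    # ssu: evaluate the accurate tail on a dense quantile grid of the observed
    # statistics and interpolate (the grid spacing adds < 1e-3 to the KS bound)
    q = np.einsum("ni,ni->n", Z, Z)
    lam = np.maximum(np.linalg.eigvalsh(ar1_ld.values), 0)
    grid = np.quantile(q, np.linspace(0, 1, 801))
    sf_grid = np.array([mixture_sf(x, lam, method="davies") for x in grid])
    p_ssu = np.interp(q, grid, sf_grid)
    assert sps.kstest(p_ssu, "uniform").statistic < crit + 1e-3
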