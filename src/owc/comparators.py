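"""Comparison gene-based tests operating on the same (Z, R) inputs as OWC.

* ST — sum test, the burden statistic ``B = sum(Z) ~ N(0, 1'R1)``;
* S2T — squared sum test ``Q = sum(Z^2)``, a chi-square mixture;
* AT — adaptive test, min-p over ``Q_rho = (1-rho)Q + rho B^2`` on a short
  one-dimensional rho grid, assessed by Monte Carlo;
* aSPU — adaptive sum of powered scores ``SPU(gamma) = sum(Z^gamma)`` over
  gamma = 1..8 and infinity (max |Z|), min-p by Monte Carlo;
* GATES — extended Simes correction using the effective number of
  independent p-values estimated from the LD matrix.
"""
from __future__ import annotations

import math

import numpy as np

from .ld import LDMatrix
from .stats import MixtureSpec, burden_LB, liu_params, liu_sf, ssu_SQ, _matrix, _sqrt_psd

#: the one-dimensional rho grid of the adaptive test
AT_GRID: tuple[float, ...] = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

#: powers of the SPU family; infinity denotes max |Z|
SPU_GAMMAS: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, math.inf)


def sum_test_ST(z: np.ndarray, R) -> float:
    """Burden-style sum test p-value (alias of the L_B component)."""
    return burden_LB(z, R)[1]


def squared_sum_S2T(z: np.ndarray, R) -> float:
    """Sum-of-squares test p-value (alias of the unweighted S_Q component)."""
    return ssu_SQ(z, R)[1]


class AtPrecomputation:
    """Per-gene mixture parameters for each rho of the adaptive test."""

    def __init__(self, R: LDMatrix, grid: tuple[float, ...] = AT_GRID) -> None:
        Rv = _matrix(R)
        self.M = Rv.shape[0]
        self.grid = tuple(grid)
        S = _sqrt_psd(Rv)
        u = S @ np.ones(self.M)
        uu = np.outer(u, u)
        self.liu = []
        for rho in self.grid:
            lam = np.linalg.eigvalsh((1.0 - rho) * Rv + rho * uu)
            self.liu.append(liu_params(MixtureSpec(lam).eigenvalues))
        # rows of [B^2, Q] weights per rho
        self.coef = np.array([[rho, 1.0 - rho] for rho in self.grid])
        self.chol = np.linalg.cholesky(Rv + 1e-10 * np.eye(self.M))

    def t_values(self, Zmat: np.ndarray) -> np.ndarray:
        """min over rho of the mixture p-value of Q_rho, per row of Zmat."""
        Zmat = np.atleast_2d(np.asarray(Zmat, dtype=float))
        b2 = Zmat.sum(axis=1) ** 2
        q = np.einsum("ni,ni->n", Zmat, Zmat)
        base = np.column_stack([b2, q])
        T = np.ones(base.shape[0])
        for g in range(len(self.grid)):
            np.minimum(T, liu_sf(base @ self.coef[g], self.liu[g]), out=T)
        return T

    def sample_null(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.M)) @ self.chol.T


def adaptive_AT(
    z: np.ndarray,
    R: LDMatrix,
    grid: tuple[float, ...] = AT_GRID,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    precomp: AtPrecomputation | None = None,
) -> float:
    """Adaptive test p-value: Monte Carlo assessment of min-p over the rho grid."""
    pre = precomp if precomp is not None else AtPrecomputation(R, grid)
    T_obs = float(pre.t_values(np.atleast_2d(z))[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_T = pre.t_values(pre.sample_null(B, rng))
    return (int(np.sum(null_T <= T_obs)) + 1) / (B + 1)


# ---------------------------------------------------------------------------
# aSPU


def spu_statistics(Zmat: np.ndarray, gammas: tuple[float, ...] = SPU_GAMMAS) -> np.ndarray:
    """``n x G`` matrix of SPU statistics, mapped so that larger = more extreme.

    Odd finite powers are two-sided, so their statistic is ``|sum Z^gamma|``;
    even powers are one-sided upper; infinity is ``max |Z|``.
    """
    Zmat = np.atleast_2d(np.asarray(Zmat, dtype=float))
    cols = []
    for g in gammas:
        if math.isinf(g):
            cols.append(np.abs(Zmat).max(axis=1))
        elif int(g) % 2 == 0:
            cols.append((Zmat ** int(g)).sum(axis=1))
        else:
            cols.append(np.abs((Zmat ** int(g)).sum(axis=1)))
    return np.column_stack(cols)


def _aspu_from_stats(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """aSPU p-values for rows of ``obs`` given shared null SPU statistics.

    Per-power p-values of the null draws use within-sample ranks (counting
    self, floor 1/B); observed draws are counted against the null sample
    with the +1 correction.  The overall p-value compares min-p statistics
    the same way.
    """
    B = null.shape[0]
    null_sorted = np.sort(null, axis=0)
    # null per-gamma p: count of null >= value, self included
    p_null = np.empty_like(null)
    for g in range(null.shape[1]):
        geq = B - np.searchsorted(null_sorted[:, g], null[:, g], side="left")
        p_null[:, g] = geq / B
    t_null = p_null.min(axis=1)

    p_obs = np.empty_like(obs)
    for g in range(obs.shape[1]):
        geq = B - np.searchsorted(null_sorted[:, g], obs[:, g], side="left")
        p_obs[:, g] = (geq + 1) / (B + 1)
    t_obs = p_obs.min(axis=1)

    t_null_sorted = np.sort(t_null)
    count = np.searchsorted(t_null_sorted, t_obs, side="right")
    return (count + 1) / (B + 1)


def aspu(
    z: np.ndarray,
    R: LDMatrix,
    gammas: tuple[float, ...] = SPU_GAMMAS,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Adaptive SPU p-value by Monte Carlo over the power set gamma=1..8, inf."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Rv = _matrix(R)
    D = np.linalg.cholesky(Rv + 1e-10 * np.eye(Rv.shape[0]))
    null = spu_statistics(rng.standard_normal((B, Rv.shape[0])) @ D.T, gammas)
    obs = spu_statistics(np.atleast_2d(z), gammas)
    return float(_aspu_from_stats(obs, null)[0])


# ---------------------------------------------------------------------------
# GATES


def pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Correlation between two-sided p-values of SNPs with genotype correlation r.

    Sixth-order polynomial fit of the GATES procedure (Li et al.); applied
    to |r| since p-value correlation is direction-free.
    """
    a = np.abs(np.asarray(r, dtype=float))
    out = (((((0.2982 * a - 0.0127) * a + 0.0588) * a + 0.0099) * a + 0.6281) * a - 0.0009) * a
    if out.ndim == 2:
        np.fill_diagonal(out, 1.0)
    return out


class GatesCache:
    """Effective-number-of-tests values for SNP subsets of one gene.

    ``m_e`` of a subset S is ``|S| - sum_{lambda_i > 1}(lambda_i - 1)`` over
    the eigenvalues of the p-value-correlation block, with genotype
    correlation mapped to p-value correlation by
    :func:`pvalue_correlation`.  Swap in another estimator by subclassing
    ``me_of_subset`` or passing a different ``transform``.
    """

    def __init__(self, R: LDMatrix, transform=pvalue_correlation) -> None:
        self.pcorr = transform(_matrix(R))
        self.M = self.pcorr.shape[0]
        self._cache: dict[int, float] = {}

    def me_of_subset(self, idx: tuple[int, ...]) -> float:
        key = 0
        for i in idx:
            key |= 1 << i
        if key not in self._cache:
            sub = self.pcorr[np.ix_(idx, idx)]
            lam = np.linalg.eigvalsh(sub)
            self._cache[key] = float(len(idx) - np.sum(lam[lam > 1] - 1.0))
        return self._cache[key]


def gates(pvals: np.ndarray, R: LDMatrix, cache: GatesCache | None = None) -> float:
    """GATES extended-Simes p-value ``min_j m_e p_(j) / m_e(j)``, in (0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = cache if cache is not None else GatesCache(R)
    if p.size != c.M:
        raise ValueError("p-values not aligned to the LD matrix")
    order = np.argsort(p, kind="stable")
    me_all = c.me_of_subset(tuple(range(c.M)))
    best = np.inf
    for j in range(1, c.M + 1):
        me_j = c.me_of_subset(tuple(sorted(order[:j])))
        best = min(best, me_all * p[order[j - 1]] / me_j)
    return float(min(max(best, np.finfo(float).tiny), 1.0))
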