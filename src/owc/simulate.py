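"""Simulation study harness: synthetic LD, null/alternative Z draws, and
type-I-error / power estimation for any registered gene-based test.

The null design draws summary Z-scores from ``MVN(0, R)``; the alternative
design shifts the mean to ``A x Delta`` where ``A`` holds the signs (+1
risk, -1 protective) of the causal SNPs and ``Delta`` their effect sizes —
either a fixed vector or drawn fresh per replicate from a uniform or
normal law.  Monte-Carlo-p tests (OWC, AT, aSPU) share one null reference
sample per study cell, which is statistically identical to re-simulating
the null for every replicate but fits interactive time scales.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import comparators as cmp
from .ld import LDMatrix, cholesky_factor, psd_repair
from .omnibus import (
    CHUNK,
    GenePrecomputation,
    RhoGrid,
    pvalue_from_reference,
)
from .stats import liu_params, liu_sf, MixtureSpec

logger = logging.getLogger(__name__)

METHODS = ("owc", "st", "s2t", "at", "aspu", "gates")


# ---------------------------------------------------------------------------
# synthetic inputs


def synthetic_ld(kind: str, M: int, param: float = 0.5) -> LDMatrix:
    """Synthetic LD matrix: ``ar1`` (param^|i-j|), ``exchangeable`` (constant
    off-diagonal) or ``block`` (two AR(1) blocks, zero cross-correlation)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if kind in ("ar1", "block") and not (-1.0 < param < 1.0):
        raise ValueError(f"AR(1) parameter must lie in (-1, 1): {param}")
    if kind == "exchangeable" and not (-1.0 / max(M - 1, 1) < param < 1.0):
        raise ValueError(f"exchangeable parameter {param} is not a valid correlation")
    ids = [f"snp{i + 1}" for i in range(M)]
    if kind == "ar1":
        idx = np.arange(M)
        values = param ** np.abs(idx[:, None] - idx[None, :])
    elif kind == "exchangeable":
        values = np.full((M, M), float(param))
        np.fill_diagonal(values, 1.0)
    elif kind == "block":
        h = M // 2
        values = np.eye(M)
        for lo, hi in ((0, h), (h, M)):
            idx = np.arange(hi - lo)
            values[lo:hi, lo:hi] = param ** np.abs(idx[:, None] - idx[None, :])
    else:
        raise ValueError(f"unknown LD kind {kind!r}")
    return LDMatrix(ids, values)


def synthetic_maf(M: int, seed: int | np.random.Generator = 0,
                  low: float = 0.067, high: float = 0.453) -> np.ndarray:
    """Common-variant MAFs drawn uniformly on [low, high] (post-QC range)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(low, high, size=M)


@dataclass
class EffectConfig:
    """Causal-SNP effects for the alternative design ``MVN(A x Delta, R)``.

    ``delta`` is either a fixed vector (one entry per causal SNP) or a
    distribution spec ``("uniform", a, b)`` / ``("normal", mu, sd)`` drawn
    fresh for every replicate.  ``signs`` are +/-1 effect directions.
    """

    causal_idx: np.ndarray
    signs: np.ndarray
    delta: np.ndarray | tuple

    def __post_init__(self) -> None:
        self.causal_idx = np.asarray(self.causal_idx, dtype=int)
        self.signs = np.asarray(self.signs, dtype=float)
        if self.causal_idx.size != self.signs.size:
            raise ValueError("causal_idx and signs must have equal length")
        if not np.all(np.isin(self.signs, (-1.0, 1.0))):
            raise ValueError("signs must be +/-1")
        if not isinstance(self.delta, tuple):
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.size != self.causal_idx.size:
                raise ValueError("fixed delta must have one entry per causal SNP")

    def sample_means(self, M: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n x M`` mean matrix; non-causal columns are zero."""
        mean = np.zeros((n, M))
        k = self.causal_idx.size
        if isinstance(self.delta, tuple):
            dist, a, b = self.delta
            if dist == "uniform":
                d = rng.uniform(a, b, size=(n, k))
            elif dist == "normal":
                d = rng.normal(a, b, size=(n, k))  # b is a standard deviation
            else:
                raise ValueError(f"unknown delta distribution {dist!r}")
        else:
            d = np.broadcast_to(self.delta, (n, k))
        mean[:, self.causal_idx] = self.signs * d
        return mean


def random_causal_config(
    M: int,
    n_causal: int,
    delta,
    n_protective: int = 0,
    seed: int | np.random.Generator = 0,
) -> EffectConfig:
    """Randomly place causal SNPs and assign signs (protective ones get -1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(M, size=n_causal, replace=False))
    signs = np.ones(n_causal)
    if n_protective:
        signs[rng.choice(n_causal, size=n_protective, replace=False)] = -1.0
    return EffectConfig(idx, signs, delta)


def sample_z(
    R: LDMatrix,
    config: EffectConfig | None,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """``n`` i.i.d. draws of ``Z ~ MVN(mean, R)`` via the Cholesky factor."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = cholesky_factor(psd_repair(R)).lower_triangular
    Z = rng.standard_normal((n, R.M)) @ D.T
    if config is not None:
        Z += config.sample_means(R.M, n, rng)
    return Z


# ---------------------------------------------------------------------------
# test registry: batched p-value evaluators sharing a null reference


@dataclass
class BatchTest:
    """A gene-based test evaluated over batches of Z vectors.

    ``resolution`` is the smallest attainable p-value (0 for analytic
    tests); study functions refuse significance levels below it.
    """

    name: str
    resolution: float
    pvalues: callable


def make_test(
    name: str,
    R: LDMatrix,
    maf: np.ndarray | None = None,
    null_B: int = 10_000,
    seed: int | np.random.Generator = 0,
    grid: RhoGrid | None = None,
) -> BatchTest:
    """Instantiate a registered test for one gene (building any null reference)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Rv = R.values
    name = name.lower()
    if name == "st":
        var = float(np.sum(Rv))

        def p_st(Zmat):
            s = np.atleast_2d(Zmat).sum(axis=1)
            return sps.chi2.sf(s * s / var, 1)

        return BatchTest("st", 0.0, p_st)
    if name == "s2t":
        params = liu_params(MixtureSpec(np.linalg.eigvalsh(Rv)).eigenvalues)

        def p_s2t(Zmat):
            Zmat = np.atleast_2d(Zmat)
            return liu_sf(np.einsum("ni,ni->n", Zmat, Zmat), params)

        return BatchTest("s2t", 0.0, p_s2t)
    if name == "gates":
        cache = cmp.GatesCache(R)

        def p_gates(Zmat):
            Zmat = np.atleast_2d(Zmat)
            pv = 2.0 * sps.norm.sf(np.abs(Zmat))
            return np.array([cmp.gates(row, R, cache=cache) for row in pv])

        return BatchTest("gates", 0.0, p_gates)
    if name == "at":
        pre = cmp.AtPrecomputation(R)
        ref = np.sort(pre.t_values(pre.sample_null(null_B, rng)))

        def p_at(Zmat):
            return pvalue_from_reference(pre.t_values(Zmat), ref)

        return BatchTest("at", 1.0 / (null_B + 1), p_at)
    if name == "aspu":
        D = cholesky_factor(psd_repair(R)).lower_triangular
        null = cmp.spu_statistics(rng.standard_normal((null_B, R.M)) @ D.T)

        def p_aspu(Zmat):
            return cmp._aspu_from_stats(cmp.spu_statistics(Zmat), null)

        return BatchTest("aspu", 1.0 / (null_B + 1), p_aspu)
    if name == "owc":
        pre = GenePrecomputation(R, maf, grid)
        ref = np.sort(pre.null_t(null_B, rng))

        def p_owc(Zmat):
            return pvalue_from_reference(pre.t_values(Zmat), ref)

        return BatchTest("owc", 1.0 / (null_B + 1), p_owc)
    raise ValueError(f"unknown test {name!r}; choose from {METHODS}")


# ---------------------------------------------------------------------------
# study designs


@dataclass
class SimDesign:
    """One simulation experiment: LD source, replication count, level, seed."""

    R: LDMatrix
    n_reps: int
    alpha: float
    seed: int
    null_B: int = 10_000
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def _resolve_test(test, design: SimDesign, rng: np.random.Generator) -> BatchTest:
    if isinstance(test, str):
        test = make_test(test, design.R, design.maf, design.null_B, rng)
    if test.resolution > 0 and design.alpha < test.resolution:
        raise ValueError(
            f"alpha {design.alpha:g} below the Monte Carlo resolution "
            f"{test.resolution:g}; increase null_B"
        )
    return test


def _rejection_rate(test: BatchTest, design: SimDesign,
                    config: EffectConfig | None) -> tuple[float, int]:
    ss = np.random.SeedSequence(design.seed)
    rng_null, rng_reps = (np.random.default_rng(s) for s in ss.spawn(2))
    test = _resolve_test(test, design, rng_null)
    D = cholesky_factor(psd_repair(design.R)).lower_triangular
    hits = 0
    done = 0
    while done < design.n_reps:
        take = min(CHUNK, design.n_reps - done)
        Z = rng_reps.standard_normal((take, design.R.M)) @ D.T
        if config is not None:
            Z += config.sample_means(design.R.M, take, rng_reps)
        hits += int(np.sum(test.pvalues(Z) <= design.alpha))
        done += take
    return hits / design.n_reps, design.n_reps


def type1_ratio(test, design: SimDesign) -> tuple[float, float]:
    """(type-I rate)/alpha over null replicates, with its Monte Carlo s.e."""
    rate, n = _rejection_rate(test, design, None)
    se = float(np.sqrt(max(rate * (1 - rate), design.alpha) / n)) / design.alpha
    return rate / design.alpha, se


def power_estimate(test, design: SimDesign, config: EffectConfig) -> tuple[float, float]:
    """Power (%) at the design's significance level, with binomial s.e. (%)."""
    rate, n = _rejection_rate(test, design, config)
    se = float(np.sqrt(rate * (1 - rate) / n))
    return 100.0 * rate, 100.0 * se


def run_type1_study(methods, design: SimDesign) -> pd.DataFrame:
    """Type-I ratio table (one row per method) at the design's level."""
    rows = []
    for m in methods:
        ratio, se = type1_ratio(m, design)
        rows.append({"method": m, "alpha": design.alpha, "ratio": ratio, "mc_se": se})
    return pd.DataFrame(rows)


def run_power_study(methods, design: SimDesign, config: EffectConfig) -> pd.DataFrame:
    """Power table (one row per method) for one effect configuration."""
    rows = []
    for m in methods:
        power, se = power_estimate(m, design, config)
        rows.append({"method": m, "alpha": design.alpha, "power_pct": power, "se_pct": se})
    return pd.DataFrame(rows)
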