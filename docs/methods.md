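# Methods

## Problem setting

Gene-based association tests aggregate the evidence of the `M` SNPs in a
gene (plus a flanking window) into one test, trading the resolution of
single-variant analysis for power and interpretability. This package
works entirely from GWAS *summary statistics*: per-SNP Z-scores (or
p-values with signed effect estimates) and a SNP-by-SNP linkage
disequilibrium (LD) correlation matrix `R` estimated from a reference
panel. Under the null hypothesis of no association, the vector of
Z-scores is asymptotically multivariate normal, `Z ~ MVN(0, R)`.

## Component statistics

Four classical statistics are linear or quadratic forms in `Z`:

| statistic | definition | null law | strength |
|---|---|---|---|
| burden `L_B` | `1'Z` | `N(0, 1'R1)` | concordant effect directions |
| weighted sum `L_W` | `w'Z`, `w_j = 1/sqrt(p_j(1-p_j))` | `N(0, w'Rw)` | rarer variants up-weighted |
| score `S_S` | `Z'R^{-1}Z` | `chi^2_M` | sparse/mixed signals |
| sum of squares `S_Q` | `Z'Z` | `sum_i lambda_i chi^2_1`, `lambda = eig(R)` | dense mixed signals |

`S_S` is the supremum of `(W'Z)^2 / (W'RW)` over weight vectors `W`,
attained at `W = R^{-1}Z`; this maximization property is verified in the
test suite.

## The omnibus combination test

No single weighting is best across genetic architectures. The omnibus
statistic takes a convex combination

```
L_rho = rho1 L_B^2 + rho2 L_W^2 + rho3 S_S + rho4 S_Q  =  Z' A Z,
A = rho1 11' + rho2 ww' + rho3 R^{-1} + rho4 I,
```

whose null law is the chi-square mixture `sum_i lambda_i chi^2_1` with
`lambda = eig(RA)` (computed stably as the spectrum of the symmetric
matrix `R^{1/2} A R^{1/2}`). The weights `rho` range over the 0.1-step
lattice of the 4-simplex (286 points). Each grid point yields an
asymptotic p-value `p(L_rho)`; the omnibus statistic is

```
T = min_rho p(L_rho),
```

whose own null distribution is assessed by Monte Carlo: null vectors
`Z_b = D L_b` with `D` the (lower) Cholesky factor of `R` and
`L_b ~ N(0, I)`, and

```
p_T = [ #{ b : T_b <= T_obs } + 1 ] / (B + 1).
```

Because observed and null statistics pass through exactly the same map,
this p-value is calibrated by construction regardless of small
inaccuracies in the per-point asymptotic tails.

A staged ("fast") estimator starts at `B0 = 10` draws and multiplies the
cumulative draw count by 10 until either the uncorrected tail frequency
`count/B` exceeds `p0 = 1e-5` or the cap `Bmax = 1e6` is reached, so
clearly non-significant genes cost ~10 draws while significant genes get
full resolution. Draws accumulate across stages from one RNG stream, so
a schedule pinned to a single stage reproduces the direct estimator
exactly. The stopping rule deliberately uses the uncorrected frequency:
the `+1`-corrected estimate has floor `1/(B0+1)`, which would otherwise
terminate every gene at the first stage.

## Chi-square-mixture tails

Two evaluators for `P(sum_i lambda_i chi^2_1 > x)` are provided:

* **Moment matching** (`method="liu"`): matches skewness/kurtosis to a
  (non)central chi-square. It is vectorized and cheap — the engine of
  every Monte Carlo loop — and exact when all `lambda` are equal, but its
  absolute error (~5e-3 in the central region for typical LD spectra) is
  too coarse for reported single-test p-values.
* **Characteristic-function inversion** (`method="davies"`): Imhof-type
  integral on a uniform midpoint grid, absolute accuracy ~1e-8 (validated
  against closed forms and an independent one-dimensional integral
  oracle). Used for stand-alone p-values (`ssu_SQ`, the squared-sum
  comparator) and for oracle comparisons.

Inside the omnibus Monte Carlo loop the choice cancels (same map on both
sides), so the fast evaluator is used there.

## Comparison tests

* **ST** — the burden test above.
* **S2T** — the sum-of-squares test with accurate mixture tail.
* **AT** — min-p over `Q_rho = (1-rho) S_Q + rho L_B^2` on the
  one-dimensional grid `rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}`,
  assessed by Monte Carlo like the omnibus test.
* **aSPU** — sum of powered scores `SPU(gamma) = sum_j Z_j^gamma` for
  `gamma = 1..8` and `gamma = inf` (`max |Z|`); odd powers are two-sided
  via absolute values; the minimum per-power Monte Carlo p-value is
  recalibrated against the same null draws.
* **GATES** — extended Simes: `min_j m_e p_(j) / m_e(j)` where `m_e` is
  the effective number of independent p-values, computed from eigenvalues
  of the *p-value* correlation matrix. Genotype correlation is mapped to
  p-value correlation with the published sixth-order polynomial in `|r|`;
  using the raw absolute genotype correlation instead inflates type-I
  error by ~40% on AR(1) LD (measured), so the polynomial mapping is the
  default (the transform is a pluggable argument).

## Input processing and QC

* Z-scores are taken directly from a `Z` column, or reconstructed as
  `Z = sign(beta) * Phi^{-1}(1 - p/2)` from p-value plus signed beta
  (odds ratios are log-transformed first). P-values below 1e-300 are
  floored with a warning.
* SNPs map to a gene when their position falls within the gene body
  extended by a ±20 kb window (inclusive, 1-based; BED input is
  converted). A SNP may belong to several overlapping genes.
* QC per gene: drop SNPs with MAF < 0.05, then greedily prune one SNP of
  every pair with `r^2 > 0.5`, scanning in position order (keeping the
  earlier SNP; a `keep="zmax"` policy retaining the more significant SNP
  is available). The filtered LD block is PSD-repaired (eigenvalue
  flooring at 1e-8 with diagonal rescaling) before Cholesky
  factorization, and `R^{-1}` uses a condition-number-guarded ridge.

## Simulation harness

Type-I error and power studies draw `Z ~ MVN(A x Delta, R)` directly:
`A x Delta` is zero under the null; under alternatives, the causal SNPs
carry effects `Delta` with signs ±1. Effect sizes are a fixed vector or
redrawn per replicate from `U(a, b)` or `N(mu, sd)` (the second normal
parameter is a standard deviation). Defaults chosen for desk-scale runs:
synthetic LD matrices (`ar1` with parameter 0.5, `exchangeable`,
two-block), `M = 11` SNPs, MAFs uniform on [0.067, 0.453] (a plausible
post-QC common-variant range). Monte-Carlo-based tests (omnibus, AT,
aSPU) share one null reference sample per study cell; p-values computed
against it by rank are identical to the direct estimator on the same
draws.

## Numerical choices

* Per-gene spectral work (one `M x M` eigendecomposition per grid point,
  286 total) is done once and reused for every draw; batch evaluation of
  `T` then costs four quadratic forms per draw plus one vectorized tail
  evaluation per grid point.
* Null draws are generated and scored in chunks of 200,000 to bound
  memory.
* Child seeds derive from `numpy.random.SeedSequence` spawning, so every
  result is reproducible from a single integer seed.

## Limitations

* There is no analytic p-value for the omnibus statistic; resolution is
  bounded by `1/(Bmax + 1)`.
* The multivariate-normal model for `Z` assumes the LD reference panel
  matches the GWAS population; mismatch biases all LD-aware tests.
* Power results depend on the LD matrix; the bundled synthetic designs
  are calibrated for desk-scale verification, not for reproducing any
  particular gene's architecture.
* MAF-weighted grid points require MAFs; when absent, the search
  restricts to the 66 grid points with `rho2 = 0` (logged).
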