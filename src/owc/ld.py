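"""SNP correlation (LD) matrices: construction, validation, repair, factorization.

A gene's linkage-disequilibrium matrix ``R`` is the pairwise Pearson
correlation matrix of genotype dosages for the SNPs assigned to the gene.
Under no association the vector of per-SNP Z-scores is multivariate normal
with covariance ``R``, so every null computation in this package runs
through an :class:`LDMatrix` and its Cholesky factor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
DIAG_TOL = 1e-8
PSD_FLOOR = 1e-8

#: condition number above which `regularized_inverse` escalates to a ridge
COND_MAX = 1e8
#: ridge applied automatically on escalation
AUTO_RIDGE = 1e-6


class LDError(ValueError):
    """Invalid LD matrix or operation on one."""


@dataclass
class LDMatrix:
    """Symmetric unit-diagonal SNP correlation matrix with aligned SNP ids.

    Parameters
    ----------
    snp_ids
        SNP identifiers, one per row/column, in matrix order.
    values
        ``M x M`` correlation matrix; symmetric to 1e-8, unit diagonal.
    psd_repaired
        True if the matrix went through :func:`psd_repair`.
    """

    snp_ids: list[str]
    values: np.ndarray
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise LDError(f"LD matrix must be square, got shape {v.shape}")
        if len(self.snp_ids) != v.shape[0]:
            raise LDError(
                f"{len(self.snp_ids)} SNP ids for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        if not np.all(np.isfinite(v)):
            raise LDError("LD matrix contains non-finite entries")
        if v.shape[0] == 0:  # empty gene after QC: valid degenerate matrix
            self.values = v
            self.snp_ids = list(self.snp_ids)
            return
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise LDError("LD matrix is not symmetric (tolerance 1e-8)")
        if np.max(np.abs(np.diag(v) - 1.0)) > DIAG_TOL:
            raise LDError("LD matrix diagonal must be 1 (tolerance 1e-8)")
        if np.max(np.abs(v)) > 1.0 + SYMMETRY_TOL:
            raise LDError("LD matrix entries must lie in [-1, 1]")
        # enforce exact symmetry / unit diagonal / range
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        self.snp_ids = list(self.snp_ids)

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray | list[int]) -> "LDMatrix":
        """Conformal subset keeping rows/columns ``idx`` in the given order."""
        idx = np.asarray(idx, dtype=int)
        return LDMatrix(
            [self.snp_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            psd_repaired=self.psd_repaired,
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class CholeskyFactor:
    """Lower-triangular factor ``D`` with ``D D' = R``."""

    snp_ids: list[str]
    lower_triangular: np.ndarray


def ld_from_genotypes(dosages: np.ndarray, snp_ids: list[str] | None = None) -> LDMatrix:
    """Pearson-correlation LD matrix from an ``n x M`` dosage matrix.

    Raises :class:`LDError` naming the offending SNP if a column is constant.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LDError("dosage matrix must be n x M with n >= 2")
    M = X.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(M)]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = snp_ids[int(np.argmin(sd))]
        raise LDError(f"constant dosage column for SNP {bad!r}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(snp_ids, np.clip(R, -1.0, 1.0))


def psd_repair(R: LDMatrix, floor: float = PSD_FLOOR) -> LDMatrix:
    """Raise eigenvalues below ``floor`` and rescale back to unit diagonal.

    A no-op (returning ``R`` itself) when the matrix is already positive
    semi-definite at the floor.  Eigenvalue flooring is deterministic and
    cheap; it is an approximation to the nearest correlation matrix.
    """
    w, V = np.linalg.eigh(R.values)
    if w[0] >= floor:
        return R
    w = np.maximum(w, floor)
    repaired = (V * w) @ V.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    logger.info("psd_repair: floored %d eigenvalues below %g", int(np.sum(w == floor)), floor)
    return LDMatrix(R.snp_ids, repaired, psd_repaired=True)


def cholesky_factor(R: LDMatrix) -> CholeskyFactor:
    """Lower-triangular ``D`` with ``D D' = R`` (used to sample MVN(0, R))."""
    try:
        D = np.linalg.cholesky(R.values)
    except np.linalg.LinAlgError as exc:
        raise LDError(
            "LD matrix is not positive definite; run psd_repair first"
        ) from exc
    return CholeskyFactor(R.snp_ids, D)


def regularized_inverse(
    R: LDMatrix,
    ridge: float = 0.0,
    *,
    cond_max: float = COND_MAX,
    auto_ridge: float = AUTO_RIDGE,
) -> np.ndarray:
    """Inverse of ``R`` (or of ``R + ridge*I``) for the score test.

    With ``ridge == 0`` the condition number is checked; if it exceeds
    ``cond_max`` the ridge auto-escalates to ``auto_ridge`` and the event is
    logged.  Singular input with no ridge available raises :class:`LDError`
    suggesting a ridge or more aggressive pruning.
    """
    w = np.linalg.eigvalsh(R.values)
    used = ridge
    if ridge == 0.0:
        if w[0] <= 0:
            if auto_ridge > 0:
                used = auto_ridge
                logger.warning(
                    "LD matrix singular (min eigenvalue %.3g); using ridge %g", w[0], auto_ridge
                )
            else:
                raise LDError(
                    "LD matrix is singular; supply a ridge or prune correlated SNPs"
                )
        elif w[-1] / w[0] > cond_max:
            used = auto_ridge
            logger.warning(
                "LD matrix ill-conditioned (cond %.3g > %.3g); ridge escalated to %g",
                w[-1] / w[0], cond_max, auto_ridge,
            )
    A = R.values + used * np.eye(R.M) if used > 0 else R.values
    # solve via Cholesky rather than forming inv() from an LU factorization
    L = np.linalg.cholesky(A)
    inv = np.linalg.solve(A, np.eye(R.M))
    del L
    return (inv + inv.T) / 2.0


def read_ld_matrix(path) -> LDMatrix:
    """Read a whitespace-delimited square matrix, optional header of SNP ids."""
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise LDError(f"empty LD matrix file: {path}")
    snp_ids: list[str] | None = None
    try:
        float(lines[0][0])
    except ValueError:
        snp_ids = lines[0]
        lines = lines[1:]
    values = np.array([[float(x) for x in row] for row in lines])
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(values.shape[0])]
    return LDMatrix(snp_ids, values)


def write_ld_matrix(R: LDMatrix, path) -> None:
    """Write the same dialect :func:`read_ld_matrix` accepts (with header)."""
    with open(path, "w") as fh:
        fh.write(" ".join(R.snp_ids) + "\n")
        for row in R.values:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_genotype_matrix(path, delimiter=None) -> np.ndarray:
    """Read an ``n x M`` dosage matrix from delimited text (no header)."""
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)
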