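"""GWAS summary-statistic input: parsing, QC filtering, gene assignment.

Summary files carry per-SNP id, position, MAF, effect size (or odds ratio)
and p-value, or a precomputed Z.  A missing Z is reconstructed as
``Z = sign(beta) * Phi^{-1}(1 - p/2)``.  SNPs are assigned to genes by a
window of 20 kb up- and downstream of the annotated interval, and each
gene's SNP set is QC-filtered: rare variants (MAF < 0.05) are removed and
one of each SNP pair with pairwise LD r^2 > 0.5 is pruned so that the
gene's LD matrix stays invertible.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDMatrix

logger = logging.getLogger(__name__)

#: p-values below this are clamped before the normal-quantile transform
PVALUE_FLOOR = 1e-300

DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "maf": "MAF",
    "beta": "BETA",
    "odds_ratio": "OR",
    "pvalue": "P",
    "z": "Z",
}


class SummaryFormatError(ValueError):
    """Configuration or format problem in a summary-statistics file."""


@dataclass
class SnpRecord:
    """One SNP's summary statistics.

    Either ``z`` or (``pvalue`` and the sign of ``beta``) must be present so
    a signed Z-score can be formed.
    """

    snp_id: str
    chrom: str = ""
    pos: int = 0
    maf: float | None = None
    beta: float | None = None
    pvalue: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} for {self.snp_id} outside (0, 0.5]")
        if self.z is None and (self.pvalue is None or self.beta is None):
            raise ValueError(
                f"SNP {self.snp_id}: need either z or (pvalue and signed beta)"
            )

    def zscore(self) -> float:
        """Signed Z: the stored one, or sign(beta)*Phi^{-1}(1-p/2)."""
        if self.z is not None:
            return float(self.z)
        sign = 0 if self.beta == 0 else int(math.copysign(1, self.beta))
        return zscore_from_p(self.pvalue, sign)


@dataclass
class GeneAnnotation:
    """A gene interval (1-based, closed)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GeneSummary:
    """Aligned per-gene vectors of SNP ids, Z-scores and MAFs."""

    gene_id: str
    snps: list[SnpRecord] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def z(self) -> np.ndarray:
        return np.array([s.zscore() for s in self.snps])

    @property
    def maf(self) -> np.ndarray | None:
        vals = [s.maf for s in self.snps]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=int)


def zscore_from_p(pvalue: float, beta_sign: int) -> float:
    """Signed Z from a two-sided p-value: ``sign(beta) * Phi^{-1}(1 - p/2)``.

    ``beta_sign == 0`` returns 0.  p-values below 1e-300 are clamped (with a
    warning) to avoid quantile overflow; p outside (0, 1] is a domain error.
    """
    if not (0.0 < pvalue <= 1.0):
        raise ValueError(f"p-value {pvalue} outside (0, 1]")
    if pvalue < PVALUE_FLOOR:
        warnings.warn(
            f"p-value {pvalue:.3g} below floor {PVALUE_FLOOR:g}; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        pvalue = PVALUE_FLOOR
    if beta_sign == 0:
        return 0.0
    return float(beta_sign * stats.norm.isf(pvalue / 2.0))


def p_from_z(z: float) -> float:
    """Two-sided normal p-value of a Z-score (inverse of :func:`zscore_from_p`)."""
    return float(2.0 * stats.norm.sf(abs(z)))


def read_summary(path, column_map: dict[str, str] | None = None) -> list[SnpRecord]:
    """Read a delimited summary-statistics file into :class:`SnpRecord` rows.

    ``column_map`` maps field names (``snp_id``, ``chrom``, ``pos``, ``maf``,
    ``beta``, ``odds_ratio``, ``pvalue``, ``z``) to column headers; defaults
    cover the common SNP/CHR/BP/MAF/BETA/P/Z convention.  Rows whose
    mandatory fields fail to parse are dropped and counted in the log.  If
    only an odds ratio is given, ``beta = log(OR)``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise SummaryFormatError(f"no data rows in {path}")
    cols = set(df.columns)
    if cmap["snp_id"] not in cols:
        raise SummaryFormatError(f"missing mandatory column {cmap['snp_id']!r}")
    has_z = cmap["z"] in cols
    has_p = cmap["pvalue"] in cols and (cmap["beta"] in cols or cmap["odds_ratio"] in cols)
    if not has_z and not has_p:
        raise SummaryFormatError(
            f"need either a Z column ({cmap['z']!r}) or p-value plus "
            f"effect-size columns ({cmap['pvalue']!r}, {cmap['beta']!r}/{cmap['odds_ratio']!r})"
        )

    def _get(row, key, cast):
        col = cmap[key]
        if col not in cols:
            return None
        val = row[col]
        if pd.isna(val):
            return None
        return cast(val)

    records: list[SnpRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        try:
            beta = _get(row, "beta", float)
            if beta is None:
                orat = _get(row, "odds_ratio", float)
                if orat is not None:
                    if orat <= 0:
                        raise ValueError(f"odds ratio {orat} <= 0")
                    beta = math.log(orat)
            rec = SnpRecord(
                snp_id=str(row[cmap["snp_id"]]),
                chrom=str(_get(row, "chrom", lambda v: v) or ""),
                pos=int(_get(row, "pos", float) or 0),
                maf=_get(row, "maf", float),
                beta=beta,
                pvalue=_get(row, "pvalue", float),
                z=_get(row, "z", float),
            )
        except (ValueError, TypeError):
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.info("read_summary: dropped %d unparseable rows from %s", dropped, path)
    if not records:
        raise SummaryFormatError(f"no parseable rows in {path}")
    return records


def read_gene_annotations(path, bed: bool = True) -> list[GeneAnnotation]:
    """Read a BED-like 4-column table (chrom, start, end, gene_id).

    BED input is 0-based half-open and is converted to the internal 1-based
    closed convention (``start + 1``, ``end``); pass ``bed=False`` for a
    table already 1-based closed.
    """
    genes = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene_id = ln.split()[:4]
            start, end = int(start), int(end)
            if bed:
                start += 1
            genes.append(GeneAnnotation(gene_id, chrom, start, end))
    return genes


def assign_snps_to_genes(
    snps: list[SnpRecord],
    genes: list[GeneAnnotation],
    window_bp: int = 20_000,
) -> list[GeneSummary]:
    """Assign each SNP to every gene whose +/-``window_bp`` window contains it.

    A SNP belongs to gene g iff chromosomes match and
    ``g.start - window <= pos <= g.end + window`` (boundaries inclusive).
    A SNP may land in several overlapping genes; genes with no SNPs are
    omitted.  SNPs within each gene are ordered by position.
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    out = []
    for g in genes:
        members = [
            s
            for s in by_chrom.get(g.chrom, [])
            if g.start - window_bp <= s.pos <= g.end + window_bp
        ]
        if members:
            out.append(GeneSummary(g.gene_id, members))
    return out


def qc_filter(
    gene: GeneSummary,
    R: LDMatrix,
    maf_min: float = 0.05,
    r2_max: float = 0.5,
    keep: str = "position",
) -> tuple[GeneSummary, LDMatrix]:
    """Remove rare variants and prune one of each highly correlated SNP pair.

    Step 1 drops SNPs with ``maf < maf_min``.  Step 2 scans the survivors and
    greedily drops any SNP whose r^2 with an already-kept SNP exceeds
    ``r2_max``.  With ``keep='position'`` (default) the scan runs in genomic
    order, keeping the earlier SNP of a pair — a choice independent of the
    observed Z-scores, so it cannot distort the null.  ``keep='zmax'`` scans
    in decreasing |Z| instead, keeping the more significant member.

    Returns the filtered gene and the conformally subset LD matrix; a gene
    whose SNPs are all removed comes back with ``M == 0`` so downstream
    tests can skip it explicitly.
    """
    if R.M != gene.M:
        raise ValueError("LD matrix not aligned to gene SNP order")
    # SNPs with no MAF cannot be judged rare and are kept at this step
    idx = [i for i, s in enumerate(gene.snps) if s.maf is None or s.maf >= maf_min]
    if keep == "position":
        order = sorted(idx, key=lambda i: gene.snps[i].pos)
    elif keep == "zmax":
        order = sorted(idx, key=lambda i: -abs(gene.snps[i].zscore()))
    else:
        raise ValueError(f"unknown keep policy {keep!r}")
    kept: list[int] = []
    r2 = R.values**2
    for i in order:
        if all(r2[i, j] <= r2_max for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: gene.snps[i].pos)  # preserve genomic order
    dropped = gene.M - len(kept)
    if dropped:
        logger.info("qc_filter(%s): %d of %d SNPs removed", gene.gene_id, dropped, gene.M)
    filtered = GeneSummary(gene.gene_id, [gene.snps[i] for i in kept])
    return filtered, R.subset(kept)


def write_gene_summary(gene: GeneSummary, path) -> None:
    """Serialize one gene's aligned SNP table as TSV for audit."""
    df = pd.DataFrame(
        {
            "snp_id": gene.snp_ids,
            "chrom": [s.chrom for s in gene.snps],
            "pos": [s.pos for s in gene.snps],
            "maf": [s.maf for s in gene.snps],
            "z": [s.zscore() for s in gene.snps],
        }
    )
    df.to_csv(path, sep="\t", index=False)
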