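"""Allele-specific expression scoring for F1 hybrid crosses.

In a Mus musculus x M. castaneus hybrid, reads overlapping strain-specific
SNPs can be assigned to a parental allele.  Per SNP, allelic activity is the
pseudocount-normalized ratio

    (musculus coverage + 1) / (castaneus coverage + 1)

which is always finite and positive.  Per gene, ratios are summarized as
mean +/- SD across SNPs, and genotypes (wild type vs mutant) are compared by
a two-tailed Mann-Whitney U test on the per-SNP ratio sets — exact null
distribution for small samples without ties, tie-corrected normal
approximation otherwise.  A ratio r converts to a musculus allele fraction
r / (1 + r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllelicResult",
    "normalized_allele_expression",
    "gene_allelic_summary",
    "compare_alleles",
    "allele_fraction",
    "read_snp_table",
    "write_snp_table",
    "write_allelic_results",
]

SNP_COLUMNS = ["gene", "pos", "mus_count", "cast_count", "genotype"]

# exact Mann-Whitney only for small samples; beyond this the normal
# approximation is indistinguishable and enumeration cost explodes
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class AllelicResult:
    gene: str
    genotypes: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    u_statistic: float
    p_value: float
    method: str  # 'exact' or 'asymptotic'


def normalized_allele_expression(mus_count: int, cast_count: int) -> float:
    """Pseudocount-normalized allelic ratio (mus + 1) / (cast + 1)."""
    if mus_count < 0 or cast_count < 0:
        raise ValueError(
            f"allele counts must be non-negative, got ({mus_count}, {cast_count})"
        )
    return (mus_count + 1) / (cast_count + 1)


def allele_fraction(ratio: float) -> float:
    """Convert an allelic ratio to the musculus allele fraction r/(1+r)."""
    if ratio < 0:
        raise ValueError(f"allelic ratio must be non-negative, got {ratio}")
    return ratio / (1.0 + ratio)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if (table["mus_count"] < 0).any() or (table["cast_count"] < 0).any():
        raise ValueError("SNP table contains negative counts")
    dup = table.duplicated(subset=["gene", "pos", "genotype"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene, pos, genotype) rows: "
            f"{table.loc[dup, ['gene', 'pos', 'genotype']].values.tolist()}"
        )
    return table


def _ratios(table: pd.DataFrame, gene: str, genotype: str) -> np.ndarray:
    sub = table[(table["gene"] == gene) & (table["genotype"] == genotype)]
    return (sub["mus_count"].to_numpy() + 1.0) / (sub["cast_count"].to_numpy() + 1.0)


def gene_allelic_summary(
    table: pd.DataFrame, gene: str, genotype: str
) -> tuple[float, float, int]:
    """Mean, sample SD, and n of pseudocount ratios for one gene/genotype.

    With a single SNP the sample SD is undefined; 0 is reported by convention
    (n=1 flags it).
    """
    _validate_table(table)
    r = _ratios(table, gene, genotype)
    if r.size == 0:
        raise ValueError(f"no SNPs for gene {gene!r}, genotype {genotype!r}")
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd, int(r.size)


def compare_alleles(
    table: pd.DataFrame, gene: str, genotypes: tuple[str, str] | None = None
) -> AllelicResult:
    """Two-tailed Mann-Whitney comparison of per-SNP allelic ratios between
    two genotypes of one gene.

    The exact null distribution is used when min(n1, n2) <= 8 and there are
    no ties; otherwise the tie-corrected normal approximation.
    """
    _validate_table(table)
    if genotypes is None:
        found = sorted(table.loc[table["gene"] == gene, "genotype"].unique())
        if len(found) != 2:
            raise ValueError(
                f"gene {gene!r} needs exactly two genotypes, found {found}"
            )
        genotypes = (found[0], found[1])
    x = _ratios(table, gene, genotypes[0])
    y = _ratios(table, gene, genotypes[1])
    for gt, arr in zip(genotypes, (x, y)):
        if arr.size == 0:
            raise ValueError(f"no SNPs for gene {gene!r}, genotype {gt!r}")

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)

    sds = []
    for arr in (x, y):
        sds.append(float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0)
    return AllelicResult(
        gene=gene,
        genotypes=genotypes,
        means=(float(x.mean()), float(y.mean())),
        sds=(sds[0], sds[1]),
        ns=(int(x.size), int(y.size)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


# ---------------------------------------------------------------------------
# I/O


def read_snp_table(path) -> pd.DataFrame:
    """Read a `gene pos mus_count cast_count genotype` TSV."""
    table = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=SNP_COLUMNS,
        header=None,
        skiprows=_count_header_rows(path),
    )
    table["pos"] = table["pos"].astype(int)
    table["mus_count"] = table["mus_count"].astype(int)
    table["cast_count"] = table["cast_count"].astype(int)
    return _validate_table(table)


def _count_header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline().split()
    return 1 if first[:1] == ["gene"] else 0


def write_snp_table(table: pd.DataFrame, path) -> None:
    _validate_table(table)[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def write_allelic_results(results: list[AllelicResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "genotype_a": r.genotypes[0],
                "genotype_b": r.genotypes[1],
                "mean_a": r.means[0],
                "sd_a": r.sds[0],
                "n_a": r.ns[0],
                "mean_b": r.means[1],
                "sd_b": r.sds[1],
                "n_b": r.ns[1],
                "U": r.u_statistic,
                "p_value": r.p_value,
                "method": r.method,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
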