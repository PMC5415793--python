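"""Percent paternal-X expression from allelic SNP counts.

The central statistic of the pipeline: at each SNP the percent of
SNP-overlapping reads from the paternal (inactive-X) allele, averaged
unweighted across the SNPs of a gene that reach a total-coverage threshold
(default 10X; 5X is the sensitivity preset).  Gene totals, library-size
normalized by median-of-ratios, are scaled by that percentage to give the
paternal-scaled counts used for absolute differential testing:

    paternal_scaled = total_reads x paternal / (maternal + paternal)
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 10
SENSITIVITY_MIN_COVERAGE = 5


def snp_percent_paternal(maternal_count: int, paternal_count: int) -> float:
    """Percent of reads at one SNP from the paternal allele; NaN at zero coverage."""
    if maternal_count < 0 or paternal_count < 0:
        raise ValueError("counts must be non-negative")
    cov = maternal_count + paternal_count
    if cov == 0:
        return float("nan")
    return 100.0 * paternal_count / cov


def per_snp_table(allelic_counts: pd.DataFrame) -> pd.DataFrame:
    """Add coverage and percent_paternal columns to an allelic-count table."""
    df = allelic_counts.copy()
    df["coverage"] = df["maternal_count"] + df["paternal_count"]
    cov = df["coverage"].to_numpy(dtype=float)
    pat = df["paternal_count"].to_numpy(dtype=float)
    df["percent_paternal"] = np.where(cov > 0, 100.0 * pat / np.maximum(cov, 1.0), np.nan)
    return df


def gene_percent_paternal(
    allelic_counts: pd.DataFrame,
    snp_to_gene: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    coverage_weighted: bool = False,
) -> pd.DataFrame:
    """Per-(gene, sample) percent paternal-X expression.

    SNPs with total coverage >= ``min_coverage`` are "informative"; the gene
    value is the unweighted mean of their per-SNP percentages (the default;
    ``coverage_weighted=True`` weights by coverage instead).  Genes with no
    informative SNP in a sample get ``percent_paternal`` NaN and
    ``n_informative_snps`` 0.

    ``snp_to_gene`` maps snp_id -> gene_id; a SNP shared by overlapping
    genes may appear once per gene (logged).

    Returns one row per (gene_id, sample_id) over the full gene x sample
    grid, with columns n_informative_snps, percent_paternal,
    mean_snp_coverage.
    """
    dup = snp_to_gene.groupby("snp_id")["gene_id"].nunique()
    shared = dup[dup > 1]
    if len(shared):
        logger.info("%d SNPs assigned to more than one gene", len(shared))

    df = per_snp_table(allelic_counts).merge(snp_to_gene, on="snp_id", how="inner")
    df = df[df["coverage"] >= min_coverage]

    if coverage_weighted:
        def _agg(g: pd.DataFrame) -> pd.Series:
            w = g["coverage"].to_numpy(float)
            return pd.Series({
                "n_informative_snps": len(g),
                "percent_paternal": float(np.average(g["percent_paternal"], weights=w)),
                "mean_snp_coverage": float(w.mean()),
            })
        summ = (
            df.groupby(["gene_id", "sample_id"])[["coverage", "percent_paternal"]]
            .apply(_agg).reset_index()
        )
    else:
        summ = (
            df.groupby(["gene_id", "sample_id"])
            .agg(
                n_informative_snps=("snp_id", "size"),
                percent_paternal=("percent_paternal", "mean"),
                mean_snp_coverage=("coverage", "mean"),
            )
            .reset_index()
        )

    genes = snp_to_gene["gene_id"].unique()
    samples = allelic_counts["sample_id"].unique()
    grid = pd.MultiIndex.from_product(
        [genes, samples], names=["gene_id", "sample_id"]
    ).to_frame(index=False)
    out = grid.merge(summ, on=["gene_id", "sample_id"], how="left")
    out["n_informative_snps"] = out["n_informative_snps"].fillna(0).astype(int)
    return out


def percent_matrix(gene_summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the per-(gene, sample) summary to a gene x sample percent matrix."""
    return gene_summary.pivot(
        index="gene_id", columns="sample_id", values="percent_paternal"
    )


def common_informative_genes(
    gene_summary: pd.DataFrame, samples: Sequence[str]
) -> tuple[set[str], dict[str, set[str]]]:
    """Genes with a defined percent in *every* listed sample.

    Returns the common set and the per-sample informative sets.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    mat = percent_matrix(gene_summary)
    missing = [s for s in samples if s not in mat.columns]
    if missing:
        raise ValueError(f"samples without summaries: {missing}")
    per_sample = {s: set(mat.index[mat[s].notna()]) for s in samples}
    common = set.intersection(*per_sample.values())
    return common, per_sample


def size_factors(total_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (gene x sample count matrix)."""
    logc = np.log(total_counts.where(total_counts > 0))
    ref = logc.mean(axis=1)
    usable = ref.notna()
    if not usable.any():
        raise ValueError("no gene has non-zero counts in every sample")
    lr = logc.loc[usable].sub(ref[usable], axis=0)
    return np.exp(lr.median(axis=0)).rename("size_factor")


def normalize_totals(total_counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's counts by its median-of-ratios size factor."""
    return total_counts.div(size_factors(total_counts), axis=1)


def scaled_paternal_counts(
    normalized_totals: pd.DataFrame,
    percent: pd.DataFrame,
    round_to_int: bool = True,
) -> pd.DataFrame:
    """Paternal-scaled expression: normalized total x percent/100 per cell.

    Genes whose percent is undefined (NaN) in any sample are dropped (and
    logged); by default the result is rounded to the nearest integer so
    negative-binomial count machinery applies downstream.
    """
    common = normalized_totals.index.intersection(percent.index)
    pct = percent.loc[common, normalized_totals.columns]
    defined = pct.notna().all(axis=1)
    if (~defined).any():
        logger.info(
            "excluding %d genes with undefined percent in some sample",
            int((~defined).sum()),
        )
    scaled = normalized_totals.loc[common[defined]] * pct[defined] / 100.0
    if round_to_int:
        scaled = scaled.round().astype(np.int64)
    return scaled


def rpkm(
    total_counts: pd.DataFrame, gene_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads."""
    lengths = pd.Series(
        {g: gene_lengths[g] for g in total_counts.index}, dtype=float
    )
    per_million = total_counts.sum(axis=0) / 1e6
    return total_counts.div(per_million, axis=1).div(lengths / 1e3, axis=0)
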