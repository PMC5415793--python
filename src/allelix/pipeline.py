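"""End-to-end orchestration: quantify -> classify -> enrich -> report.

`run_pipeline` consumes the file formats defined in :mod:`allelix.io_formats`
and produces the per-gene classification table, quintile enrichment, and a
summary report of the cascade stage counts (informative per group, common
set, escapees, candidates, significant, derepressed up/down).

`cascade_from_tables` recomputes the same cascade directly from published
per-line percent tables (one row per gene, one percent column per line)
plus a differential-expression table, for checking printed gene counts
without re-running quantification.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import allelic_quant as aq
from . import classify as cl
from . import enrichment as en
from .io_formats import read_allelic_counts, read_table, read_total_counts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and bookkeeping for a full run."""

    allelic_counts: str
    total_counts: str
    snp_to_gene: str
    design: dict[str, str]             # sample_id -> WT | KO
    outdir: str = "allelix_out"
    min_coverage: int = aq.DEFAULT_MIN_COVERAGE
    escapee_threshold: float = cl.DEFAULT_ESCAPEE_THRESHOLD
    delta: float = cl.DEFAULT_DELTA
    fdr: float = cl.DEFAULT_FDR
    bh_family: str = "candidates"
    n_quantiles: int = 5
    fisher_draws: int = en.DEFAULT_MC_DRAWS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.escapee_threshold <= 0 or self.delta <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")

    def config_hash(self) -> str:
        """Fingerprint of the analytic settings (output location excluded)."""
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    gene_summary: pd.DataFrame
    classification: pd.DataFrame
    quintiles: pd.DataFrame
    enrichment: pd.DataFrame
    counts: dict[str, float] = field(default_factory=dict)


def quantify(
    allelic_counts: pd.DataFrame,
    snp_to_gene: pd.DataFrame,
    total_counts: pd.DataFrame,
    design: cl.SampleDesign,
    min_coverage: int = aq.DEFAULT_MIN_COVERAGE,
) -> dict:
    """Gene-level percent matrices and paternal-scaled counts for both groups."""
    summary = aq.gene_percent_paternal(allelic_counts, snp_to_gene, min_coverage)
    mat = aq.percent_matrix(summary)
    for s in design.wt_samples + design.ko_samples:
        if s not in mat.columns:
            raise ValueError(f"sample {s!r} missing from allelic counts")
    wt_percent = mat[design.wt_samples]
    ko_percent = mat[design.ko_samples]
    normalized = aq.normalize_totals(total_counts)
    scaled = aq.scaled_paternal_counts(
        normalized, mat[design.wt_samples + design.ko_samples]
    )
    return {
        "gene_summary": summary,
        "wt_percent": wt_percent,
        "ko_percent": ko_percent,
        "normalized_totals": normalized,
        "scaled_counts": scaled,
    }


def analyze(
    allelic_counts: pd.DataFrame,
    snp_to_gene: pd.DataFrame,
    total_counts: pd.DataFrame,
    design: cl.SampleDesign,
    min_coverage: int = aq.DEFAULT_MIN_COVERAGE,
    escapee_threshold: float = cl.DEFAULT_ESCAPEE_THRESHOLD,
    delta: float = cl.DEFAULT_DELTA,
    fdr: float = cl.DEFAULT_FDR,
    bh_family: str = "candidates",
    n_quantiles: int = 5,
    fisher_draws: int = en.DEFAULT_MC_DRAWS,
    seed: int = 0,
) -> PipelineResult:
    """Run the full in-memory analysis on count tables."""
    q = quantify(allelic_counts, snp_to_gene, total_counts, design, min_coverage)
    res = cl.classify_genes(
        q["wt_percent"], q["ko_percent"], q["scaled_counts"], design,
        escapee_threshold=escapee_threshold, delta=delta, fdr=fdr,
        bh_family=bh_family,
    )
    table = res.table

    counts: dict[str, float] = dict(res.counts)
    _, per_sample = aq.common_informative_genes(
        q["gene_summary"], design.wt_samples + design.ko_samples
    )
    wt_inf = set.intersection(*(per_sample[s] for s in design.wt_samples))
    ko_inf = set.intersection(*(per_sample[s] for s in design.ko_samples))
    counts["n_wt_informative"] = len(wt_inf)
    counts["n_ko_informative"] = len(ko_inf)

    derepressed = table["status"] == cl.STATUS_UP
    if len(table) >= n_quantiles:
        quint = en.quintile_partition(table["wt_mean_percent"], k=n_quantiles)
        enr, fisher_p = en.quintile_enrichment(
            quint, derepressed, method="mc", n_draws=fisher_draws, seed=seed
        )
        counts["fisher_p"] = fisher_p
    else:
        quint = pd.DataFrame(
            columns=["gene_id", "wt_percent", "rank", "quintile"]
        )
        enr = pd.DataFrame()
        counts["fisher_p"] = float("nan")
    r, n_r = en.wt_ko_correlation(
        table["wt_mean_percent"], table["ko_mean_percent"]
    )
    counts["wt_ko_pearson_r"] = r
    counts["n_correlated_genes"] = n_r

    return PipelineResult(
        gene_summary=q["gene_summary"],
        classification=table,
        quintiles=quint,
        enrichment=enr,
        counts=counts,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, analyze, write all outputs.

    Outputs (TSV with a provenance header comment, plus summary.json) land
    in ``config.outdir``.  Deterministic for a fixed config and seed.
    """
    design = cl.SampleDesign(dict(config.design))
    allelic = read_allelic_counts(config.allelic_counts)
    totals = read_total_counts(config.total_counts)
    snp_map = pd.read_csv(config.snp_to_gene, sep="\t", dtype=str)
    if not {"snp_id", "gene_id"} <= set(snp_map.columns):
        raise ValueError("snp_to_gene needs snp_id and gene_id columns")

    result = analyze(
        allelic, snp_map, totals, design,
        min_coverage=config.min_coverage,
        escapee_threshold=config.escapee_threshold,
        delta=config.delta,
        fdr=config.fdr,
        bh_family=config.bh_family,
        n_quantiles=config.n_quantiles,
        fisher_draws=config.fisher_draws,
        seed=config.seed,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# allelix {__version__} config={config.config_hash()} "
        f"seed={config.seed}\n"
    )

    def _write(df: pd.DataFrame, name: str, index: bool) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)

    _write(result.gene_summary, "gene_summary.tsv", index=False)
    _write(result.classification.rename_axis("gene_id"), "classification.tsv",
           index=True)
    _write(result.quintiles, "quintiles.tsv", index=False)
    _write(result.enrichment.reset_index(), "enrichment.tsv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {"version": __version__, "config_hash": config.config_hash(),
             "seed": config.seed, "counts": result.counts},
            fh, indent=2, sort_keys=True, default=float,
        )
        fh.write("\n")
    return result


# ---------------------------------------------------------------------------
# Cascade recomputation from published per-line tables
# ---------------------------------------------------------------------------

def _find_columns(df: pd.DataFrame, pattern: str) -> list[str]:
    rx = re.compile(pattern, re.IGNORECASE)
    return [c for c in df.columns if rx.search(str(c))]


def cascade_from_tables(
    percent_table: str | Path | pd.DataFrame,
    diff_table: str | Path | pd.DataFrame | None = None,
    gene_col: str | None = None,
    wt_cols: list[str] | None = None,
    ko_cols: list[str] | None = None,
    escapee_threshold: float = cl.DEFAULT_ESCAPEE_THRESHOLD,
    delta: float = cl.DEFAULT_DELTA,
    fdr: float = cl.DEFAULT_FDR,
    log2fc_col: str | None = None,
) -> dict[str, float]:
    """Recompute the cascade counts from per-line percent-paternal tables.

    ``percent_table``: one row per gene with per-line percent columns (WT
    lines matched by /wt/i, knockout lines by /ko|ko1|eed/i unless given
    explicitly).  Rows with missing values are dropped (only the common
    informative set supports the comparison).  ``diff_table`` optionally
    supplies a per-gene paternal log2 fold change (column matched by
    /log2/i) used for the up/down split of significant candidates.

    Returns the stage counts plus quintile-4 derepressed count, Fisher p
    and the WT-KO Pearson r.
    """
    df = percent_table if isinstance(percent_table, pd.DataFrame) else read_table(percent_table)
    if gene_col is None:
        gene_col = df.columns[0]
    if wt_cols is None:
        wt_cols = _find_columns(df, r"wt")
    if ko_cols is None:
        ko_cols = [c for c in _find_columns(df, r"ko|eed|mut") if c not in wt_cols]
    if len(wt_cols) < 2 or len(ko_cols) < 2:
        raise ValueError(
            f"could not locate per-line percent columns (wt={wt_cols}, ko={ko_cols})"
        )
    df = df.set_index(gene_col)
    wt = df[wt_cols].apply(pd.to_numeric, errors="coerce")
    ko = df[ko_cols].apply(pd.to_numeric, errors="coerce")
    keep = wt.notna().all(axis=1) & ko.notna().all(axis=1)
    wt, ko = wt[keep], ko[keep]

    is_escapee = cl.call_escapees(wt, escapee_threshold).astype(bool)
    is_candidate = cl.call_candidates(wt, ko, delta)
    pvals = pd.Series(
        [cl.welch_test(wt.loc[g].to_numpy(), ko.loc[g].to_numpy())
         for g in wt.index],
        index=wt.index,
    )
    significant = pd.Series(False, index=wt.index)
    fam = wt.index[is_candidate]
    if len(fam):
        _, sig = cl.bh_adjust(pvals.loc[fam].to_numpy(), fdr)
        significant.loc[fam] = sig

    out: dict[str, float] = {
        "n_common_informative": int(keep.sum()),
        "n_escapees": int(is_escapee.sum()),
        "n_ko_ge_escapee_threshold": int((ko >= escapee_threshold).all(axis=1).sum()),
        "n_candidates": int(is_candidate.sum()),
        "n_significant": int((is_candidate & significant).sum()),
    }

    derepressed = is_candidate & significant
    if diff_table is not None:
        dt = diff_table if isinstance(diff_table, pd.DataFrame) else read_table(diff_table)
        if log2fc_col is None:
            cand = _find_columns(dt, r"log2")
            if not cand:
                raise ValueError("no log2 fold-change column found in diff table")
            log2fc_col = cand[0]
        lfc = pd.to_numeric(
            dt.set_index(dt.columns[0])[log2fc_col], errors="coerce"
        ).reindex(wt.index)
        up = derepressed & (lfc > 0)
        out["n_derepressed_up"] = int(up.sum())
        out["n_derepressed_down"] = int((derepressed & ~(lfc > 0)).sum())
        derepressed = up

    if len(wt) >= 5:
        quint = en.quintile_partition(wt.mean(axis=1))
        enr, p = en.quintile_enrichment(quint, derepressed, method="mc")
        out["fisher_p"] = p
        out["n_quintile4_derepressed"] = int(enr.loc[4, "n_derepressed"])
    r, n = en.wt_ko_correlation(wt.mean(axis=1), ko.mean(axis=1))
    out["wt_ko_pearson_r"] = r
    return out
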