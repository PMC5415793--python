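"""Escapee and derepression calling on percent paternal-X expression.

The cascade, applied to the set of genes informative in every WT and KO
sample:

1. *Escapees* — >= 10% paternal expression in every WT line (genes with at
   least this much inactive-X output are conventionally classed as
   X-inactivation escapees).
2. *Candidates* — every KO line's percent exceeds the WT mean by >= 10
   percentage points (a consistent relative increase).
3. *Significance* — Welch's unequal-variance t-test of per-line percentages,
   Benjamini-Hochberg corrected within the candidate family, FDR 0.1.
4. *Up/down split* — a negative-binomial Wald test on paternal-scaled
   counts separates genes whose shift is driven by paternal-allele
   upregulation (log2FC > 0, "derepressed_up") from shifts explained by
   maternal-allele downregulation (log2FC <= 0, "derepressed_down").

Thresholds are percentage *points* (>= is inclusive) and all are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ESCAPEE_THRESHOLD = 10.0
DEFAULT_DELTA = 10.0
DEFAULT_FDR = 0.1
LOG2FC_PSEUDOCOUNT = 0.5

STATUS_SILENCED = "silenced"
STATUS_ESCAPEE = "escapee"
STATUS_UP = "derepressed_up"
STATUS_DOWN = "derepressed_down"


@dataclass
class SampleDesign:
    """Sample-to-group assignment for the two-genotype comparison."""

    groups: dict[str, str]  # sample_id -> "WT" | "KO"

    def __post_init__(self) -> None:
        bad = set(self.groups.values()) - {"WT", "KO"}
        if bad:
            raise ValueError(f"unknown groups {bad}; use WT/KO")
        if len(self.wt_samples) < 2 or len(self.ko_samples) < 2:
            raise ValueError("need >= 2 samples per group for testing")

    @property
    def wt_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "WT"]

    @property
    def ko_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "KO"]


def call_escapees(
    wt_percent: pd.DataFrame, threshold_percent: float = DEFAULT_ESCAPEE_THRESHOLD
) -> pd.Series:
    """Escapee flag per gene: percent >= threshold in *every* WT sample.

    ``wt_percent`` is a gene x WT-sample matrix; genes with any NaN are not
    evaluated (returned NaN -> excluded upstream).
    """
    complete = wt_percent.notna().all(axis=1)
    flags = pd.Series(np.nan, index=wt_percent.index, dtype=object)
    flags[complete] = (wt_percent[complete] >= threshold_percent).all(axis=1)
    return flags


def call_candidates(
    wt_percent: pd.DataFrame,
    ko_percent: pd.DataFrame,
    delta: float = DEFAULT_DELTA,
    reference: str = "wt_mean",
) -> pd.Series:
    """Consistent-increase flag: every KO line >= WT reference + delta points.

    ``reference``: "wt_mean" (default) compares each KO line against the WT
    mean; "ko_mean" instead requires the KO *mean* to exceed WT mean + delta.
    Only genes informative in all WT and all KO samples are evaluated.
    """
    idx = wt_percent.index.intersection(ko_percent.index)
    wt_mean = wt_percent.loc[idx].mean(axis=1)
    if reference == "wt_mean":
        flag = (ko_percent.loc[idx].ge(wt_mean + delta, axis=0)).all(axis=1)
    elif reference == "ko_mean":
        flag = ko_percent.loc[idx].mean(axis=1) >= wt_mean + delta
    else:
        raise ValueError(f"unknown reference {reference!r}")
    complete = wt_percent.loc[idx].notna().all(axis=1) & ko_percent.loc[idx].notna().all(axis=1)
    return flag & complete


def welch_test(wt_values: np.ndarray, ko_values: np.ndarray) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Degenerate input (zero variance in both groups) returns p = 1 for equal
    means and p = 0 for different means.
    """
    a = np.asarray(wt_values, dtype=float)
    b = np.asarray(ko_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def bh_adjust(p_values: np.ndarray, fdr: float = DEFAULT_FDR) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags (q <= fdr)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q <= fdr


def nb_differential(
    scaled_counts: pd.DataFrame,
    design: SampleDesign,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
    dispersion: str = "common",
) -> pd.DataFrame:
    """Per-gene two-group negative-binomial Wald test on paternal-scaled counts.

    log2FC = log2((mean_KO + c) / (mean_WT + c)) with pseudocount c.  The
    Wald statistic compares log(mean + c) between groups with a delta-method
    standard error from the NB variance mu + alpha mu^2.  The dispersion
    alpha is method-of-moments, floored at 1e-8; by default one *common*
    alpha is pooled across genes (genewise moment estimates at n = 4 vs 3
    are too noisy to be useful and make the test conservative);
    ``dispersion="per-gene"`` uses the genewise estimates instead.

    Genes that are all-zero in both groups are excluded.  Returns a frame
    indexed by gene with columns base_mean_wt, base_mean_ko, log2fc, p_value.
    """
    if dispersion not in ("common", "per-gene"):
        raise ValueError(f"unknown dispersion mode {dispersion!r}")
    wt = scaled_counts[design.wt_samples].to_numpy(dtype=float)
    ko = scaled_counts[design.ko_samples].to_numpy(dtype=float)
    keep = ~((wt.sum(axis=1) == 0) & (ko.sum(axis=1) == 0))
    wt, ko = wt[keep], ko[keep]
    index = scaled_counts.index[keep]
    n_wt, n_ko = wt.shape[1], ko.shape[1]

    m_wt, m_ko = wt.mean(axis=1), ko.mean(axis=1)
    v_wt = wt.var(axis=1, ddof=1)
    v_ko = ko.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_wt = (v_wt - m_wt) / np.maximum(m_wt, 1e-300) ** 2
        a_ko = (v_ko - m_ko) / np.maximum(m_ko, 1e-300) ** 2
    per_gene = ((n_wt - 1) * a_wt + (n_ko - 1) * a_ko) / (n_wt + n_ko - 2)
    if dispersion == "common":
        usable = np.isfinite(per_gene) & (np.minimum(m_wt, m_ko) > 0)
        alpha = np.full(
            per_gene.shape,
            max(float(per_gene[usable].mean()) if usable.any() else 0.0, 1e-8),
        )
    else:
        alpha = np.maximum(per_gene, 1e-8)

    c = pseudocount
    log2fc = np.log2((m_ko + c) / (m_wt + c))
    var_wt = (m_wt + alpha * m_wt**2) / n_wt / (m_wt + c) ** 2
    var_ko = (m_ko + alpha * m_ko**2) / n_ko / (m_ko + c) ** 2
    se = np.sqrt(var_wt + var_ko)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(m_ko + c) - np.log(m_wt + c)) / se
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return pd.DataFrame(
        {
            "base_mean_wt": m_wt,
            "base_mean_ko": m_ko,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=index,
    )


def finalize_status(
    is_escapee: pd.Series,
    is_candidate: pd.Series,
    significant: pd.Series,
    log2fc: pd.Series,
) -> pd.Series:
    """Resolve per-gene status from the cascade flags.

    derepressed_up    = candidate & significant & log2FC > 0
    derepressed_down  = candidate & significant & log2FC <= 0
    escapee           = escapee flag, if not derepressed
    silenced          = everything else
    """
    idx = is_candidate.index
    status = pd.Series(STATUS_SILENCED, index=idx, dtype=object)
    esc = is_escapee.reindex(idx).fillna(False).astype(bool)
    status[esc] = STATUS_ESCAPEE
    dere = is_candidate.astype(bool) & significant.reindex(idx).fillna(False).astype(bool)
    lfc = log2fc.reindex(idx)
    status[dere & (lfc > 0)] = STATUS_UP
    status[dere & (lfc <= 0)] = STATUS_DOWN
    return status


@dataclass
class CascadeResult:
    """Full classification table plus the cascade's stage counts."""

    table: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)


def classify_genes(
    wt_percent: pd.DataFrame,
    ko_percent: pd.DataFrame,
    scaled_counts: pd.DataFrame,
    design: SampleDesign,
    escapee_threshold: float = DEFAULT_ESCAPEE_THRESHOLD,
    delta: float = DEFAULT_DELTA,
    fdr: float = DEFAULT_FDR,
    bh_family: str = "candidates",
    dispersion: str = "common",
) -> CascadeResult:
    """Run the full escapee/derepression cascade on the common gene set.

    ``bh_family`` chooses the multiple-testing family: "candidates"
    (default) corrects over the consistent-increase genes only; "all"
    corrects over every common-set gene.
    """
    common = wt_percent.dropna().index.intersection(ko_percent.dropna().index)
    common = common.sort_values()
    wt = wt_percent.loc[common]
    ko = ko_percent.loc[common]

    is_escapee = call_escapees(wt, escapee_threshold).astype(bool)
    is_candidate = call_candidates(wt, ko, delta)

    pvals = pd.Series(
        [welch_test(wt.loc[g].to_numpy(), ko.loc[g].to_numpy()) for g in common],
        index=common,
        name="p_value",
    )
    qvals = pd.Series(np.nan, index=common, name="q_value")
    significant = pd.Series(False, index=common)
    family = common[is_candidate] if bh_family == "candidates" else common
    if len(family):
        q, sig = bh_adjust(pvals.loc[family].to_numpy(), fdr)
        qvals.loc[family] = q
        significant.loc[family] = sig

    nb = nb_differential(
        scaled_counts.reindex(common).dropna(), design, dispersion=dispersion
    )
    log2fc = nb["log2fc"].reindex(common)

    status = finalize_status(is_escapee, is_candidate, significant, log2fc)

    table = pd.DataFrame(
        {
            "wt_mean_percent": wt.mean(axis=1),
            "ko_mean_percent": ko.mean(axis=1),
            "delta_percent": ko.mean(axis=1) - wt.mean(axis=1),
            "is_escapee": is_escapee,
            "is_candidate": is_candidate,
            "p_value": pvals,
            "q_value": qvals,
            "significant": significant,
            "log2fc_paternal": log2fc,
            "status": status,
        }
    )
    counts = {
        "n_common_informative": int(len(common)),
        "n_escapees": int(is_escapee.sum()),
        "n_ko_ge_escapee_threshold": int(
            (ko >= escapee_threshold).all(axis=1).sum()
        ),
        "n_candidates": int(is_candidate.sum()),
        "n_significant": int((is_candidate & significant).sum()),
        "n_derepressed_up": int((status == STATUS_UP).sum()),
        "n_derepressed_down": int((status == STATUS_DOWN).sum()),
    }
    return CascadeResult(table=table, counts=counts)
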