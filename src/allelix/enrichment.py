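"""Quintile partitioning, enrichment statistics and evolutionary strata.

Genes are ranked by WT percent paternal-X expression and split into k
near-equal groups (quintiles by default); the distribution of derepressed
genes across the groups is tested with Fisher's exact test on the 2 x k
contingency table — exact network enumeration for small tables, a
seeded Monte-Carlo tail estimate otherwise.  Expression-level comparisons
between derepressed and non-derepressed genes use the Mann-Whitney U test,
and WT-vs-KO paternal percentages are summarized by Pearson correlation.
Evolutionary-stratum assignment places each gene by its human-X start
coordinate within published stratum boundary intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_FISHER_MAX_TOTAL = 30
DEFAULT_MC_DRAWS = 100_000


# ---------------------------------------------------------------------------
# Quintiles
# ---------------------------------------------------------------------------

def quintile_partition(wt_percents: pd.Series, k: int = 5) -> pd.DataFrame:
    """Rank genes by WT percent (ascending) and split into k groups.

    Ties are broken by gene_id so the partition is deterministic.  Group 1
    holds the lowest percents.  When n is not divisible by k the larger
    groups come first: n = 338, k = 5 gives sizes [68, 68, 68, 67, 67].

    Returns a frame with columns gene_id, wt_percent, rank (1-based),
    quintile (1..k).
    """
    if wt_percents.isna().any():
        raise ValueError("undefined percents in quintile input")
    n = len(wt_percents)
    if n < k:
        raise ValueError(f"cannot split {n} genes into {k} groups")
    order = sorted(wt_percents.items(), key=lambda kv: (kv[1], kv[0]))
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    rows = []
    rank = 0
    for q, size in enumerate(sizes, start=1):
        for _ in range(size):
            gene, pct = order[rank]
            rank += 1
            rows.append((gene, float(pct), rank, q))
    return pd.DataFrame(rows, columns=["gene_id", "wt_percent", "rank", "quintile"])


def quintile_table(
    assignments: pd.DataFrame, derepressed: pd.Series
) -> pd.DataFrame:
    """2 x k contingency: derepressed / not per quintile, plus percent ranges."""
    df = assignments.copy()
    flags = derepressed.reindex(df["gene_id"])
    if flags.isna().any():
        missing = df["gene_id"][flags.isna().to_numpy()].tolist()
        raise ValueError(f"derepression flag missing for genes: {missing[:5]}")
    df["derepressed"] = flags.to_numpy(dtype=bool)
    out = df.groupby("quintile").agg(
        n_genes=("gene_id", "size"),
        n_derepressed=("derepressed", "sum"),
        min_percent=("wt_percent", "min"),
        max_percent=("wt_percent", "max"),
    )
    out["n_other"] = out["n_genes"] - out["n_derepressed"]
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test on a 2 x k table
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a 2 x k table given its margins."""
    lg = math.lgamma
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    num = sum(lg(x + 1) for x in row) + sum(lg(x + 1) for x in col) - lg(n + 1)
    den = sum(lg(x + 1) for x in table.ravel())
    return num - den


def fisher_exact_2xk(
    table: np.ndarray,
    method: str = "auto",
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 0,
) -> float:
    """Fisher's exact test p-value for a 2 x k contingency table.

    The p-value is the total probability, under fixed margins, of tables no
    more probable than the observed one.  ``method``: "exact" enumerates the
    network of tables (feasible for small totals), "mc" estimates the tail
    by resampling tables from the fixed-margins null with a seeded
    generator, "auto" picks exact for totals <= 30 (or 2 x 2) and MC
    otherwise.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if (t.sum(axis=0) == 0).any():
        raise ValueError("a column (quintile) has zero genes")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t)[1])
    if method == "auto":
        method = "exact" if t.sum() <= EXACT_FISHER_MAX_TOTAL else "mc"
    if method == "exact":
        return _fisher_exact_enumerate(t)
    if method == "mc":
        return _fisher_mc(t, n_draws=n_draws, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def _fisher_exact_enumerate(t: np.ndarray) -> float:
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    obs_logp = _log_table_prob(t)
    cutoff = obs_logp + 1e-9  # tolerate float round-off at ties
    k = t.shape[1]
    total_a = int(row[0])
    acc = 0.0

    def recurse(j: int, remaining: int, cells: list[int]) -> None:
        nonlocal acc
        if j == k - 1:
            if remaining <= col[j]:
                cand = np.array([cells + [remaining],
                                 list(col[: k - 1] - np.array(cells)) + [col[j] - remaining]])
                lp = _log_table_prob(cand)
                if lp <= cutoff:
                    acc += math.exp(lp)
            return
        hi = min(int(col[j]), remaining)
        for a in range(hi + 1):
            recurse(j + 1, remaining - a, cells + [a])

    recurse(0, total_a, [])
    return min(acc, 1.0)


def _fisher_mc(t: np.ndarray, n_draws: int, seed: int) -> float:
    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    col = t.sum(axis=0)
    row = t.sum(axis=1)
    n = int(t.sum())
    k = t.shape[1]
    cutoff = _log_table_prob(t) + 1e-9
    # Sample tables from the fixed-margins null column by column: the count
    # of "derepressed" genes landing in column j is hypergeometric given
    # what remains after columns < j.  Equivalent to permuting gene labels.
    a = np.empty((n_draws, k), dtype=np.int64)
    good = np.full(n_draws, int(row[0]), dtype=np.int64)
    total = n
    for j in range(k):
        a[:, j] = rng.hypergeometric(good, total - good, int(col[j]))
        good -= a[:, j]
        total -= int(col[j])
    cells = np.concatenate([a, col[None, :] - a], axis=1)
    # log prob given margins (margin terms are constant across draws)
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - math.lgamma(n + 1)
    logp = const - gammaln(cells + 1.0).sum(axis=1)
    hits = int((logp <= cutoff).sum())
    return (hits + 1) / (n_draws + 1)


def quintile_enrichment(
    assignments: pd.DataFrame,
    derepressed: pd.Series,
    method: str = "mc",
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 0,
    quintile_vs_rest: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Contingency table and Fisher p for derepressed genes across quintiles.

    Default is the full 2 x k test; ``quintile_vs_rest=q`` collapses to a
    2 x 2 test of quintile q against the others.
    """
    counts = quintile_table(assignments, derepressed)
    if quintile_vs_rest is not None:
        q = quintile_vs_rest
        inq = counts.loc[q]
        rest = counts.drop(index=q).sum()
        t = np.array(
            [[inq["n_derepressed"], rest["n_derepressed"]],
             [inq["n_other"], rest["n_other"]]],
            dtype=np.int64,
        )
    else:
        t = counts[["n_derepressed", "n_other"]].to_numpy(dtype=np.int64).T
    p = fisher_exact_2xk(t, method=method, n_draws=n_draws, seed=seed)
    return counts, p


# ---------------------------------------------------------------------------
# Rank and correlation statistics
# ---------------------------------------------------------------------------

def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for group a, p-value).

    Exact null enumeration when both groups are <= 20 and tie-free;
    otherwise the normal approximation with tie correction.  All values
    identical across both groups gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wt_ko_correlation(
    wt_mean_percents: pd.Series, ko_mean_percents: pd.Series
) -> tuple[float, int]:
    """Pearson r between paired WT and KO gene means; (NaN, n) if degenerate."""
    df = pd.concat(
        {"wt": wt_mean_percents, "ko": ko_mean_percents}, axis=1, join="inner"
    ).dropna()
    n = len(df)
    if n < 2 or df["wt"].std() == 0 or df["ko"].std() == 0:
        return float("nan"), n
    r = float(stats.pearsonr(df["wt"], df["ko"]).statistic)
    return r, n


# ---------------------------------------------------------------------------
# Evolutionary strata
# ---------------------------------------------------------------------------

@dataclass
class StratumBoundaries:
    """Ordered, non-overlapping half-open intervals on the human X."""

    intervals: list[tuple[str, int, int]]  # (name, start, end)

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda x: x[1])
        for (n1, s1, e1), (n2, s2, e2) in zip(iv, iv[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping strata {n1} and {n2}")
        for n, s, e in iv:
            if s >= e:
                raise ValueError(f"empty stratum interval {n}")
        self.intervals = iv

    def assign(self, human_start: int | None) -> str | None:
        """Stratum containing ``human_start`` (half-open); None if outside all."""
        if human_start is None:
            return None
        for name, s, e in self.intervals:
            if s <= human_start < e:
                return name
        return None


def assign_strata(genes, boundaries: StratumBoundaries) -> pd.Series:
    """Stratum per gene from its ``human_start``; None when unmapped/outside."""
    return pd.Series(
        {g.gene_id: boundaries.assign(g.human_start) for g in genes}, dtype=object
    )
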