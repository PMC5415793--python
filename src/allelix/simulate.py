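"""Synthetic F1-hybrid allelic RNA-seq datasets with known ground truth.

The generator emulates the study design the pipeline targets: a polymorphic
X chromosome assayed in 4 wild-type and 3 knockout lines, ~8 informative
SNPs per gene, most genes expressing 0-10% from the paternal (inactive) X,
escapees at >= 10%, and a derepressed class whose paternal fraction shifts
upward in the knockout.

Sampling model, per gene g and sample s:

* class ~ categorical(class_fractions); true WT paternal fraction uniform
  in the class's range; KO fraction = WT fraction (+ ko_shift/100 for the
  derepressed class).
* total count ~ NegativeBinomial(mean = total_mean x uniform gene factor,
  dispersion alpha); the KO total for derepressed genes is inflated so the
  *maternal* output stays constant while the paternal allele gains reads
  (derepression adds transcripts; it does not reapportion them).
* allelic coverage = Binomial(total, allelic_fraction), split across the
  gene's SNPs by a symmetric Dirichlet-multinomial (some SNPs fall below
  the 10X filter on purpose); paternal reads per SNP ~
  BetaBinomial(coverage, f, rho) — rho = 0 recovers pure binomial noise.

Fixed seed implies byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    write_allelic_counts,
    write_bed12,
    write_signal_track,
    write_snp_catalog,
    write_total_counts,
)
from .types import GeneModel, SignalTrack, SnpSite

CLASS_SILENCED = "silenced"
CLASS_ESCAPEE = "escapee"
CLASS_DEREPRESSED = "derepressed"

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters; defaults mirror the emulated experiment."""

    n_wt: int = 4
    n_ko: int = 3
    n_genes: int = 340
    snps_per_gene_mean: float = 8.0           # Poisson, floored at 1
    class_fractions: dict = field(default_factory=lambda: {
        CLASS_SILENCED: 0.76, CLASS_ESCAPEE: 0.05, CLASS_DEREPRESSED: 0.19,
    })
    wt_percent_ranges: dict = field(default_factory=lambda: {
        CLASS_SILENCED: (0.0, 3.0),           # bulk of the inactive X
        CLASS_DEREPRESSED: (3.0, 6.0),        # the susceptible stratum
        CLASS_ESCAPEE: (10.0, 30.0),
    })
    ko_shift: float = 20.0                    # percentage points, derepressed only
    total_mean: float = 500.0                 # NB mean of per-gene totals
    total_dispersion: float = 0.05            # NB alpha (var = mu + alpha mu^2)
    allelic_fraction: float = 0.6             # share of a gene's reads over SNPs
    dirichlet_alpha: float = 5.0              # SNP coverage concentration
    rho: float = 0.01                         # beta-binomial overdispersion
    chrom: str = "chrX"
    gene_spacing: int = 20_000
    gene_length_range: tuple = (2_000, 10_000)
    seed: int = 1

    def validate(self) -> None:
        fr = self.class_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for cls, (lo, hi) in self.wt_percent_ranges.items():
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"bad percent range for {cls}: ({lo}, {hi})")
            shift = self.ko_shift if cls == CLASS_DEREPRESSED else 0.0
            if hi + shift > 100:
                raise ValueError(
                    f"ko_shift pushes {cls} fraction above 100% ({hi} + {shift})"
                )
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.allelic_fraction <= 1:
            raise ValueError("allelic_fraction must be in (0, 1]")
        if self.n_wt < 2 or self.n_ko < 2:
            raise ValueError("need >= 2 samples per group")

    @property
    def wt_samples(self) -> list[str]:
        return [f"WT{i+1}" for i in range(self.n_wt)]

    @property
    def ko_samples(self) -> list[str]:
        return [f"KO{i+1}" for i in range(self.n_ko)]


@dataclass
class SimDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimConfig
    snps: list[SnpSite]
    genes: list[GeneModel]
    snp_to_gene: pd.DataFrame        # snp_id, gene_id
    allelic_counts: pd.DataFrame     # sample_id, snp_id, maternal, paternal
    total_counts: pd.DataFrame       # gene x sample
    truth: pd.DataFrame              # per-gene class + true fractions

    def design_groups(self) -> dict[str, str]:
        return {
            **{s: "WT" for s in self.config.wt_samples},
            **{s: "KO" for s in self.config.ko_samples},
        }


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, f: float,
                   rho: float) -> np.ndarray:
    """Paternal reads out of n at true fraction f with overdispersion rho."""
    n = np.asarray(n, dtype=np.int64)
    if f <= 0:
        return np.zeros_like(n)
    if f >= 1:
        return n.copy()
    if rho == 0:
        return rng.binomial(n, f)
    conc = (1.0 - rho) / rho
    p = rng.beta(f * conc, (1.0 - f) * conc, size=n.shape)
    return rng.binomial(n, p)


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Draw a complete allelic dataset (catalog, counts, models, truth)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    samples = cfg.wt_samples + cfg.ko_samples
    is_ko = np.array([s in cfg.ko_samples for s in samples])

    genes: list[GeneModel] = []
    snps: list[SnpSite] = []
    map_rows = []
    truth_rows = []
    count_rows = []
    totals = np.zeros((cfg.n_genes, len(samples)))

    pos_cursor = cfg.gene_spacing
    width = len(str(cfg.n_genes))
    for gi in range(cfg.n_genes):
        gene_id = f"gene{gi+1:0{width}d}"
        length = int(rng.integers(*cfg.gene_length_range))
        start = pos_cursor
        end = start + length
        pos_cursor = end + cfg.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id, cfg.chrom, strand, start, end))

        cls = classes[rng.choice(len(classes), p=probs)]
        lo, hi = cfg.wt_percent_ranges[cls]
        wt_f = rng.uniform(lo, hi) / 100.0
        ko_f = wt_f + (cfg.ko_shift / 100.0 if cls == CLASS_DEREPRESSED else 0.0)

        n_snps = max(1, int(rng.poisson(cfg.snps_per_gene_mean)))
        offsets = np.sort(
            rng.choice(length, size=min(n_snps, length), replace=False)
        )
        gene_snps = []
        for k, off in enumerate(offsets):
            mat, pat = rng.choice(4, size=2, replace=False)
            snp_id = f"{gene_id}_snp{k+1}"
            gene_snps.append(snp_id)
            snps.append(
                SnpSite(cfg.chrom, start + int(off) + 1, _BASES[mat], _BASES[pat],
                        snp_id)
            )
            map_rows.append((snp_id, gene_id))

        gene_factor = rng.uniform(0.5, 2.0)
        mu_wt = cfg.total_mean * gene_factor
        # derepression adds paternal transcripts on top of a constant
        # maternal output: total KO mean scales by (1 - f_wt) / (1 - f_ko)
        mu_ko = mu_wt * (1.0 - wt_f) / (1.0 - ko_f)
        alpha = cfg.total_dispersion
        for si, s in enumerate(samples):
            mu = mu_ko if is_ko[si] else mu_wt
            if alpha > 0:
                r = 1.0 / alpha
                tot = int(rng.negative_binomial(r, r / (r + mu)))
            else:
                tot = int(rng.poisson(mu))
            totals[gi, si] = tot
            f = ko_f if is_ko[si] else wt_f
            allelic_cov = int(rng.binomial(tot, cfg.allelic_fraction))
            w = rng.dirichlet(np.full(len(gene_snps), cfg.dirichlet_alpha))
            per_snp = rng.multinomial(allelic_cov, w)
            pat_reads = _beta_binomial(rng, per_snp, f, cfg.rho)
            for snp_id, cov, patr in zip(gene_snps, per_snp, pat_reads):
                count_rows.append((s, snp_id, int(cov - patr), int(patr)))

        truth_rows.append(
            (gene_id, cls, wt_f, ko_f, len(gene_snps), mu_wt, mu_ko)
        )

    dataset = SimDataset(
        config=cfg,
        snps=snps,
        genes=genes,
        snp_to_gene=pd.DataFrame(map_rows, columns=["snp_id", "gene_id"]),
        allelic_counts=pd.DataFrame(
            count_rows,
            columns=["sample_id", "snp_id", "maternal_count", "paternal_count"],
        ),
        total_counts=pd.DataFrame(
            totals.astype(np.int64),
            index=[g.gene_id for g in genes],
            columns=samples,
        ).rename_axis("gene_id"),
        truth=pd.DataFrame(
            truth_rows,
            columns=["gene_id", "true_class", "true_wt_fraction",
                     "true_ko_fraction", "n_snps", "mu_wt", "mu_ko"],
        ).set_index("gene_id"),
    )
    return dataset


def simulate_signal_tracks(
    dataset: SimDataset,
    amplitudes: dict[str, float] | None = None,
    peak_sd: float = 1_000.0,
    background: float = 0.1,
    seed: int | None = None,
) -> SignalTrack:
    """Synthesize a 50-bp inactive-X signal track with TSS-peaked signal.

    Peak amplitude at each gene's TSS is set by its true class
    (``amplitudes`` maps class to amplitude; default gives the derepressed
    class twice the silenced amplitude, mimicking open/active chromatin at
    susceptible genes).  Deterministic given the seed.
    """
    cfg = dataset.config
    if amplitudes is None:
        amplitudes = {CLASS_SILENCED: 1.0, CLASS_DEREPRESSED: 2.0,
                      CLASS_ESCAPEE: 0.5}
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    span = max(g.end for g in dataset.genes) + 20_000
    nbins = span // 50 + 1
    grid = np.arange(nbins) * 50.0 + 25.0
    sig = np.full(nbins, background)
    for g in dataset.genes:
        amp = amplitudes[dataset.truth.loc[g.gene_id, "true_class"]]
        if amp == 0:
            continue
        lo = max(0, (g.tss - 4 * int(peak_sd)) // 50)
        hi = min(nbins, (g.tss + 4 * int(peak_sd)) // 50 + 1)
        d = grid[lo:hi] - g.tss
        sig[lo:hi] += amp * np.exp(-0.5 * (d / peak_sd) ** 2)
    noise = rng.normal(0, 0.01, size=nbins)
    sig = np.maximum(sig + noise, 0.0)
    values = {int(i) * 50: float(v) for i, v in enumerate(sig) if v != 0.0}
    return SignalTrack(chrom=cfg.chrom, bin_width=50, values=values)


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp_catalog": outdir / "snps.vcf",
        "gene_models": outdir / "genes.bed",
        "allelic_counts": outdir / "allelic_counts.tsv",
        "total_counts": outdir / "total_counts.tsv",
        "snp_to_gene": outdir / "snp_to_gene.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_snp_catalog(dataset.snps, paths["snp_catalog"], format="vcf")
    write_bed12(dataset.genes, paths["gene_models"])
    write_allelic_counts(dataset.allelic_counts, paths["allelic_counts"])
    write_total_counts(dataset.total_counts, paths["total_counts"])
    dataset.snp_to_gene.to_csv(paths["snp_to_gene"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t")
    return paths


def evaluate_calls(
    truth: pd.DataFrame,
    classification: pd.DataFrame,
    min_true_escapee_fraction: float = 0.15,
) -> dict[str, float]:
    """Score a classification table against the generator's ground truth.

    Returns derepression sensitivity (true derepressed genes called
    derepressed_up), the false-derepression rate (true silenced genes called
    derepressed in either direction), and escapee recovery restricted to
    true escapees at or above ``min_true_escapee_fraction``.
    """
    t = classification.join(truth, how="inner")
    out: dict[str, float] = {}
    dere = t["true_class"] == CLASS_DEREPRESSED
    if dere.any():
        out["derepression_sensitivity"] = float(
            (t.loc[dere, "status"] == "derepressed_up").mean()
        )
        out["n_true_derepressed"] = int(dere.sum())
    sil = t["true_class"] == CLASS_SILENCED
    if sil.any():
        out["false_derepression_rate"] = float(
            t.loc[sil, "status"].isin(["derepressed_up", "derepressed_down"]).mean()
        )
        out["n_true_silenced"] = int(sil.sum())
    esc = (t["true_class"] == CLASS_ESCAPEE) & (
        t["true_wt_fraction"] >= min_true_escapee_fraction
    )
    if esc.any():
        out["escapee_recovery"] = float(t.loc[esc, "is_escapee"].mean())
        out["n_true_escapees"] = int(esc.sum())
    return out


def deep_coverage_config(**overrides) -> SimConfig:
    """A high-coverage, low-noise preset for consistency checks."""
    base = SimConfig(
        total_mean=40_000.0, total_dispersion=0.0, allelic_fraction=0.5,
        rho=0.0, n_genes=50,
    )
    return replace(base, **overrides)
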