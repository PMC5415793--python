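# Methods

## Model and procedure

The unit of observation is a parental read-count pair at a
strain-distinguishing SNP: in an F1 hybrid whose maternal X is active and
whose paternal X is inactive (imprinted X-inactivation), the fraction of
SNP-overlapping reads carrying the paternal allele measures leakage from
the silenced chromosome.  The pipeline assumes counting is done upstream
(reads mapped allele-specifically to two in-silico parental genomes built
by SNP substitution; `io_formats.apply_snps_to_fasta` provides the
substitution step) and takes the counts as given — no read-level modeling,
no mapping-bias correction beyond the orientation-swap hook for
reciprocal-cross designs (`read_snp_catalog(..., swap_alleles=True)`).

Per SNP, percent paternal = 100·p/(m+p), undefined (NaN, never an error)
at zero coverage.  Per gene and sample, the statistic is the **unweighted
mean** over SNPs with total coverage ≥ `min_coverage`; weighting by
coverage is available but off by default, since the per-SNP percentages
are treated as exchangeable estimates of one underlying gene fraction.
Genes must be informative (≥ 1 qualifying SNP) in *every* sample of a
comparison to enter it; per-sample informative sets are kept alongside.

The classification cascade and its defaults:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 10 reads (5 = sensitivity preset) | per-SNP total allelic coverage for informativeness |
| `escapee_threshold` | 10 % | minimum paternal share in every WT line |
| `delta` | 10 percentage points | consistent KO increase over the WT mean |
| `fdr` | 0.1 | Benjamini–Hochberg level over the candidate family |
| log2FC pseudocount | 0.5 | stabilizes fold changes of zero-containing genes |

Thresholds are inclusive (≥), and `delta` is absolute percentage points,
not a relative 10%: both cutoffs live on the same percent-of-total scale.
"Consistent increase" means every KO line clears WT mean + δ; a variant
comparing the KO mean instead is exposed via `reference="ko_mean"`.
BH correction defaults to the candidate family only — the hypothesis
being corrected is "this consistently increased gene is significant" —
with `bh_family="all"` for genome-wide correction.

## The differential test on paternal-scaled counts

A relative shift in the paternal share can come from paternal gain or
maternal loss.  To separate these, library-normalized total gene counts
(median-of-ratios size factors) are multiplied by the paternal fraction
and rounded, giving integer paternal-scaled counts; a two-group
negative-binomial Wald test then compares WT and KO.  The statistic is
log(mean_KO + c) − log(mean_WT + c) with a delta-method standard error
from the NB variance μ + αμ².  The dispersion α is method-of-moments,
floored at 1e-8.  By default a single **common** α is pooled across genes:
with 4 + 3 samples, genewise moment estimates are so noisy that their
positive part systematically inflates the standard error, and measured
type-I error under a Poisson null drops to ~0.037; the pooled estimator
restores ~0.05 while remaining method-of-moments.  `dispersion="per-gene"`
retains the genewise estimator for data with strong gene-specific
overdispersion.  This test is deliberately transparent rather than a
reimplementation of shrinkage-based packages: the scientific content here
is the paternal-scaling construction and the sign of the fold change, not
dispersion shrinkage.

## Enrichment statistics

Quintile partition: stable ascending sort by WT percent, ties broken by
gene identifier so the partition is deterministic; when n is not divisible
by k the larger groups take the lowest ranks (338 → 68, 68, 68, 67, 67).
Fisher's exact test on the 2×k table sums the null probability of all
margin-fixed tables no more probable than the observed one; exact network
enumeration is used for totals ≤ 30 (or any 2×2, via scipy), and a
Monte-Carlo estimate — tables sampled by sequential hypergeometric column
draws, 10⁵ draws, seeded, with the (hits+1)/(draws+1) estimator —
otherwise, since exact 2×k enumeration is exponential in the margins.
Mann–Whitney U uses exact enumeration for tie-free groups of ≤ 20 and the
tie-corrected normal approximation otherwise.  WT–KO association is plain
Pearson correlation of gene-level means.  Evolutionary strata are assigned
by locating each gene's human-X start coordinate in half-open,
non-overlapping stratum intervals supplied by the caller.

## Chromatin metaprofiles

Signal is carried on a fixed 50-bp grid (`SignalTrack`); bedGraph input is
rebinned on load by overlap-weighted averaging with gaps treated as zero —
the tracks are peak-call derived, so absence means no signal, not missing
data.  Off-grid coordinates (negative, or beyond a declared contig length)
are missing.  TSS mode produces exactly 40 sections of 500 bp over
[−10 kb, +10 kb) around the TSS, half-open; gene-body mode 40 even
sections from TSS to TTS with fractional boundaries for genes shorter than
2 kb.  Sections are overlap-weighted means of native bins, which makes
rebinning conserve total signal over covered spans.  Minus-strand genes
are orientation-flipped in both modes (section 1 is always upstream/at the
TSS); the flip can be bypassed by pre-reversing labels if unflipped
profiles are wanted.  Sections with no on-grid native bin are NaN and are
excluded from per-gene and per-class means, distinguishing absent data
from absent signal.  Peak-level allelic fractions pool reads over the SNPs
inside the half-open peak interval.

## Synthetic data generator

The generator emulates the targeted study design, not arbitrary data:
4 WT + 3 KO lines; 340 genes; SNPs per gene Poisson(8) floored at 1; class
mix 76% silenced / 5% escapee / 19% derepressed; WT paternal fractions
uniform in 0–3% (silenced), 3–6% (derepressed — the susceptible stratum),
10–30% (escapee); KO adds +20 points to derepressed genes only.  Totals
are NB(mean 500 × gene factor, α 0.05); derepression *adds* paternal
transcripts, so KO totals scale by (1−f_WT)/(1−f_KO) to keep maternal
output constant.  Allelic coverage is a binomial thinning of the total
(fraction 0.6) split across SNPs by a symmetric Dirichlet-multinomial
(α = 5); these two values are calibrated so the informative-SNP yield
matches the emulated design — about eight qualifying SNPs per gene at the
10X filter — while still leaving some SNPs below threshold to exercise the
filter.  Paternal reads are beta-binomial with ρ = 0.01 (ρ = 0 recovers
binomial, used by the exact-limit tests).  Signal tracks place a Gaussian
TSS peak (σ = 1 kb) whose amplitude depends on gene class, over a small
constant background with additive noise.  All sampling flows from one
`numpy` generator, so a fixed seed yields byte-identical output files.

What the generator does **not** emulate: mapping bias and its SNP-level
correlation structure, isoform-specific allelic ratios, SNPs shared by
overlapping genes, contamination between lines, and any dependence of
dispersion on expression level.  Passing recovery tests therefore show the
cascade's thresholds and tests behave as specified under the stated noise
model — not that real libraries are free of those artifacts.

## Numerical choices and degenerate inputs

Zero-coverage SNPs and uninformative genes are NaN, propagated and
filtered explicitly, never silently zero.  Welch's test returns p = 1 for
two zero-variance groups with equal means (p = 0 if means differ).  Genes
all-zero in both groups are excluded from the NB test.  Fisher enumeration
tolerates float round-off at probability ties (1e-9 log-slack).  Quintile
and tie rules are deterministic as described.  `run_pipeline` stamps every
output table with the tool version, a hash of the analytic configuration
(output paths excluded) and the seed.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full design at its
native size (340 genes, 7 samples), the NB null calibration at 2,000 genes
(Monte-Carlo standard error ≈ 0.005 on the rejection rate), the escapee
recovery check on a 400-gene escapee-rich arm (~150 qualifying escapees),
and Monte-Carlo/exact Fisher agreement at 10⁵ draws; everything completes
in well under a minute per stage.

## Known limitations

The per-gene NB Wald test is asymptotic in a regime (n = 4 vs 3) where
asymptotics are generous; its calibration is verified empirically at the
defaults and the common-dispersion choice is part of that calibration.
The published per-line supplementary tables that would allow recomputing
the original study's printed gene counts are not redistributed here; the
recomputation path (`pipeline.cascade_from_tables`) is implemented and
tested on synthetic tables of the same layout, and activates on the real
tables when placed under `data/supplementary/`.
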