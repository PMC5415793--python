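"""Allelic chromatin signal summarization around genes.

Works on 50-bp-binned, library-normalized allelic tracks (ChIP-seq,
DNaseI-seq, CHART-seq).  Two metaprofile modes:

* TSS mode — 40 sections of 500 bp covering [-10 kb, +10 kb) around each
  TSS, each section the (overlap-weighted) mean of its native 50-bp bins.
* gene-body mode — 40 even-length sections from TSS to TTS, regardless of
  gene length.

Minus-strand genes are orientation-flipped so section 1 is always the most
upstream.  Sections with no on-grid native bin are NaN (missing, not zero)
and are excluded from per-gene and per-class means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GeneModel, SignalTrack

logger = logging.getLogger(__name__)

TSS_FLANK = 10_000
TSS_SECTION = 500
GENEBODY_NBINS = 40


@dataclass
class Metaprofile:
    """Per-gene binned signal and its across-gene average."""

    mode: str                 # "tss" | "genebody"
    bin_labels: list          # TSS-relative bp offsets or gene-body fractions
    matrix: pd.DataFrame      # genes x bins, NaN = no data

    @property
    def mean_profile(self) -> pd.Series:
        return self.matrix.mean(axis=0, skipna=True)


def allelic_peak_fraction(
    peak: tuple[str, int, int],
    snp_counts: pd.DataFrame,
    snp_positions: pd.Series,
) -> float:
    """Percent inactive-X signal of a peak from SNP-overlapping reads.

    ``snp_counts`` has columns snp_id, maternal_count (active-X),
    paternal_count (inactive-X); ``snp_positions`` maps snp_id to 1-based
    position on the peak's chromosome.  The fraction pools reads over every
    SNP inside the half-open peak interval; NaN if no SNP-overlapping reads.
    """
    chrom, start, end = peak
    if end <= start:
        raise ValueError(f"bad peak interval [{start},{end})")
    pos = snp_positions.reindex(snp_counts["snp_id"])
    inside = ((pos - 1) >= start) & ((pos - 1) < end)
    sub = snp_counts.loc[inside.to_numpy(dtype=bool)]
    total = int(sub["maternal_count"].sum() + sub["paternal_count"].sum())
    if total == 0:
        return float("nan")
    return 100.0 * float(sub["paternal_count"].sum()) / total


def _section_mean(track: SignalTrack, start: float, end: float) -> float:
    """Overlap-weighted mean of native bins over [start, end); NaN if off-grid."""
    w = track.bin_width
    lo = int(np.floor(start / w)) * w
    acc = 0.0
    covered = 0.0
    b = lo
    while b < end:
        ov = min(end, b + w) - max(start, b)
        if ov > 0:
            v = track.get_bin(b)
            if not np.isnan(v):
                acc += v * ov
                covered += ov
        b += w
    if covered == 0:
        return float("nan")
    return acc / covered


def tss_metaprofile(
    track: SignalTrack,
    genes: list[GeneModel],
    flank: int = TSS_FLANK,
    section: int = TSS_SECTION,
) -> Metaprofile:
    """Average 50-bp bins into ``section``-bp sections over TSS +/- ``flank``.

    The window is [-flank, +flank) in transcription orientation: for a
    minus-strand gene the genomic window is walked in reverse so section 1
    is always ``flank`` bp upstream of the TSS.  Off-grid sections (e.g.
    TSS closer than ``flank`` to the contig start) are NaN.
    """
    if section % track.bin_width:
        raise ValueError("section must be a multiple of the native bin width")
    if (2 * flank) % section:
        raise ValueError("window must tile into whole sections")
    nbins = 2 * flank // section
    offsets = [-flank + i * section for i in range(nbins)]
    rows = {}
    for g in genes:
        if g.chrom != track.chrom:
            logger.warning("gene %s not on track chrom %s", g.gene_id, track.chrom)
            continue
        vals = np.empty(nbins)
        for i, off in enumerate(offsets):
            if g.strand == "+":
                s = g.tss + off
            else:
                s = g.tss - off - section + 1
            vals[i] = _section_mean(track, s, s + section)
        rows[g.gene_id] = vals
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    return Metaprofile(mode="tss", bin_labels=offsets, matrix=matrix)


def genebody_profile(
    track: SignalTrack, genes: list[GeneModel], nbins: int = GENEBODY_NBINS
) -> Metaprofile:
    """Average 50-bp bins into ``nbins`` even sections spanning TSS to TTS.

    Section boundaries are fractional for genes whose length is not a
    multiple of ``nbins`` x 50 bp; each section takes the overlap-weighted
    mean of the native bins it touches.  Orientation follows transcription
    (section 1 at the TSS) unless ``strand`` handling is bypassed by the
    caller reversing labels.
    """
    labels = [(i + 0.5) / nbins for i in range(nbins)]
    rows = {}
    for g in genes:
        if g.length <= 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        if g.chrom != track.chrom:
            logger.warning("gene %s not on track chrom %s", g.gene_id, track.chrom)
            continue
        step = g.length / nbins
        vals = np.empty(nbins)
        for i in range(nbins):
            s = g.start + i * step
            vals[i] = _section_mean(track, s, s + step)
        if g.strand == "-":
            vals = vals[::-1]
        rows[g.gene_id] = vals
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return Metaprofile(mode="genebody", bin_labels=labels, matrix=matrix)


def profile_by_class(
    profile: Metaprofile, status: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean profile per gene class; returns (class x bin frame, class sizes).

    ``status`` maps gene_id to its class label (e.g. derepressed_up /
    silenced / escapee).  Genes without a label raise; empty classes are
    simply absent.  NaN sections are excluded per class and bin.
    """
    labels = status.reindex(profile.matrix.index)
    if labels.isna().any():
        missing = profile.matrix.index[labels.isna()].tolist()
        raise ValueError(f"genes without classification: {missing[:5]}")
    grouped = profile.matrix.groupby(labels).mean()
    sizes = labels.value_counts()
    empty = set(sizes.index[sizes == 0])
    if empty:
        logger.warning("empty classes omitted: %s", sorted(empty))
    return grouped, sizes
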