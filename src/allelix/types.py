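"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
SNP positions are 1-based (VCF dialect).  Gene intervals are 0-based
half-open (BED dialect).  Conversion happens at the file boundary; in-memory
objects always carry their native convention, stated per field below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpSite:
    """A strain-distinguishing SNP on the polymorphic X chromosome.

    ``pos`` is 1-based.  ``maternal_allele`` is the 129/S1 (active-X) base,
    ``paternal_allele`` the JF1/Ms (inactive-X) base.
    """

    chrom: str
    pos: int
    maternal_allele: str
    paternal_allele: str
    snp_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.maternal_allele not in _BASES or self.paternal_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.maternal_allele!r}/{self.paternal_allele!r} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(
                f"maternal and paternal alleles identical at {self.chrom}:{self.pos}"
            )


@dataclass
class GeneModel:
    """Gene span with strand-aware TSS; intervals 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    human_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Library-normalized allelic signal on a fixed 50-bp grid.

    ``values`` maps bin start (a multiple of ``bin_width``) to signal.
    Bins absent from the map are zero (peak-derived tracks: absence means
    no signal).  ``chrom_length``, when known, bounds the valid grid; bins
    outside [0, chrom_length) are treated as missing rather than zero.
    """

    chrom: str
    bin_width: int = 50
    values: dict[int, float] = field(default_factory=dict)
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        for start, v in self.values.items():
            if start % self.bin_width:
                raise ValueError(
                    f"bin start {start} not a multiple of bin_width {self.bin_width}"
                )
            if v < 0:
                raise ValueError(f"negative signal {v} at bin {start}")

    def get_bin(self, start: int) -> float:
        """Signal in the native bin starting at ``start``; NaN when off-grid."""
        if start < 0:
            return np.nan
        if self.chrom_length is not None and start >= self.chrom_length:
            return np.nan
        return self.values.get(start, 0.0)

    def total_signal(self) -> float:
        """Sum of bin value x bin width over recorded bins."""
        return sum(self.values.values()) * self.bin_width
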