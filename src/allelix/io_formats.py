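"""Readers and writers for every external format the pipeline touches.

Formats and conventions
-----------------------
* SNP catalog: VCF 4.x (REF = maternal/129-like allele, ALT = paternal/
  JF1-like allele — a documented input contract, swappable with
  ``swap_alleles=True`` for reciprocal-cross data) or a 5-column TSV.
  Positions 1-based.
* Gene models: BED12 (or a minimal GTF); intervals 0-based half-open.
* Allelic counts and total counts: TSV with header.
* Signal: bedGraph, rebinned onto a 50-bp grid on load.
* In-silico parental genomes: FASTA with catalog alleles substituted in.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import GeneModel, SignalTrack, SnpSite

logger = logging.getLogger(__name__)

SNP_TSV_COLUMNS = ["chrom", "pos", "snp_id", "maternal_allele", "paternal_allele"]
ALLELIC_COUNT_COLUMNS = ["sample_id", "snp_id", "maternal_count", "paternal_count"]

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# SNP catalog
# ---------------------------------------------------------------------------

def _check_duplicates(snps: list[SnpSite]) -> None:
    seen: set[tuple[str, int]] = set()
    dups = []
    for s in snps:
        key = (s.chrom, s.pos)
        if key in seen:
            dups.append(f"{s.chrom}:{s.pos}")
        seen.add(key)
    if dups:
        raise ValueError(f"duplicate SNP positions: {', '.join(sorted(set(dups)))}")


def read_snp_catalog(
    path: str | Path, format: str | None = None, swap_alleles: bool = False
) -> list[SnpSite]:
    """Read the strain SNP catalog from VCF or TSV.

    VCF convention: REF is the maternal (129/S1-like) allele, ALT the
    paternal (JF1/Ms-like) allele.  ``swap_alleles`` flips the orientation
    (reciprocal-cross design).  Non-SNV records are skipped with a warning;
    duplicated (chrom, pos) is an error naming the position.  Output is
    ordered by (chrom, pos).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        snps = _read_snp_vcf(path)
    elif format == "tsv":
        snps = _read_snp_tsv(path)
    else:
        raise ValueError(f"unknown SNP catalog format {format!r}")
    if swap_alleles:
        snps = [
            SnpSite(s.chrom, s.pos, s.paternal_allele, s.maternal_allele, s.snp_id)
            for s in snps
        ]
    snps.sort(key=lambda s: (s.chrom, s.pos))
    _check_duplicates(snps)
    return snps


def _read_snp_vcf(path: Path) -> list[SnpSite]:
    from cyvcf2 import VCF

    snps = []
    for i, rec in enumerate(VCF(str(path))):
        alts = rec.ALT
        if len(rec.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1 or not (
            rec.REF in _BASES and alts[0] in _BASES
        ):
            logger.warning(
                "skipping non-SNV record at %s:%d (REF=%s ALT=%s)",
                rec.CHROM, rec.POS, rec.REF, ",".join(alts),
            )
            continue
        snp_id = rec.ID if rec.ID not in (None, ".") else f"snv_{rec.CHROM}_{rec.POS}"
        snps.append(SnpSite(rec.CHROM, rec.POS, rec.REF, alts[0], snp_id))
    return snps


def _read_snp_tsv(path: Path) -> list[SnpSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    missing = set(SNP_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP TSV missing columns: {sorted(missing)}")
    return [
        SnpSite(r.chrom, int(r.pos), r.maternal_allele, r.paternal_allele, r.snp_id)
        for r in df.itertuples()
    ]


def write_snp_catalog(snps: Sequence[SnpSite], path: str | Path,
                      format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=.,Number=0,Type=Flag,Description="">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in snps:
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.snp_id or '.'}\t"
                    f"{s.maternal_allele}\t{s.paternal_allele}\t.\t.\t.\n"
                )
    else:
        pd.DataFrame(
            [(s.chrom, s.pos, s.snp_id, s.maternal_allele, s.paternal_allele)
             for s in snps],
            columns=SNP_TSV_COLUMNS,
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# In-silico parental genomes
# ---------------------------------------------------------------------------

def apply_snps_to_fasta(
    reference_fasta: str | Path,
    snps: Iterable[SnpSite],
    haplotype: str,
    out_fasta: str | Path,
) -> None:
    """Substitute catalog alleles into a reference to build a parental genome.

    Every output sequence is identical to the input except at SNP positions,
    which carry the requested haplotype's allele; lengths are preserved.  A
    reference base matching neither allele is permitted but logged (strain
    SNPs are called against a third reference strain).  A SNP beyond its
    contig end is an error.
    """
    if haplotype not in ("maternal", "paternal"):
        raise ValueError(f"haplotype must be maternal or paternal, got {haplotype!r}")
    from Bio import SeqIO
    from Bio.Seq import Seq

    by_chrom: dict[str, list[SnpSite]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)

    records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    found = set(r.id for r in records)
    for chrom in by_chrom:
        if chrom not in found:
            raise ValueError(f"SNP contig {chrom!r} absent from reference")
    for rec in records:
        seq = bytearray(str(rec.seq).upper(), "ascii")
        for s in by_chrom.get(rec.id, []):
            if s.pos > len(seq):
                raise ValueError(
                    f"SNP {s.chrom}:{s.pos} beyond contig end ({len(seq)} bp)"
                )
            ref_base = chr(seq[s.pos - 1])
            if ref_base not in (s.maternal_allele, s.paternal_allele):
                logger.info(
                    "reference base %s at %s:%d matches neither allele (%s/%s)",
                    ref_base, s.chrom, s.pos, s.maternal_allele, s.paternal_allele,
                )
            allele = s.maternal_allele if haplotype == "maternal" else s.paternal_allele
            seq[s.pos - 1] = ord(allele)
        rec.seq = Seq(seq.decode("ascii"))
    SeqIO.write(records, str(out_fasta), "fasta")


# ---------------------------------------------------------------------------
# Allelic and total counts
# ---------------------------------------------------------------------------

def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    """Read per-(sample, SNP) maternal/paternal read counts from TSV.

    One row per (sample_id, snp_id); duplicates are an error, as are
    negative or non-integer counts (reported with their row number, where
    row 1 is the first data row).  Missing pairs are simply absent and are
    treated as zero coverage downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str})
    missing = set(ALLELIC_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allelic counts TSV missing columns: {sorted(missing)}")
    for col in ("maternal_count", "paternal_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"invalid {col} at data row {row}: {df[col].iloc[row - 1]!r}")
        df[col] = vals.astype(np.int64)
    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "snp_id"]].apply(tuple, axis=1).tolist()
        raise ValueError(f"duplicate (sample, snp) rows: {pairs[:5]}")
    return df[ALLELIC_COUNT_COLUMNS]


def write_allelic_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[ALLELIC_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_total_counts(path: str | Path) -> pd.DataFrame:
    """Read the gene x sample total read-count matrix (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df.values < 0).any():
        raise ValueError("negative total counts")
    return df


def write_total_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 (default) or GTF; 0-based half-open."""
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if format == "bed":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            exons: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    import re

    spans: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = re.search(r'gene_id "([^"]+)"', f[8])
            if not m:
                continue
            gid = m.group(1)
            start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based closed
            d = spans.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
            d["exons"].append((start, end))
    genes = []
    for gid, d in spans.items():
        exons = _merge_intervals(d["exons"])
        genes.append(
            GeneModel(gid, d["chrom"], d["strand"], exons[0][0], exons[-1][1], exons)
        )
    return genes


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, e in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph signal
# ---------------------------------------------------------------------------

def read_signal_track(
    path: str | Path, bin_width: int = 50, chrom: str | None = None
) -> SignalTrack:
    """Load a bedGraph onto a fixed ``bin_width`` grid.

    Each grid bin receives the coverage-weighted mean of the interval values
    covering it, with uncovered stretches contributing zero (peak-derived
    tracks: absence of signal, not missing data).  Total signal is conserved:
    sum(bin value x bin width) equals sum(interval value x interval length).
    Overlapping intervals or a malformed line raise with the line number.
    """
    acc: dict[int, float] = {}
    seen_chrom: str | None = None
    prev_end = -1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph fields")
            try:
                c, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line") from exc
            if chrom is not None and c != chrom:
                continue
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: bad interval [{start},{end})")
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise ValueError(
                    f"{path}:{ln}: multiple chromosomes in track ({seen_chrom}, {c});"
                    " pass chrom= to select one"
                )
            if start < prev_end:
                raise ValueError(f"{path}:{ln}: overlapping intervals")
            prev_end = end
            for b in range(start // bin_width * bin_width, end, bin_width):
                ov = min(end, b + bin_width) - max(start, b)
                acc[b] = acc.get(b, 0.0) + value * ov / bin_width
    if seen_chrom is None:
        raise ValueError(f"{path}: no intervals read")
    return SignalTrack(chrom=seen_chrom, bin_width=bin_width, values=acc)


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    """Write one bedGraph line per non-zero native bin (sorted by start)."""
    with open(path, "w") as fh:
        for start in sorted(track.values):
            v = track.values[start]
            if v != 0.0:
                fh.write(
                    f"{track.chrom}\t{start}\t{start + track.bin_width}\t{v:.10g}\n"
                )


# ---------------------------------------------------------------------------
# Result / supplementary tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Read a result or supplementary table from XLSX or TSV/CSV."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)
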