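"""Readers and writers for the on-disk formats the pipeline consumes.

Strict about coordinate conventions: BED and bedGraph are 0-based
half-open on disk and in memory; GFF3 is 1-based closed on disk and is
converted to 0-based half-open exactly once, here.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval


class ParseError(ValueError):
    """A malformed record in an input file; the message names the location."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of intervals (0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0), preserving input order."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    GFF3 coordinates are 1-based closed; they are converted to 0-based
    half-open (start-1, end). Only ``gene`` features are kept, one span
    per gene id (first occurrence wins). A gene without a ``+``/``-``
    strand is a parse error.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: fewer than 9 columns")
            if fields[2] != "gene":
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: gene feature without strand"
                )
            attrs = dict(
                item.split("=", 1)
                for item in fields[8].split(";")
                if "=" in item
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"gene_{lineno}"))
            if gene_id in seen:
                continue
            seen.add(gene_id)
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[3]) - 1, int(fields[4]), strand
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            genes.append(GeneModel(gene_id, iv))
    if not genes:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tk27compare\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PFM / PWM
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path, pseudocount: float = 1.0):
    """Read a JASPAR-style position frequency matrix.

    Counts are converted to probabilities with an additive pseudocount
    per cell (avoids -inf log-odds for unseen bases). Returns a
    :class:`~k27compare.motif_analysis.PWM`.
    """
    from .motif_analysis import PWM  # deferred: avoid import cycle

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array(
        [motif.counts[base] for base in "ACGT"], dtype=float
    )  # 4 x w
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ParseError(f"{path}: malformed PFM")
    if np.any(counts < 0):
        raise ParseError(f"{path}: negative count in PFM")
    if np.any(counts.sum(axis=0) == 0):
        raise ParseError(f"{path}: PFM column sums to zero")
    return PWM.from_counts(
        motif.name or Path(path).stem, counts, pseudocount=pseudocount
    )


# ---------------------------------------------------------------------------
# Counts TSV
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples table of counts (TSV, header row, gene-id index).

    Duplicate gene ids and non-numeric cells are errors naming the
    offending row/cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().values)[0]
        raise ParseError(
            f"{path}: non-numeric value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return numeric


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    track,
    path: str | Path,
    bin_size: int = 50,
    scale: float = 1.0,
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write binned tag coverage as a sorted bedGraph (0-based half-open).

    ``scale`` multiplies every value (browser normalization, see
    :func:`~k27compare.normalization.track_scale_factor`). Zero bins are
    omitted.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            pos = track.positions[chrom]
            if len(pos) == 0:
                continue
            limit = (
                chrom_sizes[chrom]
                if chrom_sizes is not None
                else int(pos[-1]) + 1
            )
            n_bins = -(-limit // bin_size)
            counts = np.bincount(pos // bin_size, minlength=n_bins)
            for b in np.nonzero(counts)[0]:
                start = int(b) * bin_size
                end = min(start + bin_size, limit)
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{counts[b] * scale:.6g}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: need 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes
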