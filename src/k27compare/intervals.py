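"""Genomic interval and gene-model primitives.

All coordinates inside the package are 0-based half-open ([start, end)).
Conversion from 1-based closed conventions (GFF3) happens exactly once,
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / scaffold name; non-empty.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its stranded genomic span.

    TSS and TES are the strand-aware 5' and 3' ends: for a ``+`` strand
    gene TSS == interval.start; for a ``-`` strand gene TSS == interval.end.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id} must be stranded (+ or -), "
                f"got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        return (
            self.interval.start
            if self.interval.strand == "+"
            else self.interval.end
        )

    @property
    def tes(self) -> int:
        return (
            self.interval.end
            if self.interval.strand == "+"
            else self.interval.start
        )

    def target_window(self, upstream: int = 1000) -> GenomicInterval:
        """Eligibility window for peak-to-gene assignment.

        Extends the gene body ``upstream`` bp past the TSS in the
        strand-aware direction: [TSS - upstream, TES] for ``+`` genes,
        [TES, TSS + upstream] for ``-`` genes.
        """
        iv = self.interval
        if iv.strand == "+":
            return GenomicInterval(
                iv.chrom, max(0, iv.start - upstream), iv.end, "+"
            )
        return GenomicInterval(iv.chrom, iv.start, iv.end + upstream, "-")
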