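"""Core domain types for gene-trap screen analysis.

Coordinates are 0-based half-open throughout the package; only written
report tables use the 1-based inclusive genome-browser convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

# Genetic feature labels. Exons of coding transcripts are split into
# 5'UTR / CDS / 3'UTR; exons of non-coding transcripts are labelled
# NC_EXON and treated as exonic (they disrupt the transcript when hit).
FIVE_UTR = "5UTR"
CDS = "CDS"
INTRON = "intron"
THREE_UTR = "3UTR"
PROMOTER = "promoter"
NC_EXON = "nc_exon"

FEATURES = frozenset({FIVE_UTR, CDS, INTRON, THREE_UTR, PROMOTER, NC_EXON})
EXONIC_FEATURES = frozenset({FIVE_UTR, CDS, THREE_UTR, NC_EXON})

SORTED = "sorted"
UNSORTED = "unsorted"
POPULATIONS = (SORTED, UNSORTED)

STRANDS = ("+", "-")


def flip_strand(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the fixed bin length that tiles each chromosome.

    Bins are contiguous, non-overlapping intervals anchored at coordinate 0
    of every chromosome; the last bin is truncated at the chromosome end.
    """

    chrom_sizes: dict[str, int]
    bin_length: int

    def __post_init__(self) -> None:
        if self.bin_length <= 0:
            raise ValueError(f"bin_length must be positive, got {self.bin_length}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_length(chrom)
        return -(-size // self.bin_length)  # ceil division

    def bin_interval(self, chrom: str, index: int) -> tuple[int, int]:
        """Half-open [start, end) of a bin; the final bin is clipped."""
        size = self.chrom_length(chrom)
        if not 0 <= index < self.n_bins(chrom):
            raise IndexError(f"bin index {index} out of range for {chrom}")
        start = index * self.bin_length
        return start, min(start + self.bin_length, size)

    def iter_bins(self, chrom: str) -> Iterator[tuple[int, int, int]]:
        for i in range(self.n_bins(chrom)):
            s, e = self.bin_interval(chrom, i)
            yield i, s, e


@dataclass(frozen=True)
class GeneModel:
    """One transcript record in genePred coordinates (0-based half-open).

    ``cds_start == cds_end`` marks a non-coding transcript.
    """

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_name}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_name}: tx_start must be < tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(
                f"{self.gene_name}: exon_starts and exon_ends lengths differ "
                f"({len(self.exon_starts)} vs {len(self.exon_ends)})"
            )
        if not self.exon_starts:
            raise ValueError(f"{self.gene_name}: at least one exon required")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not s < e:
                raise ValueError(f"{self.gene_name}: empty or inverted exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_name}: exons not sorted / overlapping")
            prev_end = e
        if self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end:
            raise ValueError(f"{self.gene_name}: exons outside transcript bounds")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_name}: cds bounds outside transcript bounds")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start for '+', tx_end - 1 for '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True, order=True)
class Insertion:
    """A gene-trap integration point.

    ``strand`` is the chromosome strand of the aligned flanking read;
    ``population`` is "sorted" (selected) or "unsorted" (control).
    """

    chrom: str
    pos: int
    strand: str
    population: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"insertion strand must be + or -, got {self.strand!r}")
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.pos < 0:
            raise ValueError(f"negative insertion coordinate {self.pos}")


@dataclass(frozen=True)
class FeatureInterval:
    """A strand-aware genomic interval carrying one genetic feature of a gene."""

    chrom: str
    start: int
    end: int
    feature: str
    gene_name: str
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty feature interval [{self.start}, {self.end})")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid feature strand {self.strand!r}")
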