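"""Strand-aware feature derivation from transcript models and bin annotation.

Every transcript contributes 5'UTR / CDS / intron / 3'UTR intervals (or
``nc_exon`` for non-coding transcripts) that partition its transcribed span,
plus a promoter interval covering the bases immediately upstream of its TSS
on the gene's strand. Bins are annotated with every (gene, feature, strand)
triple whose interval overlaps the bin by at least one base; the analyses
key off exclusivity flags derived from that triple set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import (
    CDS,
    EXONIC_FEATURES,
    FIVE_UTR,
    INTRON,
    NC_EXON,
    PROMOTER,
    THREE_UTR,
    FeatureInterval,
    GeneModel,
    GenomeLayout,
)

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 2000


@dataclass(frozen=True)
class BinAnnotation:
    """The set of (gene_name, feature, strand) triples overlapping one bin.

    Exclusivity flags are pure functions of the triple set:

    * ``exclusive_intron`` — non-empty, every triple is an intron, and all
      triples share one gene strand (a mixed-strand intron bin has no
      well-defined antisense orientation and is excluded).
    * ``exclusive_promoter`` — non-empty and every triple is a promoter.
    * ``has_exonic`` — any triple is 5'UTR, CDS, 3'UTR or nc_exon.
    """

    triples: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)

    @property
    def exclusive_intron(self) -> bool:
        if not self.triples:
            return False
        strands = {t[2] for t in self.triples}
        return all(t[1] == INTRON for t in self.triples) and len(strands) == 1

    @property
    def intron_strand(self) -> str:
        """The shared gene strand of an exclusively intronic bin."""
        if not self.exclusive_intron:
            raise ValueError("bin is not exclusively intronic")
        return next(iter(self.triples))[2]

    @property
    def exclusive_promoter(self) -> bool:
        return bool(self.triples) and all(t[1] == PROMOTER for t in self.triples)

    @property
    def has_exonic(self) -> bool:
        return any(t[1] in EXONIC_FEATURES for t in self.triples)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(sorted({t[0] for t in self.triples}))


EMPTY_ANNOTATION = BinAnnotation()


def derive_features(
    gene: GeneModel,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_length: int | None = None,
) -> list[FeatureInterval]:
    """Split one transcript into its annotatable feature intervals.

    Exonic bases land in 5'UTR / CDS / 3'UTR according to the coding bounds
    and the gene's strand (the 5'UTR is TSS-proximal); gaps between
    consecutive exons become introns; non-coding transcripts emit ``nc_exon``
    for every exon. The promoter is the ``promoter_length`` bases directly
    upstream of the TSS on the gene's strand, clipped to the chromosome.
    """
    out: list[FeatureInterval] = []

    def add(start: int, end: int, feature: str) -> None:
        if start < end:
            out.append(
                FeatureInterval(gene.chrom, start, end, feature, gene.gene_name, gene.strand)
            )

    for s, e in zip(gene.exon_starts, gene.exon_ends):
        if not gene.is_coding:
            add(s, e, NC_EXON)
            continue
        # left of cds_start / right of cds_end are untranslated; which one
        # is the 5' side depends on the strand
        left = FIVE_UTR if gene.strand == "+" else THREE_UTR
        right = THREE_UTR if gene.strand == "+" else FIVE_UTR
        add(s, min(e, gene.cds_start), left)
        add(max(s, gene.cds_start), min(e, gene.cds_end), CDS)
        add(max(s, gene.cds_end), e, right)

    for prev_end, next_start in zip(gene.exon_ends, gene.exon_starts[1:]):
        add(prev_end, next_start, INTRON)

    if gene.strand == "+":
        p_start, p_end = gene.tx_start - promoter_length, gene.tx_start
    else:
        p_start, p_end = gene.tx_end, gene.tx_end + promoter_length
    p_start = max(p_start, 0)
    if chrom_length is not None:
        p_end = min(p_end, chrom_length)
    add(p_start, p_end, PROMOTER)

    return out


def derive_all_features(
    genes: list[GeneModel],
    layout: GenomeLayout | None = None,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> list[FeatureInterval]:
    """Feature intervals for every transcript; all isoforms contribute."""
    features = []
    for g in genes:
        clen = layout.chrom_length(g.chrom) if layout is not None else None
        features.extend(derive_features(g, promoter_length, clen))
    return features


def annotate_bins(
    features: list[FeatureInterval], layout: GenomeLayout
) -> dict[tuple[str, int], BinAnnotation]:
    """Map (chrom, bin index) -> BinAnnotation for every bin touching a feature.

    Bins overlapping no feature are absent from the map (empty annotation).
    Because bins tile each chromosome regularly, the bins overlapping a
    feature [start, end) are exactly indices floor(start/L) .. floor((end-1)/L).
    """
    sets: dict[tuple[str, int], set[tuple[str, str, str]]] = {}
    L = layout.bin_length
    for f in features:
        if f.chrom not in layout:
            raise KeyError(f"feature on unknown chromosome {f.chrom!r}")
        size = layout.chrom_length(f.chrom)
        start = max(f.start, 0)
        end = min(f.end, size)
        if start >= end:
            continue
        triple = (f.gene_name, f.feature, f.strand)
        for idx in range(start // L, (end - 1) // L + 1):
            sets.setdefault((f.chrom, idx), set()).add(triple)
    annotation = {key: BinAnnotation(frozenset(s)) for key, s in sets.items()}
    n_mixed = sum(
        1
        for a in annotation.values()
        if a.triples
        and all(t[1] == INTRON for t in a.triples)
        and len({t[2] for t in a.triples}) > 1
    )
    if n_mixed:
        logger.info(
            "%d purely intronic bins span genes on both strands; "
            "excluded from the antisense-intronic analysis",
            n_mixed,
        )
    return annotation


def features_to_bed(features: list[FeatureInterval], path: str) -> None:
    """BED6 export of feature intervals, name = gene|feature."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_name}|{f.feature}\t0\t{f.strand}\n"
            )
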