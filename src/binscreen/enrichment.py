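"""The four enrichment analyses: eligible-unit selection, one-sided Fisher
tests, Benjamini-Hochberg correction and ranking.

Each analysis compares the frequency of qualifying insertions in a unit
(bin or gene) in the sorted (selected) population against the unsorted
(control) population, using the 2x2 table [[a, A-a], [b, B-b]] where A and B
are the genome-wide independent-insertion totals. The one-sided alternative
is enrichment in the sorted cells. p-values are BH-corrected within the
eligible-unit family of each analysis and units are ranked in ascending
order of the corrected value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .binning import (
    MINUS_SORTED,
    MINUS_UNSORTED,
    PLUS_SORTED,
    PLUS_UNSORTED,
    BinTable,
)
from .models import flip_strand


@dataclass(frozen=True)
class ContingencyTable:
    """Qualifying counts a (sorted) and b (unsorted) against totals A and B."""

    a: int
    A: int
    b: int
    B: int

    def __post_init__(self) -> None:
        if not 0 <= self.a <= self.A:
            raise ValueError(f"need 0 <= a <= A, got a={self.a}, A={self.A}")
        if not 0 <= self.b <= self.B:
            raise ValueError(f"need 0 <= b <= B, got b={self.b}, B={self.B}")


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested unit: a bin (chrom/start/end set) or a gene (bin fields None)."""

    unit_id: str
    genes: tuple[str, ...]
    a: int
    b: int
    A: int
    B: int
    p_raw: float
    p_fdr: float
    rank: int
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


def fisher_pvalues(a, A, b, B) -> np.ndarray:
    """Vectorised one-sided (enrichment) Fisher p-values.

    For the table [[a, A-a], [b, B-b]] with fixed margins, the p-value is
    the hypergeometric upper tail P(X >= a) with population A+B, A success
    states and a+b draws. Computed in log space by scipy, stable for totals
    up to at least 1e7.
    """
    a = np.asarray(a, dtype=np.int64)
    A = np.asarray(A, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    B = np.asarray(B, dtype=np.int64)
    p = hypergeom.sf(a - 1, A + B, A, a + b)
    # sf can round a hair above 1 or to exactly 0 only by underflow; clip
    # into the half-open unit interval the test guarantees
    return np.clip(p, np.finfo(float).tiny, 1.0)


def fisher_one_sided_greater(t: ContingencyTable) -> float:
    """One-sided Fisher p for enrichment of the sorted population."""
    if t.A == 0 and t.B == 0:
        raise ValueError("no insertions in either population: Fisher test undefined")
    return float(fisher_pvalues(t.a, t.A, t.b, t.B))


def fdr_correct(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up corrected p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish(units, table: BinTable) -> list[EnrichmentResult]:
    """Fisher + BH over eligible units, then rank.

    ``units`` is a list of (unit_id, genes, a, b, chrom, start, end).
    Tie-break for equal corrected p: raw p, then genomic position / unit id,
    so ranking is reproducible.
    """
    if not units:
        return []
    A, B = table.total_sorted, table.total_unsorted
    if A == 0 and B == 0:
        raise ValueError("no insertions in either population")
    a = np.array([u[2] for u in units], dtype=np.int64)
    b = np.array([u[3] for u in units], dtype=np.int64)
    p_raw = fisher_pvalues(a, A, b, B)
    p_fdr = fdr_correct(p_raw)
    order = sorted(
        range(len(units)),
        key=lambda i: (p_fdr[i], p_raw[i], units[i][4] or "", units[i][5] or 0, units[i][0]),
    )
    results = []
    for rank, i in enumerate(order, start=1):
        unit_id, genes, ai, bi, chrom, start, end = units[i]
        results.append(
            EnrichmentResult(
                unit_id=unit_id,
                genes=genes,
                a=int(ai),
                b=int(bi),
                A=A,
                B=B,
                p_raw=float(p_raw[i]),
                p_fdr=float(p_fdr[i]),
                rank=rank,
                chrom=chrom,
                start=start,
                end=end,
            )
        )
    return results


def _bin_unit(table: BinTable, key: tuple[str, int], genes, a, b):
    chrom, idx = key
    start, end = table.layout.bin_interval(chrom, idx)
    return (f"{chrom}:{start}-{end}", genes, a, b, chrom, start, end)


def antisense_intronic_analysis(table: BinTable) -> list[EnrichmentResult]:
    """Enrichment of antisense insertions in exclusively intronic bins.

    Eligible: bins annotated exclusively as intron (single gene strand) with
    at least one antisense-oriented insertion in the sorted cells. The
    qualifying count is the antisense-strand tally only.
    """
    units = []
    for key in table.occupied_or_annotated():
        ann = table.annotation_for(key)
        if not ann.exclusive_intron:
            continue
        anti = flip_strand(ann.intron_strand)
        c = table.bin_counts(key)
        a = int(c[PLUS_SORTED] if anti == "+" else c[MINUS_SORTED])
        if a < 1:
            continue
        b = int(c[PLUS_UNSORTED] if anti == "+" else c[MINUS_UNSORTED])
        units.append(_bin_unit(table, key, ann.gene_names, a, b))
    return _finish(units, table)


def upstream_analysis(table: BinTable) -> list[EnrichmentResult]:
    """Enrichment of insertions (either orientation) in exclusively promoter bins."""
    units = []
    for key in table.occupied_or_annotated():
        ann = table.annotation_for(key)
        if not ann.exclusive_promoter:
            continue
        c = table.bin_counts(key)
        a = int(c[PLUS_SORTED] + c[MINUS_SORTED])
        if a < 1:
            continue
        b = int(c[PLUS_UNSORTED] + c[MINUS_UNSORTED])
        units.append(_bin_unit(table, key, ann.gene_names, a, b))
    return _finish(units, table)


def inactivating_analysis(table: BinTable) -> list[EnrichmentResult]:
    """Enrichment of gene-disrupting insertions.

    Exonic bins (5'UTR / CDS / 3'UTR / nc_exon) count insertions in either
    orientation; exclusively intronic bins count sense-oriented insertions
    only (the trap's splice acceptor truncates the transcript only in
    sense). The same per-bin counting rule yields the control count b.
    """
    units = []
    for key in table.occupied_or_annotated():
        ann = table.annotation_for(key)
        c = table.bin_counts(key)
        if ann.has_exonic:
            a = int(c[PLUS_SORTED] + c[MINUS_SORTED])
            b = int(c[PLUS_UNSORTED] + c[MINUS_UNSORTED])
        elif ann.exclusive_intron:
            sense = ann.intron_strand
            a = int(c[PLUS_SORTED] if sense == "+" else c[MINUS_SORTED])
            b = int(c[PLUS_UNSORTED] if sense == "+" else c[MINUS_UNSORTED])
        else:
            continue
        if a < 1:
            continue
        units.append(_bin_unit(table, key, ann.gene_names, a, b))
    return _finish(units, table)


def gene_based_analysis(table: BinTable) -> list[EnrichmentResult]:
    """Per-gene aggregation of all insertions in bins carrying that gene.

    Every bin annotated with a gene (any feature, promoter included)
    contributes both strands' counts to that gene's sum; a bin overlapping
    two genes contributes to both. Genes with at least one sorted insertion
    are tested.
    """
    gene_a: dict[str, int] = {}
    gene_b: dict[str, int] = {}
    for key in table.occupied_or_annotated():
        ann = table.annotation_for(key)
        if not ann.triples:
            continue
        c = table.bin_counts(key)
        a = int(c[PLUS_SORTED] + c[MINUS_SORTED])
        b = int(c[PLUS_UNSORTED] + c[MINUS_UNSORTED])
        for gene in ann.gene_names:
            gene_a[gene] = gene_a.get(gene, 0) + a
            gene_b[gene] = gene_b.get(gene, 0) + b
    units = [
        (gene, (gene,), gene_a[gene], gene_b.get(gene, 0), None, None, None)
        for gene in sorted(gene_a)
        if gene_a[gene] >= 1
    ]
    return _finish(units, table)


ANALYSES = {
    "antisense-intronic": antisense_intronic_analysis,
    "upstream": upstream_analysis,
    "inactivating": inactivating_analysis,
    "gene": gene_based_analysis,
}
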