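"""Deduplication, bin assignment and strand-resolved counting of insertions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import EMPTY_ANNOTATION, BinAnnotation
from .models import SORTED, UNSORTED, GenomeLayout, Insertion, flip_strand

logger = logging.getLogger(__name__)

# column order of the per-bin count vector
PLUS_SORTED, MINUS_SORTED, PLUS_UNSORTED, MINUS_UNSORTED = range(4)
COUNT_COLUMNS = ("plus_sorted", "minus_sorted", "plus_unsorted", "minus_unsorted")


def orientation(read_strand: str, feature_strand: str) -> str:
    """"sense" iff the read strand equals the feature's gene strand."""
    flip_strand(read_strand)  # validates
    flip_strand(feature_strand)
    return "sense" if read_strand == feature_strand else "antisense"


def dedup_insertions(insertions: list[Insertion]) -> list[Insertion]:
    """Collapse reads to independent integration events.

    One event per unique (chrom, pos, strand, population); a site seen in
    both populations counts once in each. Result order is canonical
    (sorted), so it is independent of input order.
    """
    return sorted(set(insertions))


def assign_bin(ins: Insertion, layout: GenomeLayout) -> tuple[str, int]:
    """The (chrom, bin index) whose interval encompasses the insertion point."""
    size = layout.chrom_length(ins.chrom)  # KeyError for unknown chromosome
    if not 0 <= ins.pos < size:
        raise ValueError(f"insertion at {ins.chrom}:{ins.pos} outside chromosome [0, {size})")
    return ins.chrom, ins.pos // layout.bin_length


@dataclass
class BinTable:
    """Per-bin, per-strand, per-population tallies of independent insertions.

    ``counts`` maps (chrom, bin index) -> int64[4] in the order
    (+sorted, -sorted, +unsorted, -unsorted); bins with no insertions are
    absent. Totals are genome-wide deduplicated insertion counts per
    population and serve as the Fisher-test margins.
    """

    layout: GenomeLayout
    counts: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    annotation: dict[tuple[str, int], BinAnnotation] = field(default_factory=dict)
    total_sorted: int = 0
    total_unsorted: int = 0

    def bin_counts(self, key: tuple[str, int]) -> np.ndarray:
        c = self.counts.get(key)
        return c if c is not None else np.zeros(4, dtype=np.int64)

    def annotation_for(self, key: tuple[str, int]) -> BinAnnotation:
        return self.annotation.get(key, EMPTY_ANNOTATION)

    def occupied_or_annotated(self) -> list[tuple[str, int]]:
        return sorted(set(self.counts) | set(self.annotation))


def tally(
    insertions: list[Insertion],
    annotation: dict[tuple[str, int], BinAnnotation],
    layout: GenomeLayout,
) -> BinTable:
    """Tally deduplicated insertions into a BinTable.

    Totals count every independent insertion genome-wide, whether or not its
    bin carries any annotation.
    """
    table = BinTable(layout=layout, annotation=annotation)
    col_of = {
        (SORTED, "+"): PLUS_SORTED,
        (SORTED, "-"): MINUS_SORTED,
        (UNSORTED, "+"): PLUS_UNSORTED,
        (UNSORTED, "-"): MINUS_UNSORTED,
    }
    for ins in insertions:
        key = assign_bin(ins, layout)
        vec = table.counts.get(key)
        if vec is None:
            vec = table.counts[key] = np.zeros(4, dtype=np.int64)
        vec[col_of[ins.population, ins.strand]] += 1
        if ins.population == SORTED:
            table.total_sorted += 1
        else:
            table.total_unsorted += 1
    return table


def write_bedgraph_tracks(table: BinTable, prefix: str) -> list[str]:
    """bedGraph export of the four count tracks (+/- x sorted/unsorted)."""
    paths = []
    for col, name in enumerate(COUNT_COLUMNS):
        path = f"{prefix}.{name}.bedgraph"
        with open(path, "w") as fh:
            for (chrom, idx), vec in sorted(table.counts.items()):
                if vec[col]:
                    s, e = table.layout.bin_interval(chrom, idx)
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(vec[col])}\n")
        paths.append(path)
    return paths
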