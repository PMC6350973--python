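"""Readers and writers for the pipeline's standard formats.

Inputs: UCSC genePred/refFlat gene models, two-column chrom.sizes, mapped
reads as SAM/BAM, or pre-extracted insertion points as BED6. Outputs: the
ranked enrichment table (rank, bin location in 1-based inclusive browser
coordinates, overlapping genes, qualifying counts, raw and FDR-corrected p)
and serialised intermediate tables so analyses can re-run without touching
the alignments again.
"""

from __future__ import annotations

import logging

import pysam

from .annotation import BinAnnotation
from .binning import BinTable
from .enrichment import EnrichmentResult
from .models import GeneModel, GenomeLayout, Insertion

logger = logging.getLogger(__name__)


def read_chrom_sizes(path: str, bin_length: int = 1000) -> GenomeLayout:
    """Two-column TSV (name, length) -> GenomeLayout."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        logger.warning("%s: no chromosomes read", path)
    return GenomeLayout(chrom_sizes=sizes, bin_length=bin_length)


def _parse_coord_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_gene_models(path: str) -> list[GeneModel]:
    """Parse genePred-dialect gene models.

    Handles plain genePred (10+ columns, strand in column 3), refFlat
    (leading gene-symbol column) and Table Browser exports with a leading
    numeric ``bin`` column; the dialect is auto-detected per row from the
    strand-column position and whether column 1 is an integer.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 10 and f[2] in "+-":
                    off, name = 0, f[0]
                elif len(f) >= 11 and f[3] in "+-":
                    # refFlat: geneName txName chrom strand ...
                    # bin+genePred: bin name chrom strand ...
                    off = 1
                    name = f[1] if f[0].lstrip("-").isdigit() else f[0]
                else:
                    raise ValueError("unrecognised genePred dialect")
                genes.append(
                    GeneModel(
                        gene_name=name,
                        chrom=f[off + 1],
                        strand=f[off + 2],
                        tx_start=int(f[off + 3]),
                        tx_end=int(f[off + 4]),
                        cds_start=int(f[off + 5]),
                        cds_end=int(f[off + 6]),
                        exon_starts=_parse_coord_list(f[off + 8]),
                        exon_ends=_parse_coord_list(f[off + 9]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    """Plain 10-column genePred output."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s in g.exon_starts) + ","
            ends = ",".join(str(e) for e in g.exon_ends) + ","
            fh.write(
                f"{g.gene_name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t"
                f"{g.cds_start}\t{g.cds_end}\t{len(g.exon_starts)}\t{starts}\t{ends}\n"
            )


def _is_unique(read, min_mapq: int | None) -> bool:
    if read.is_secondary or read.is_supplementary:
        return False
    for tag in ("NH", "X0"):  # alignment-count tags (various aligners)
        if read.has_tag(tag) and read.get_tag(tag) > 1:
            return False
    if min_mapq is not None and read.mapping_quality < min_mapq:
        return False
    return True


def read_insertions_sam(
    path: str,
    population: str,
    max_mismatches: int = 3,
    unique_only: bool = True,
    min_mapq: int | None = None,
) -> list[Insertion]:
    """Extract insertion points from aligned gene-trap reads.

    Unmapped, multi-locus (secondary/supplementary flag or an
    alignment-count tag > 1) and too-mismatched (NM tag > ``max_mismatches``)
    records are dropped; reads lacking the mismatch tag are kept. The
    insertion point is the LTR-adjacent read end: leftmost aligned base for
    plus-strand reads, rightmost for minus-strand reads.
    """
    out: list[Insertion] = []
    n_skipped_noref = 0
    with pysam.AlignmentFile(path, check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        for read in af:
            if read.is_unmapped:
                continue
            if read.reference_name is None:
                n_skipped_noref += 1
                continue
            if unique_only and not _is_unique(read, min_mapq):
                continue
            if read.has_tag("NM") and read.get_tag("NM") > max_mismatches:
                continue
            pos = read.reference_end - 1 if read.is_reverse else read.reference_start
            chrom = read.reference_name
            clen = lengths.get(chrom)
            if clen is not None and not 0 <= pos < clen:
                raise ValueError(f"{path}: read at {chrom}:{pos} outside chromosome")
            out.append(
                Insertion(
                    chrom=chrom,
                    pos=pos,
                    strand="-" if read.is_reverse else "+",
                    population=population,
                )
            )
    if n_skipped_noref:
        logger.info("%s: skipped %d records with no reference name", path, n_skipped_noref)
    return out


def read_insertions_bed(
    path: str, population: str, layout: GenomeLayout | None = None
) -> list[Insertion]:
    """BED6 -> insertions; pos = BED start, strand from column 6 (required)."""
    out: list[Insertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 with a strand column required")
            if f[5] not in "+-":
                raise ValueError(f"{path}:{lineno}: invalid strand {f[5]!r}")
            pos = int(f[1])
            if layout is not None and not 0 <= pos < layout.chrom_length(f[0]):
                raise ValueError(f"{path}:{lineno}: coordinate outside chromosome")
            out.append(Insertion(chrom=f[0], pos=pos, strand=f[5], population=population))
    return out


def write_insertions_bed(insertions: list[Insertion], path: str) -> None:
    """BED6 export (one 1-bp interval per insertion), the tool's own converter."""
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(
                f"{ins.chrom}\t{ins.pos}\t{ins.pos + 1}\tinsertion\t0\t{ins.strand}\n"
            )


# ---------------------------------------------------------------------------
# ranked enrichment table

RANKED_COLUMNS = (
    "rank",
    "chrom",
    "bin_start",
    "bin_end",
    "genes",
    "sorted_insertions",
    "unsorted_insertions",
    "p_raw",
    "p_fdr",
)


def write_ranked_table(
    results: list[EnrichmentResult],
    path: str,
    analysis_label: str,
    total_sorted: int,
    total_unsorted: int,
) -> None:
    """Ranked TSV; bin spans reported 1-based inclusive (browser convention)."""
    with open(path, "w") as fh:
        fh.write(f"# analysis: {analysis_label}\n")
        fh.write(f"# total_insertions_sorted: {total_sorted}\n")
        fh.write(f"# total_insertions_unsorted: {total_unsorted}\n")
        fh.write("\t".join(RANKED_COLUMNS) + "\n")
        for r in results:
            if r.chrom is not None:
                loc = (r.chrom, str(r.start + 1), str(r.end))
            else:
                loc = ("", "", "")
            fh.write(
                "\t".join(
                    (
                        str(r.rank),
                        *loc,
                        ";".join(r.genes),
                        str(r.a),
                        str(r.b),
                        f"{r.p_raw:.12g}",
                        f"{r.p_fdr:.12g}",
                    )
                )
                + "\n"
            )


def read_ranked_table(path: str) -> tuple[list[EnrichmentResult], str, int, int]:
    """Inverse of :func:`write_ranked_table`."""
    label, total_sorted, total_unsorted = "", 0, 0
    results: list[EnrichmentResult] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# analysis:"):
                label = line.split(":", 1)[1].strip()
            elif line.startswith("# total_insertions_sorted:"):
                total_sorted = int(line.split(":", 1)[1])
            elif line.startswith("# total_insertions_unsorted:"):
                total_unsorted = int(line.split(":", 1)[1])
            elif not line or line.startswith(("#", "rank\t")):
                continue
            else:
                f = line.split("\t")
                chrom = f[1] or None
                start = int(f[2]) - 1 if f[2] else None
                end = int(f[3]) if f[3] else None
                genes = tuple(f[4].split(";")) if f[4] else ()
                unit_id = f"{chrom}:{start}-{end}" if chrom else (genes[0] if genes else "")
                results.append(
                    EnrichmentResult(
                        unit_id=unit_id,
                        genes=genes,
                        a=int(f[5]),
                        b=int(f[6]),
                        A=total_sorted,
                        B=total_unsorted,
                        p_raw=float(f[7]),
                        p_fdr=float(f[8]),
                        rank=int(f[0]),
                        chrom=chrom,
                        start=start,
                        end=end,
                    )
                )
    return results, label, total_sorted, total_unsorted


# ---------------------------------------------------------------------------
# intermediate serialisation (annotation map + bin counts)


def write_bin_annotation(
    annotation: dict[tuple[str, int], BinAnnotation], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbin_index\tgene\tfeature\tstrand\n")
        for (chrom, idx), ann in sorted(annotation.items()):
            for gene, feature, strand in sorted(ann.triples):
                fh.write(f"{chrom}\t{idx}\t{gene}\t{feature}\t{strand}\n")


def read_bin_annotation(path: str) -> dict[tuple[str, int], BinAnnotation]:
    sets: dict[tuple[str, int], set] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a bin-annotation table")
        for line in fh:
            chrom, idx, gene, feature, strand = line.rstrip("\n").split("\t")
            sets.setdefault((chrom, int(idx)), set()).add((gene, feature, strand))
    return {k: BinAnnotation(frozenset(s)) for k, s in sets.items()}


def write_bin_counts(table: BinTable, path: str) -> None:
    """Counts + layout in one TSV so analyses need no other input."""
    import numpy as np  # noqa: F401  (kept local: only write/read use arrays)

    with open(path, "w") as fh:
        fh.write(f"# bin_length: {table.layout.bin_length}\n")
        for chrom, size in table.layout.chrom_sizes.items():
            fh.write(f"# chrom_size: {chrom}\t{size}\n")
        fh.write(f"# total_sorted: {table.total_sorted}\n")
        fh.write(f"# total_unsorted: {table.total_unsorted}\n")
        fh.write("chrom\tbin_index\tplus_sorted\tminus_sorted\tplus_unsorted\tminus_unsorted\n")
        for (chrom, idx), c in sorted(table.counts.items()):
            fh.write(f"{chrom}\t{idx}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n")


def read_bin_counts(
    path: str, annotation: dict[tuple[str, int], BinAnnotation] | None = None
) -> BinTable:
    import numpy as np

    sizes: dict[str, int] = {}
    bin_length = None
    total_sorted = total_unsorted = 0
    counts: dict[tuple[str, int], np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# bin_length:"):
                bin_length = int(line.split(":", 1)[1])
            elif line.startswith("# chrom_size:"):
                name, size = line.split(":", 1)[1].strip().split("\t")
                sizes[name] = int(size)
            elif line.startswith("# total_sorted:"):
                total_sorted = int(line.split(":", 1)[1])
            elif line.startswith("# total_unsorted:"):
                total_unsorted = int(line.split(":", 1)[1])
            elif not line or line.startswith(("#", "chrom\t")):
                continue
            else:
                f = line.split("\t")
                counts[(f[0], int(f[1]))] = np.array(
                    [int(x) for x in f[2:6]], dtype=np.int64
                )
    if bin_length is None or not sizes:
        raise ValueError(f"{path}: missing layout header lines")
    return BinTable(
        layout=GenomeLayout(chrom_sizes=sizes, bin_length=bin_length),
        counts=counts,
        annotation=annotation or {},
        total_sorted=total_sorted,
        total_unsorted=total_unsorted,
    )
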