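"""Seeded synthetic screens: genome layout, gene models and two insertion
populations with optional TSS-proximity bias and planted enrichment.

The generator emulates the structure of a haploid gene-trap screen: a
mutagenised control ("unsorted") population and a phenotypically selected
("sorted") population of strand-oriented point insertions over an annotated
genome. Insertions are drawn from a categorical distribution over
(bin, chromosome strand) cells; retroviral TSS preference is modelled as a
weight multiplier near transcription start sites, and enrichment is planted
by multiplying the sampling weight of chosen cells (so each population
remains a single multinomial draw and the Fisher model's sampling
assumptions stay intact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import BinAnnotation, annotate_bins, derive_all_features
from .models import (
    SORTED,
    UNSORTED,
    GeneModel,
    GenomeLayout,
    Insertion,
    flip_strand,
)


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply the sampling weight of one bin's cells.

    ``orientation`` is interpreted relative to the unique gene strand of the
    target bin's annotation ("sense" / "antisense"), or applies to both
    chromosome strands ("both"); a literal chromosome strand ("+" / "-") is
    also accepted. ``population`` is "sorted" or "both".
    """

    chrom: str
    bin_index: int
    orientation: str = "both"
    multiplier: float = 50.0
    population: str = SORTED

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense", "both", "+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not (np.isfinite(self.multiplier) and self.multiplier > 0):
            raise ValueError("multiplier must be finite and positive")
        if self.population not in (SORTED, "both"):
            raise ValueError(f"bad population {self.population!r}")

    def chrom_strands(self, annotation: dict[tuple[str, int], BinAnnotation]) -> tuple[str, ...]:
        if self.orientation in "+-":
            return (self.orientation,)
        if self.orientation == "both":
            return ("+", "-")
        ann = annotation.get((self.chrom, self.bin_index))
        if ann is None or not ann.triples:
            raise ValueError(
                f"bin {self.chrom}:{self.bin_index} carries no annotation; "
                "sense/antisense planting is undefined"
            )
        strands = {t[2] for t in ann.triples}
        if len(strands) != 1:
            raise ValueError(
                f"bin {self.chrom}:{self.bin_index} overlaps genes on both strands"
            )
        gene_strand = next(iter(strands))
        return (gene_strand,) if self.orientation == "sense" else (flip_strand(gene_strand),)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic screen (all sizes in bp)."""

    n_chroms: int = 1
    chrom_length: int = 1_000_000
    bin_length: int = 1000
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (100, 500)
    intron_length_range: tuple[int, int] = (500, 5000)
    intergenic_gap_range: tuple[int, int] = (3000, 20000)
    noncoding_fraction: float = 0.1
    promoter_length: int = 2000
    n_sorted: int = 20_000
    n_unsorted: int = 20_000
    tss_bias_weight: float = 3.0
    tss_bias_window: int = 2000
    planted: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tss_bias_weight < 1:
            raise ValueError("tss_bias_weight must be >= 1")


def simulate_gene_models(cfg: SimConfig) -> tuple[GenomeLayout, list[GeneModel]]:
    """Place non-overlapping multi-exon genes on the synthetic chromosomes.

    Genes are distributed round-robin over chromosomes and laid out left to
    right with random intergenic gaps; deterministic per seed. Raises if the
    requested genes cannot be packed into the genome.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    layout = GenomeLayout(chrom_sizes=sizes, bin_length=cfg.bin_length)
    chroms = list(sizes)
    cursors = {c: 0 for c in chroms}
    genes: list[GeneModel] = []
    for gi in range(cfg.n_genes):
        chrom = chroms[gi % len(chroms)]
        gap = int(rng.integers(cfg.intergenic_gap_range[0], cfg.intergenic_gap_range[1] + 1))
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=max(n_exons - 1, 0)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        tx_start = cursors[chrom] + gap
        pos = tx_start
        exon_starts, exon_ends = [], []
        for i in range(n_exons):
            exon_starts.append(pos)
            pos += int(exon_lens[i])
            exon_ends.append(pos)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        tx_end = pos
        if tx_end > cfg.chrom_length:
            raise ValueError(
                f"infeasible packing: gene {gi + 1}/{cfg.n_genes} exceeds {chrom} length"
            )
        if rng.random() < cfg.noncoding_fraction:
            cds_start = cds_end = tx_start
        elif n_exons == 1:
            u5 = int(rng.integers(1, exon_lens[0] - 1))
            u3 = int(rng.integers(1, exon_lens[0] - u5))
            cds_start, cds_end = tx_start + u5, tx_end - u3
        else:
            cds_start = exon_starts[0] + int(rng.integers(1, exon_lens[0]))
            cds_end = exon_ends[-1] - int(rng.integers(1, exon_lens[-1]))
        genes.append(
            GeneModel(
                gene_name=f"gene{gi + 1:03d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=tuple(exon_starts),
                exon_ends=tuple(exon_ends),
            )
        )
        cursors[chrom] = tx_end
    return layout, genes


def _cell_weights(
    layout: GenomeLayout,
    annotation: dict[tuple[str, int], BinAnnotation],
    cfg: SimConfig,
    genes: list[GeneModel],
    population: str,
) -> tuple[list[str], np.ndarray]:
    """Weights over (chrom, bin, strand) cells for one population."""
    chroms = list(layout.chrom_sizes)
    weights = {c: np.ones((layout.n_bins(c), 2)) for c in chroms}
    L = layout.bin_length
    for g in genes:
        lo = max(g.tss - cfg.tss_bias_window, 0)
        hi = min(g.tss + cfg.tss_bias_window, layout.chrom_length(g.chrom))
        if lo < hi:
            weights[g.chrom][lo // L : (hi - 1) // L + 1, :] *= cfg.tss_bias_weight
    for eff in cfg.planted:
        if eff.population != "both" and eff.population != population:
            continue
        for strand in eff.chrom_strands(annotation):
            weights[eff.chrom][eff.bin_index, 0 if strand == "+" else 1] *= eff.multiplier
    flat = np.concatenate([weights[c].ravel() for c in chroms])
    return chroms, flat


def simulate_insertions(
    layout: GenomeLayout,
    annotation: dict[tuple[str, int], BinAnnotation],
    cfg: SimConfig,
    genes: list[GeneModel] = (),
) -> list[Insertion]:
    """Draw both insertion populations.

    Each population is one multinomial draw over (bin, strand) cells with
    its own weight vector, followed by uniform placement within the chosen
    bin. Each population uses its own random stream derived from the config
    seed (sorted -> [seed, 1], unsorted -> [seed, 2]), so the two
    populations are independent and deterministic per seed.
    """
    out: list[Insertion] = []
    for pop_index, (population, n) in enumerate(
        ((SORTED, cfg.n_sorted), (UNSORTED, cfg.n_unsorted)), start=1
    ):
        rng = np.random.default_rng([cfg.seed, pop_index])
        chroms, flat = _cell_weights(layout, annotation, cfg, list(genes), population)
        counts = rng.multinomial(n, flat / flat.sum())
        offset = 0
        for chrom in chroms:
            n_bins = layout.n_bins(chrom)
            block = counts[offset : offset + 2 * n_bins].reshape(n_bins, 2)
            offset += 2 * n_bins
            for bin_idx, strand_idx in zip(*np.nonzero(block)):
                k = int(block[bin_idx, strand_idx])
                s, e = layout.bin_interval(chrom, int(bin_idx))
                strand = "+" if strand_idx == 0 else "-"
                for pos in rng.integers(s, e, size=k):
                    out.append(Insertion(chrom, int(pos), strand, population))
    return out


@dataclass
class SimulatedScreen:
    """A fully materialised synthetic screen."""

    cfg: SimConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    annotation: dict[tuple[str, int], BinAnnotation]
    insertions: list[Insertion]


def simulate_screen(cfg: SimConfig) -> SimulatedScreen:
    """Gene models -> features -> bin annotation -> both insertion populations."""
    layout, genes = simulate_gene_models(cfg)
    features = derive_all_features(genes, layout, cfg.promoter_length)
    annotation = annotate_bins(features, layout)
    insertions = simulate_insertions(layout, annotation, cfg, genes)
    return SimulatedScreen(cfg, layout, genes, annotation, insertions)


def find_plantable_bins(
    screen_annotation: dict[tuple[str, int], BinAnnotation], kind: str
) -> list[tuple[str, int]]:
    """Bins eligible for planting: kind in {"exclusive_intron", "exclusive_promoter"}."""
    return sorted(
        key for key, ann in screen_annotation.items() if getattr(ann, kind)
    )


def with_planted(cfg: SimConfig, *effects: PlantedEffect) -> SimConfig:
    return replace(cfg, planted=cfg.planted + tuple(effects))


def write_screen(screen: SimulatedScreen, out_dir: str) -> dict[str, str]:
    """Write the screen in exactly the pipeline's input formats."""
    import os

    from .io import write_gene_models, write_insertions_bed

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "chrom_sizes": os.path.join(out_dir, "chrom.sizes"),
        "genes": os.path.join(out_dir, "genes.genePred"),
        "sorted": os.path.join(out_dir, "sorted.bed"),
        "unsorted": os.path.join(out_dir, "unsorted.bed"),
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in screen.layout.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    write_gene_models(screen.genes, paths["genes"])
    for pop, key in ((SORTED, "sorted"), (UNSORTED, "unsorted")):
        write_insertions_bed(
            [i for i in screen.insertions if i.population == pop], paths[key]
        )
    return paths
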