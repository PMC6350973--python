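# binscreen

Bin-based enrichment analysis of gene-trap insertional mutagenesis screens.

Haploid genetic screens mutagenise cells with a gene-trap (GT) retrovirus,
select a phenotype by FACS, and sequence the genomic flanks of the
integration sites in the selected ("sorted") and control ("unsorted")
populations. Conventional hit-calling aggregates insertions per annotated
gene and therefore only sees gene-inactivating events. `binscreen` instead
tiles the genome into fixed-length bins that ignore gene boundaries, tallies
independent, strand-oriented insertions per bin in each population, and
tests each bin for enrichment in the selected cells. Because each bin is
also annotated with the genetic features it overlaps (5'UTR, CDS, intron,
3'UTR, and a 2 kb "promoter" feature upstream of each TSS), the tool can
isolate *atypical* insertion patterns — antisense insertions in introns, or
insertions upstream of a TSS — that do not disrupt the transcript and
instead point at cis-regulatory elements, as well as the classical
inactivating patterns.

## The statistic

For a tested unit (bin or gene) with `a` qualifying insertions among `A`
total independent insertions in the sorted population, and `b` among `B` in
the unsorted population, `binscreen` computes a one-sided Fisher's exact
test on

```
        | qualifying | rest      |
sorted  |     a      |  A − a    |
unsorted|     b      |  B − b    |
```

with alternative "enriched in sorted", i.e. the hypergeometric upper tail
P(X ≥ a). p-values are Benjamini–Hochberg corrected within the eligible-unit
family of each analysis, and units are ranked by ascending corrected p.

Four analyses differ only in eligibility and in what counts as qualifying:

| analysis | eligible bins | qualifying insertions |
|---|---|---|
| antisense-intronic | exclusively intron (one gene strand), ≥1 antisense sorted insertion | antisense strand only |
| upstream | exclusively promoter, ≥1 sorted insertion | both orientations |
| inactivating | any exonic feature; or exclusively intron with ≥1 sense sorted insertion | both orientations (exonic); sense only (intron) |
| gene | every gene with ≥1 sorted insertion in its bins | both orientations over all bins carrying the gene, promoter included |

An insertion is *sense* with respect to a feature when its read strand
equals the feature's gene strand.

## Worked example

The package ships a seeded screen simulator that writes exactly the
pipeline's input formats, with an enrichment effect planted in one
exclusively-intronic bin (antisense, selected population only):

```sh
binscreen simulate --out-dir screen --seed 3 --n-sorted 4000 --n-unsorted 4000 \
    --plant chr1:300:+:50
binscreen annotate --genes screen/genes.genePred --chrom-sizes screen/chrom.sizes \
    --out screen/ann.tsv
binscreen count --sorted screen/sorted.bed --unsorted screen/unsorted.bed \
    --chrom-sizes screen/chrom.sizes --annotation screen/ann.tsv --out screen/counts.tsv
binscreen analyze --counts screen/counts.tsv --annotation screen/ann.tsv \
    --mode antisense-intronic --out screen/ranked.tsv
head -5 screen/ranked.tsv
```

prints

```
# analysis: antisense-intronic
# total_insertions_sorted: 3981
# total_insertions_unsorted: 3996
rank	chrom	bin_start	bin_end	genes	sorted_insertions	unsorted_insertions	p_raw	p_fdr
1	chr1	300001	301000	gene013	215	9	5.65921757649e-54	6.11195498261e-52
```

The header records the genome-wide independent-insertion totals (the Fisher
margins; 4000 simulated reads minus coordinate duplicates). The planted bin
(chr1:300001–301000, 1-based inclusive browser coordinates) lies in an
intron of `gene013`, a minus-strand gene, so the planted plus-strand
insertions are antisense to it: the bin ranks first with 215 antisense
insertions in the sorted cells against 9 in the unsorted cells, corrected
p ≈ 6e-52. `binscreen plot` turns a ranked table into
circle-plot data (bins at random x positions, −log10 corrected p on y) or a
per-bin sense/antisense histogram track over a region; `--image` renders a
static figure.

In a real screen the inputs are aligned 36 bp flanking reads (SAM/BAM;
uniquely mapping, ≤3 mismatches — both filters applied on reading) or
pre-extracted insertion points (BED6), plus RefSeq gene models in
genePred/refFlat format and a chrom.sizes file, with 1000 bp bins for
enrichment analyses and 250 bp bins for histogram-resolution views.

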