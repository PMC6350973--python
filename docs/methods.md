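# Methods

## Model and procedure

`binscreen` analyses gene-trap (GT) insertional mutagenesis screens in
which a selected ("sorted") and a control ("unsorted") population of
mutagenised haploid cells are compared. The unit of evidence is the
*independent insertion*: a unique (chromosome, coordinate, read strand)
integration event per population after exact-coordinate deduplication of
reads. The genome is tiled into contiguous, non-overlapping bins of fixed
length anchored at coordinate 0 of each chromosome (the last bin is
truncated); an insertion belongs to the bin containing its coordinate,
`index = floor(pos / L)`. Per bin the tool tallies plus- and minus-strand
insertions separately for each population.

Feature annotation is transcript-based. Each transcript's exonic bases are
split into 5'UTR / CDS / 3'UTR by the coding bounds, respecting strand (the
5'UTR is the TSS-proximal untranslated portion); inter-exon gaps are
introns; exons of non-coding transcripts (cds_start == cds_end in genePred)
are labelled `nc_exon`. A `promoter` feature covers the `promoter_length`
bases directly upstream of the TSS on the transcript's strand, clipped at
chromosome edges and deliberately *not* clipped against neighbouring genes.
A bin carries the (gene, feature, strand) triple of every feature interval
overlapping it by ≥1 bp; all isoforms of a gene contribute independently.

Orientation: an insertion is *sense* with respect to a feature iff its read
strand equals the feature's gene strand. A GT truncates a transcript when
spliced in sense from an intron, or when landing in exonic sequence in
either orientation; antisense intronic and promoter-region insertions
leave the transcript intact and are the signal used for regulatory-element
discovery.

Each of the four analyses selects its eligible units, forms the 2×2 table
[[a, A−a], [b, B−b]] — `a`/`b` the unit's qualifying sorted/unsorted counts,
`A`/`B` the *genome-wide* independent-insertion totals — and computes the
one-sided Fisher exact p (hypergeometric upper tail P(X ≥ a), evaluated in
log space via `scipy.stats.hypergeom.sf`, stable for totals ≥ 1e7).
Benjamini–Hochberg correction is applied within the eligible-unit family of
that analysis only; the "FDR" in outputs always means BH. Ranking is by
(corrected p, raw p, chromosome, start) so ties are broken reproducibly.

Eligibility and counting rules:

* **antisense-intronic** — bins whose whole annotation set is introns on a
  single gene strand, with ≥1 antisense sorted insertion; `a` counts the
  antisense strand only. Purely intronic bins spanning genes on *both*
  strands have no defined antisense orientation and are excluded (logged).
* **upstream** — bins annotated exclusively as promoter, ≥1 sorted
  insertion; both orientations count.
* **inactivating** — bins with any exonic feature (`nc_exon` included)
  count both orientations; exclusively intronic bins count sense only.
  The control count `b` uses the same per-bin rule.
* **gene** — per gene, both-strand counts are summed over every bin
  carrying that gene under any feature, promoter included; a bin shared by
  two genes contributes to both. Genes need ≥1 sorted insertion to be
  tested (an a=0 gene has p=1 and would only inflate the family size).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_length` | 1000 bp | analysis resolution; 250 bp for histogram-resolution views |
| `promoter_length` | 2000 bp | upstream span annotated as promoter |
| `max_mismatches` | 3 | NM-tag ceiling when reading alignments |
| `fdr_threshold` | 0.01 | labelling threshold in plots (not an output filter) |
| `top_n_plot` | 5000 | bins shown in circle-plot data |

Coordinates are 0-based half-open internally; ranked tables print 1-based
inclusive spans (genome-browser convention). The insertion point of a
minus-strand read is its rightmost aligned base, of a plus-strand read its
leftmost: the sequenced 36 bp flank abuts the retroviral LTR, so the
LTR-adjacent end is the biologically meaningful coordinate. Which read end
abuts the LTR depends on library design and is not recoverable from the
alignment alone; at 250–1000 bp bin resolution the choice is nearly
inconsequential, but it is fixed and documented here. Reads lacking a
mismatch tag are kept (the filter applies only when evidence exists);
uniqueness is enforced via secondary/supplementary flags and NH/X0-style
alignment-count tags, with an optional minimum-MAPQ fallback for aligners
that emit neither.

## Synthetic screens

The simulator generates non-overlapping multi-exon gene models (round-robin
across chromosomes, left-to-right packing with random intergenic gaps;
infeasible packings raise) and two insertion populations drawn from a
categorical distribution over (bin, strand) cells. Defaults — one 1 Mbp
chromosome, 20 genes, 20,000 insertions per population, 1000 bp bins — are
the conditions under which the recovery and calibration guarantees are
stated. Retroviral TSS preference is modelled by multiplying cell weights
by `tss_bias_weight` (default 3) within ±2 kb of every TSS; the weight is a
realism choice in the range reported for gamma-retroviral integration
preference, and since it applies to both populations equally it does not
bias the sorted-vs-unsorted comparison. Planted effects multiply the
sampling weight of chosen cells (for the stated population and orientation)
rather than injecting fixed counts, so each population remains a single
multinomial draw and the Fisher model's sampling assumptions stay intact.
Each population has its own stream seeded as `[seed, 1]` (sorted) and
`[seed, 2]` (unsorted) via numpy's SeedSequence; a sorted-only planting
therefore leaves the unsorted draw bit-for-bit unchanged.

What the simulator does *not* emulate: sequencing error and alignment
ambiguity (insertions are exact points), clustered ligation artifacts,
chromatin-driven integration hotspots beyond the TSS window, overlapping
genes (models are packed disjointly, though the annotation and analyses
fully support overlap and are tested on constructed overlapping fixtures),
and realistic genome scale. Passing recovery tests therefore demonstrate
the pipeline's logic and calibration under its own sampling model, not
performance on real screen data.

## Numerical choices and degenerate inputs

* Fisher p is clipped into (0, 1]; `A == B == 0` is an error (no data).
* BH correction of an empty p-vector is the empty vector.
* `-log10(p_fdr)` in circle-plot data is capped (default 300) where the
  corrected p underflowed to 0, and flagged `capped`.
* Duplicate chromosome names, negative lengths, exon-array length
  mismatches, out-of-bounds coordinates and unknown chromosomes are
  rejected at read time with file/line context.
* Empty input files yield empty outputs (with a warning for chrom.sizes).

## Design choices

* Bins anchored at 0 per chromosome; the trailing partial bin is kept.
* Deduplication is exact-coordinate and per population; near-duplicate
  (±1 bp) clustering is out of scope.
* Exclusivity flags are computed over the *full* multi-isoform annotation
  set: a bin that is intron in one isoform and CDS in another is not
  exclusively intronic.
* The Fisher margins use the standard table form; the tested unit's own
  counts are not subtracted from the totals.
* Verification sizes: the statistical core is checked exhaustively against
  integer enumeration for all tables with A+B ≤ 60; recovery and
  calibration guarantees use 20 seeded screens at the default conditions.

## Known limitations

* Gene-level aggregation counts a shared bin once per gene, so dense gene
  overlap inflates both genes' counts.
* The promoter feature may overlap a neighbouring gene's features; such
  bins simply lose promoter exclusivity rather than being re-assigned.
* Calibration statements are for the simulator's multinomial null;
  real screens with clonal expansion violate independence of insertions
  and will be anti-conservative to an unquantified degree.
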