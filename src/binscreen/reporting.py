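"""Display artifacts: oriented insertion histograms and ranked circle plots.

Both are produced primarily as data tables; static rendering via matplotlib
is optional and never required by the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import (
    MINUS_SORTED,
    MINUS_UNSORTED,
    PLUS_SORTED,
    PLUS_UNSORTED,
    BinTable,
)
from .enrichment import EnrichmentResult

DEFAULT_NEGLOG_CAP = 300.0


@dataclass(frozen=True)
class HistogramTrack:
    """Per-bin sense/antisense insertion counts over a region.

    Orientation is relative to ``gene_strand``: for a '+' reference gene the
    sense count is the plus-strand tally, for a '-' gene the minus-strand
    tally. Convention: sense counts are drawn above the zero line,
    antisense counts below.
    """

    chrom: str
    start: int
    end: int
    gene_name: str
    gene_strand: str
    rows: pd.DataFrame  # bin_start, bin_end, then (sense|antisense)_(sorted|unsorted)


def histogram_track(
    table: BinTable, chrom: str, start: int, end: int, gene_name: str, gene_strand: str
) -> HistogramTrack:
    """Build the oriented histogram for all bins intersecting [start, end)."""
    layout = table.layout
    size = layout.chrom_length(chrom)
    start, end = max(start, 0), min(end, size)
    if start >= end:
        raise ValueError("empty region")
    L = layout.bin_length
    rows = []
    for idx in range(start // L, (end - 1) // L + 1):
        bs, be = layout.bin_interval(chrom, idx)
        c = table.bin_counts((chrom, idx))
        if gene_strand == "+":
            sense_s, anti_s = c[PLUS_SORTED], c[MINUS_SORTED]
            sense_u, anti_u = c[PLUS_UNSORTED], c[MINUS_UNSORTED]
        else:
            sense_s, anti_s = c[MINUS_SORTED], c[PLUS_SORTED]
            sense_u, anti_u = c[MINUS_UNSORTED], c[PLUS_UNSORTED]
        rows.append((bs, be, int(sense_s), int(anti_s), int(sense_u), int(anti_u)))
    df = pd.DataFrame(
        rows,
        columns=[
            "bin_start",
            "bin_end",
            "sense_sorted",
            "antisense_sorted",
            "sense_unsorted",
            "antisense_unsorted",
        ],
    )
    return HistogramTrack(chrom, start, end, gene_name, gene_strand, df)


def circle_plot_data(
    results: list[EnrichmentResult],
    top_n: int = 5000,
    sig_threshold: float = 0.01,
    seed: int = 0,
    neglog_cap: float = DEFAULT_NEGLOG_CAP,
) -> pd.DataFrame:
    """Rows for the ranked circle plot.

    The ``top_n`` best-ranked units are placed at random x positions
    (deterministic per seed); y is -log10 of the corrected p (capped, with
    a flag, where floating-point underflow produced 0); circle size is the
    sorted-cell insertion count; units below the significance threshold
    carry their gene labels.
    """
    top = sorted(results, key=lambda r: r.rank)[:top_n]
    rng = np.random.default_rng(seed)
    x = rng.permutation(len(top))
    rows = []
    for xi, r in zip(x, top):
        capped = r.p_fdr <= 10.0 ** (-neglog_cap)
        y = neglog_cap if capped else -np.log10(r.p_fdr)
        label = ";".join(r.genes) if r.p_fdr < sig_threshold else ""
        rows.append((int(xi), float(y), r.a, label, bool(capped), r.unit_id))
    return pd.DataFrame(
        rows, columns=["x", "neg_log10_p_fdr", "size", "label", "capped", "unit_id"]
    )


def plot_circles(df: pd.DataFrame, path: str, sig_threshold: float = 0.01) -> None:
    """Optional static rendering of circle-plot data."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    sig = df["label"] != ""
    ax.scatter(df.loc[~sig, "x"], df.loc[~sig, "neg_log10_p_fdr"],
               s=10 + df.loc[~sig, "size"], c="lightgray", alpha=0.6)
    ax.scatter(df.loc[sig, "x"], df.loc[sig, "neg_log10_p_fdr"],
               s=10 + df.loc[sig, "size"], c="tab:red", alpha=0.8)
    for _, row in df.loc[sig].iterrows():
        ax.annotate(row["label"], (row["x"], row["neg_log10_p_fdr"]), fontsize=7)
    ax.axhline(-np.log10(sig_threshold), ls="--", lw=0.8, c="k")
    ax.set_xlabel("bins (random order)")
    ax.set_ylabel(r"$-\log_{10}$(FDR-corrected p)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_histogram(track: HistogramTrack, path: str) -> None:
    """Optional static rendering: sense above the zero line, antisense below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    centers = (track.rows["bin_start"] + track.rows["bin_end"]) / 2
    width = (track.rows["bin_end"] - track.rows["bin_start"]).median()
    ax.bar(centers, track.rows["sense_sorted"], width=width, color="tab:blue",
           label="sorted (sense up / antisense down)")
    ax.bar(centers, -track.rows["antisense_sorted"], width=width, color="tab:blue")
    ax.bar(centers, track.rows["sense_unsorted"], width=width * 0.5, color="tab:gray",
           label="unsorted")
    ax.bar(centers, -track.rows["antisense_unsorted"], width=width * 0.5, color="tab:gray")
    ax.axhline(0, c="k", lw=0.8)
    ax.set_xlabel(f"{track.chrom} position (bp)")
    ax.set_ylabel("independent insertions")
    ax.set_title(f"{track.gene_name} ({track.gene_strand})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
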