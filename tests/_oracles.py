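"""Independent brute-force oracles used to check the statistical core.

These deliberately avoid scipy/statsmodels: the Fisher oracle enumerates
hypergeometric point masses with exact integer arithmetic, and the FDR
oracle is a literal transcription of the Benjamini-Hochberg step-up
definition.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_tail_oracle(a: int, A: int, b: int, B: int) -> float:
    """P(X >= a) for the 2x2 table [[a, A-a], [b, B-b]] with fixed margins.

    Exact integer enumeration: X ~ Hypergeom(population A+B, A successes,
    a+b draws); one final big-int division gives a correctly rounded float.
    """
    N = a + b
    num = sum(comb(A, k) * comb(B, N - k) for k in range(a, min(A, N) + 1))
    return num / comb(A + B, N)


def fisher_tails_all_tables(max_total: int):
    """Every table with A+B <= max_total: arrays (a, A, b, B, p_oracle).

    Point masses for one (A, B, N) stratum are computed once and shared by
    all values of a via suffix sums, keeping full-integer exactness.
    """
    a_l, A_l, b_l, B_l, p_l = [], [], [], [], []
    for A in range(0, max_total + 1):
        for B in range(0, max_total - A + 1):
            if A == 0 and B == 0:
                continue  # the test statistic is undefined with no data
            denom_M = A + B
            for N in range(0, denom_M + 1):
                k_lo, k_hi = max(0, N - B), min(A, N)
                masses = [comb(A, k) * comb(B, N - k) for k in range(k_lo, k_hi + 1)]
                denom = comb(denom_M, N)
                suffix = 0
                tails = [0] * (k_hi - k_lo + 2)
                for i in range(len(masses) - 1, -1, -1):
                    suffix += masses[i]
                    tails[i] = suffix
                for a in range(k_lo, k_hi + 1):
                    b = N - a
                    a_l.append(a)
                    A_l.append(A)
                    b_l.append(b)
                    B_l.append(B)
                    p_l.append(tails[a - k_lo] / denom)
    return (
        np.array(a_l), np.array(A_l), np.array(b_l), np.array(B_l),
        np.array(p_l, dtype=float),
    )


def bh_stepup_oracle(p) -> np.ndarray:
    """Benjamini-Hochberg step-up by definition, in input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_bases_oracle(gene) -> np.ndarray:
    """Per-base feature label over the transcribed span [tx_start, tx_end)."""
    labels = np.full(gene.tx_end - gene.tx_start, "intron", dtype=object)
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        sl = slice(s - gene.tx_start, e - gene.tx_start)
        if not gene.is_coding:
            labels[sl] = "nc_exon"
            continue
        pos = np.arange(s, e)
        left_label = "5UTR" if gene.strand == "+" else "3UTR"
        right_label = "3UTR" if gene.strand == "+" else "5UTR"
        exon_labels = np.where(
            pos < gene.cds_start,
            left_label,
            np.where(pos < gene.cds_end, "CDS", right_label),
        )
        labels[sl] = exon_labels
    return labels
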