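"""Independent reference implementations used as test oracles.

Deliberately naive: literal transcriptions of the procedures under test,
coded without reference to the package internals (no interval trees, no
vectorization), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from lncarray.annotation import CATEGORIES, TranscriptRecord


def quantile_normalize_literal(df: pd.DataFrame) -> pd.DataFrame:
    """Step-by-step transcription of the quantile-normalization procedure:

    sort each column ascending; take the mean across the sorted columns at
    each row; replace each row of the sorted matrix by that mean; rearrange
    back to the input order.
    """
    arr = df.to_numpy(dtype=float)
    n_rows, n_cols = arr.shape
    sorted_cols = np.sort(arr, axis=0)
    row_means = sorted_cols.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_cols):
        order = np.argsort(arr[:, j], kind="stable")
        for rank in range(n_rows):
            out[order[rank], j] = row_means[rank]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def bh_stepup_manual(p_values) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook recipe."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(p_values[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all size-n draws (N small)."""
    universe = list(range(N))
    in_set = set(range(K))
    hits = sum(1 for draw in combinations(universe, n) if len(in_set & set(draw)) >= k)
    return hits / comb(N, n)


def classify_brute(lnc: TranscriptRecord, coding, window: int = 1000):
    """All-pairs positional classification testing each definition literally.

    Returns (category, partner_id, evidence) with the same precedence ladder
    and partner tie-breaks as the package contract: strongest physical
    overlap first; largest overlap (smallest 5' gap) wins; ties by
    lexicographic id.
    """

    def ov(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    def blocks_ov(A, B):
        return sum(ov(a, b) for a in A for b in B)

    matches = {cat: [] for cat in CATEGORIES}
    for c in coding:
        if c.biotype != "coding" or c.chrom != lnc.chrom:
            continue
        body = ov((lnc.start, lnc.end), (c.start, c.end))
        exon_exon = blocks_ov(lnc.exons, c.exons)
        introns = [(c.exons[i][1], c.exons[i + 1][0]) for i in range(len(c.exons) - 1)]
        exon_intron = blocks_ov(lnc.exons, introns)
        if c.strand == lnc.strand:
            if exon_exon > 0:
                matches["sense_overlapping"].append((exon_exon, c.transcript_id))
            elif body > 0 and exon_intron > 0:
                matches["intronic"].append((exon_intron, c.transcript_id))
        else:
            if exon_exon > 0:
                matches["natural_antisense"].append((exon_exon, c.transcript_id))
            elif body > 0:
                matches["nonoverlapping_antisense"].append((body, c.transcript_id))
            else:
                plus, minus = (lnc, c) if lnc.strand == "+" else (c, lnc)
                if plus.start >= minus.end and plus.start - minus.end < window:
                    matches["bidirectional"].append(
                        (plus.start - minus.end, c.transcript_id)
                    )
    for cat in CATEGORIES[:-1]:
        if matches[cat]:
            if cat == "bidirectional":
                evidence, partner = min(matches[cat])
            else:
                evidence, partner = min(matches[cat], key=lambda t: (-t[0], t[1]))
            return cat, partner, evidence
    return "intergenic", None, None


def random_genome(rng: np.random.Generator, n_coding=6, n_lnc=8, span=60_000):
    """Small random annotation with plenty of chance overlaps."""

    def random_tx(prefix, i, biotype, max_exons):
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, max_exons + 1))
        cur = int(rng.integers(0, span))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(100, 1200))
            exons.append((cur, cur + length))
            cur += length + int(rng.integers(100, 2500))
        return TranscriptRecord(
            f"{prefix}{i:03d}", f"g_{prefix}{i:03d}", chrom, strand,
            exons[0][0], exons[-1][1], tuple(exons), biotype,
        )

    coding = [random_tx("c", i, "coding", 3) for i in range(n_coding)]
    lncs = [random_tx("l", i, "lncRNA", 2) for i in range(n_lnc)]
    return coding, lncs
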