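"""Cis coexpression pairing of lncRNAs with coding genes, plus concordance.

Two pair families are built from the differential-expression results:

* antisense pairs — lncRNAs classified into an antisense category, paired
  with their overlapping coding partner (distance 0);
* lincRNA-neighbor pairs — intergenic lncRNAs paired with the nearest
  differentially expressed coding gene on each side within a window
  (default 300 kb), so one lincRNA can contribute up to two pairs.

Only transcripts passing the primary DE filter (FC >= 2, P < 0.05) enter
pairs.  Direction concordance — both members up or both down — is summarized
with exact rational arithmetic on counts, so the four direction-category
fractions sum to exactly 1 and the concordant fraction is exactly the sum of
the up/up and down/down fractions.

Distances are boundary gaps (nearest transcript edges), not TSS distances;
``upstream``/``downstream`` labels are taken from the lincRNA's own strand
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import CodingIndex, PositionalClass, TranscriptRecord
from .diffexpr import DEResult

logger = logging.getLogger(__name__)

NEIGHBOR_WINDOW = 300_000  # bp

ANTISENSE_CATEGORIES = ("natural_antisense", "nonoverlapping_antisense")

__all__ = [
    "NEIGHBOR_WINDOW",
    "ANTISENSE_CATEGORIES",
    "CoexpressionPair",
    "ConcordanceSummary",
    "antisense_pairs",
    "lincrna_neighbors",
    "concordance_summary",
    "write_pairs_tsv",
]


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class CoexpressionPair:
    """One lncRNA-mRNA cis pair with DE directions of both members."""

    lncrna_id: str
    mrna_id: str
    relationship: str
    distance: int  # bp, 0 for overlapping relationships
    lnc_regulation: str
    mrna_regulation: str

    @property
    def concordant(self) -> bool:
        return self.lnc_regulation == self.mrna_regulation


@dataclass(frozen=True)
class ConcordanceSummary:
    """Direction-category counts with exact fractional summaries."""

    n_up_up: int
    n_down_down: int
    n_up_down: int
    n_down_up: int

    @property
    def n_pairs(self) -> int:
        return self.n_up_up + self.n_down_down + self.n_up_down + self.n_down_up

    def _frac(self, k: int) -> Fraction:
        return Fraction(k, self.n_pairs)

    @property
    def frac_up_up(self) -> Fraction:
        return self._frac(self.n_up_up)

    @property
    def frac_down_down(self) -> Fraction:
        return self._frac(self.n_down_down)

    @property
    def frac_up_down(self) -> Fraction:
        return self._frac(self.n_up_down)

    @property
    def frac_down_up(self) -> Fraction:
        return self._frac(self.n_down_up)

    @property
    def frac_concordant(self) -> Fraction:
        return Fraction(self.n_up_up + self.n_down_down, self.n_pairs)


def _passing(de: Iterable[DEResult]) -> dict[str, DEResult]:
    return {r.transcript_id: r for r in de if r.passes_primary}


def antisense_pairs(
    classes: Iterable[PositionalClass],
    de: Iterable[DEResult],
    records: Mapping[str, TranscriptRecord] | None = None,
) -> list[CoexpressionPair]:
    """Pairs of DE antisense lncRNAs with their DE sense partner mRNAs.

    When transcript *records* are supplied, nonoverlapping-antisense lncRNAs
    lying wholly inside the partner gene body are labeled
    ``intronic_antisense`` (they sit in an intron on the opposite strand);
    otherwise the classifier category is used as the relationship.
    """
    all_de = {r.transcript_id: r for r in de}
    passing = {tx: r for tx, r in all_de.items() if r.passes_primary}
    pairs: list[CoexpressionPair] = []
    for cls in classes:
        if cls.category not in ANTISENSE_CATEGORIES:
            continue
        lnc_de = passing.get(cls.lncrna_id)
        if lnc_de is None:
            continue
        if cls.partner_id not in all_de:
            logger.warning(
                "antisense partner %s has no DE record; pair skipped", cls.partner_id
            )
            continue
        if cls.partner_id not in passing:
            continue
        mrna_de = passing[cls.partner_id]
        relationship = cls.category
        if (
            relationship == "nonoverlapping_antisense"
            and records is not None
            and cls.lncrna_id in records
            and cls.partner_id in records
        ):
            lnc = records[cls.lncrna_id]
            cod = records[cls.partner_id]
            if cod.start <= lnc.start and lnc.end <= cod.end:
                relationship = "intronic_antisense"
        pairs.append(
            CoexpressionPair(
                lncrna_id=cls.lncrna_id,
                mrna_id=cls.partner_id,
                relationship=relationship,
                distance=0,
                lnc_regulation=lnc_de.regulation,
                mrna_regulation=mrna_de.regulation,
            )
        )
    return pairs


def lincrna_neighbors(
    intergenic_lncs: Iterable[TranscriptRecord],
    coding: CodingIndex | Iterable[TranscriptRecord],
    de: Iterable[DEResult],
    window: int = NEIGHBOR_WINDOW,
) -> list[CoexpressionPair]:
    """Nearest-DE-neighbor pairs for intergenic lncRNAs within *window* bp.

    For each lincRNA passing the primary filter, the nearest coding gene that
    also passes is sought on each genomic side; each side found within the
    window yields one pair.  Relationship labels are strand-relative for the
    lincRNA (``downstream`` = the gene lies past the lincRNA's 3' end on its
    own strand).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not isinstance(coding, CodingIndex):
        coding = CodingIndex(coding)
    passing = _passing(de)

    pairs: list[CoexpressionPair] = []
    for lnc in intergenic_lncs:
        lnc_de = passing.get(lnc.transcript_id)
        if lnc_de is None:
            continue
        best: dict[str, tuple[int, str]] = {}  # side -> (gap, mrna_id)
        for c in coding.near(lnc.chrom, lnc.start, lnc.end, pad=window):
            if c.transcript_id not in passing:
                continue
            if c.start >= lnc.end:
                side, gap = "right", c.start - lnc.end
            elif c.end <= lnc.start:
                side, gap = "left", lnc.start - c.end
            else:
                continue  # overlapping gene: not a neighbor of an intergenic lnc
            if gap >= window:
                continue
            cur = best.get(side)
            if cur is None or (gap, c.transcript_id) < cur:
                best[side] = (gap, c.transcript_id)
        for side, (gap, mrna_id) in sorted(best.items()):
            if lnc.strand == "+":
                relationship = "downstream" if side == "right" else "upstream"
            else:
                relationship = "upstream" if side == "right" else "downstream"
            pairs.append(
                CoexpressionPair(
                    lncrna_id=lnc.transcript_id,
                    mrna_id=mrna_id,
                    relationship=relationship,
                    distance=gap,
                    lnc_regulation=lnc_de.regulation,
                    mrna_regulation=passing[mrna_id].regulation,
                )
            )
    return pairs


def concordance_summary(pairs: Iterable[CoexpressionPair]) -> ConcordanceSummary:
    """Count the four direction patterns over *pairs*."""
    counts = {("up", "up"): 0, ("down", "down"): 0, ("up", "down"): 0, ("down", "up"): 0}
    n = 0
    for p in pairs:
        counts[(p.lnc_regulation, p.mrna_regulation)] += 1
        n += 1
    if n == 0:
        raise EmptyInputError("no pairs to summarize")
    return ConcordanceSummary(
        n_up_up=counts[("up", "up")],
        n_down_down=counts[("down", "down")],
        n_up_down=counts[("up", "down")],
        n_down_up=counts[("down", "up")],
    )


def write_pairs_tsv(
    pairs: Iterable[CoexpressionPair],
    de: Iterable[DEResult],
    path: str | Path,
    symbols: Mapping[str, str] | None = None,
) -> None:
    """Write pairs as a TSV mirroring the published pair-table columns."""
    de_by_id = {r.transcript_id: r for r in de}
    symbols = symbols or {}
    rows = []
    for p in pairs:
        rows.append(
            {
                "lncRNA_seqname": p.lncrna_id,
                "lncRNA_symbol": symbols.get(p.lncrna_id, p.lncrna_id),
                "lncRNA_fold_change": de_by_id[p.lncrna_id].fold_change,
                "lncRNA_regulation": p.lnc_regulation,
                "genome_relationship": p.relationship,
                "nearby_gene_seqname": p.mrna_id,
                "nearby_gene_symbol": symbols.get(p.mrna_id, p.mrna_id),
                "nearby_gene_fold_change": de_by_id[p.mrna_id].fold_change,
                "nearby_gene_regulation": p.mrna_regulation,
                "distance_bp": p.distance,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "lncRNA_seqname", "lncRNA_symbol", "lncRNA_fold_change",
            "lncRNA_regulation", "genome_relationship", "nearby_gene_seqname",
            "nearby_gene_symbol", "nearby_gene_fold_change",
            "nearby_gene_regulation", "distance_bp",
        ],
    ).to_csv(path, sep="\t", index=False)
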