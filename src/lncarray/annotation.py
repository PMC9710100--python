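"""Transcript models, GTF/BED12 I/O and six-way positional lncRNA classification.

Each lncRNA is assigned exactly one category relative to the coding
transcriptome:

``sense_overlapping``
    an lncRNA exon overlaps a coding exon on the same strand;
``intronic``
    the lncRNA overlaps an intron of a same-strand coding transcript
    (without any exon–exon overlap);
``natural_antisense``
    an lncRNA exon overlaps a coding exon on the opposite strand;
``nonoverlapping_antisense``
    the lncRNA overlaps a coding gene body on the opposite strand but no exon;
``bidirectional``
    the lncRNA is head-to-head (divergent) with a coding transcript, 5' ends
    within 1000 bp, without genomic overlap;
``intergenic``
    none of the above.

When several definitions match, the first category in the order above wins
(strength-of-overlap precedence).  Among several qualifying partners the one
with the largest overlap (or smallest 5' gap) is reported; ties break by
lexicographic transcript id.

Internal coordinates are 0-based half-open; GTF I/O is 1-based inclusive and
BED12 I/O 0-based half-open, converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

CATEGORIES = (
    "sense_overlapping",
    "intronic",
    "natural_antisense",
    "nonoverlapping_antisense",
    "bidirectional",
    "intergenic",
)

BIDIRECTIONAL_WINDOW = 1000  # bp between divergent 5' ends

__all__ = [
    "CATEGORIES",
    "BIDIRECTIONAL_WINDOW",
    "TranscriptRecord",
    "PositionalClass",
    "CodingIndex",
    "read_gtf",
    "write_gtf",
    "read_bed12",
    "write_bed12",
    "classify_lncrna",
    "classify_all",
    "write_classes_tsv",
]


class ParseError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript (0-based half-open coordinates)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str  # "coding" | "lncRNA"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"{self.transcript_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ParseError(f"{self.transcript_id}: start must be < end")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ParseError(
                    f"{self.transcript_id}: exon [{s},{e}) outside transcript bounds"
                )
            if prev_end is not None and s < prev_end:
                raise ParseError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if not self.exons:
            raise ParseError(f"{self.transcript_id}: transcript without exons")

    @property
    def length(self) -> int:
        """Transcript length in nt (sum of exon lengths)."""
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def five_prime(self) -> int:
        """5' end position (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PositionalClass:
    """Classification outcome for one lncRNA."""

    lncrna_id: str
    category: str
    partner_id: str | None  # None iff intergenic
    evidence: int | None  # overlap bp, or 5'-gap bp for bidirectional


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _block_overlap(
    blocks_a: Sequence[tuple[int, int]], blocks_b: Sequence[tuple[int, int]]
) -> int:
    return sum(_interval_overlap(a, b) for a in blocks_a for b in blocks_b)


def _divergent_gap(a: TranscriptRecord, b: TranscriptRecord) -> int | None:
    """Gap between facing 5' ends of two divergent, non-overlapping transcripts.

    Returns None unless strands are opposite, bodies are disjoint, and the
    plus-strand transcript lies entirely downstream of the minus-strand one
    (head-to-head geometry: transcription runs away from the shared gap).
    """
    if a.strand == b.strand:
        return None
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    if plus.start >= minus.end:
        return plus.start - minus.end  # == distance between the 5' ends
    return None


class CodingIndex:
    """Chromosome-indexed collection of coding transcripts."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self.records: list[TranscriptRecord] = [
            r for r in records if r.biotype == "coding"
        ]
        self.by_id = {r.transcript_id: r for r in self.records}
        self._trees: dict[str, IntervalTree] = {}
        for r in self.records:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(
                r.start, r.end, r.transcript_id
            )

    def near(self, chrom: str, start: int, end: int, pad: int = 0) -> list[TranscriptRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start - pad, end + pad)
        return [self.by_id[iv.data] for iv in hits]

    def on_chrom(self, chrom: str) -> list[TranscriptRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.by_id[iv.data] for iv in tree]


def classify_lncrna(
    lnc: TranscriptRecord,
    coding: CodingIndex,
    bidirectional_window: int = BIDIRECTIONAL_WINDOW,
) -> PositionalClass:
    """Assign one of the six positional categories to *lnc*."""
    if lnc.biotype != "lncRNA":
        raise ValueError(f"{lnc.transcript_id} is not an lncRNA")

    candidates = coding.near(lnc.chrom, lnc.start, lnc.end, pad=bidirectional_window)
    # best (evidence, partner) per category; evidence maximized except for
    # bidirectional where the 5'-gap is minimized
    best: dict[str, tuple[int, str]] = {}

    def consider(cat: str, evidence: int, partner: str) -> None:
        cur = best.get(cat)
        if cat == "bidirectional":
            better = cur is None or (evidence, partner) < cur
        else:
            better = cur is None or (-evidence, partner) < (-cur[0], cur[1])
        if better:
            best[cat] = (evidence, partner)

    for c in candidates:
        body_ov = _interval_overlap((lnc.start, lnc.end), (c.start, c.end))
        if c.strand == lnc.strand:
            if body_ov > 0:
                exon_ov = _block_overlap(lnc.exons, c.exons)
                if exon_ov > 0:
                    consider("sense_overlapping", exon_ov, c.transcript_id)
                else:
                    intron_ov = _block_overlap(lnc.exons, c.introns)
                    if intron_ov > 0:
                        consider("intronic", intron_ov, c.transcript_id)
        else:
            if body_ov > 0:
                exon_ov = _block_overlap(lnc.exons, c.exons)
                if exon_ov > 0:
                    consider("natural_antisense", exon_ov, c.transcript_id)
                else:
                    consider("nonoverlapping_antisense", body_ov, c.transcript_id)
            else:
                gap = _divergent_gap(lnc, c)
                if gap is not None and gap < bidirectional_window:
                    consider("bidirectional", gap, c.transcript_id)

    for cat in CATEGORIES[:-1]:
        if cat in best:
            evidence, partner = best[cat]
            return PositionalClass(lnc.transcript_id, cat, partner, evidence)
    return PositionalClass(lnc.transcript_id, "intergenic", None, None)


def classify_all(
    lncs: Iterable[TranscriptRecord],
    coding: CodingIndex | Iterable[TranscriptRecord],
    bidirectional_window: int = BIDIRECTIONAL_WINDOW,
) -> list[PositionalClass]:
    if not isinstance(coding, CodingIndex):
        coding = CodingIndex(coding)
    return [classify_lncrna(l, coding, bidirectional_window) for l in lncs]


# ---------------------------------------------------------------------------
# I/O

def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from GTF exon features.

    Exon features must carry ``transcript_id``, ``gene_id`` and ``biotype``
    attributes.  GTF's 1-based inclusive coordinates are converted to the
    internal 0-based half-open convention.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        try:
            tx_id = f.attributes["transcript_id"][0]
            gene_id = f.attributes["gene_id"][0]
            biotype = f.attributes["biotype"][0]
        except KeyError as exc:
            raise ParseError(f"exon feature missing attribute: {exc}") from exc
        if f.strand not in "+-":
            raise ParseError(f"{tx_id}: unknown strand {f.strand!r}")
        rec = by_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": f.seqid, "strand": f.strand, "exons": [],
             "biotype": biotype},
        )
        if rec["chrom"] != f.seqid or rec["strand"] != f.strand:
            raise ParseError(f"{tx_id}: exons on multiple chromosomes/strands")
        rec["exons"].append((f.start - 1, f.end))  # 1-based inclusive -> 0-based half-open
    records = []
    for tx_id, rec in by_tx.items():
        exons = tuple(sorted(rec["exons"]))
        records.append(
            TranscriptRecord(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
                biotype=rec["biotype"],
            )
        )
    return records


def write_gtf(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            for s, e in r.exons:
                attrs = (
                    f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                    f'biotype "{r.biotype}";'
                )
                fh.write(
                    f"{r.chrom}\tlncarray\texon\t{s + 1}\t{e}\t.\t{r.strand}\t.\t{attrs}\n"
                )


def write_bed12(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            sizes = ",".join(str(e - s) for s, e in r.exons) + ","
            starts = ",".join(str(s - r.start) for s, e in r.exons) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.chrom, r.start, r.end,
                            f"{r.transcript_id}|{r.gene_id}|{r.biotype}",
                            0, r.strand, r.start, r.end, "0,0,0",
                            len(r.exons), sizes, starts,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptRecord]:
    """Read the BED12 dialect written by :func:`write_bed12` (0-based half-open)."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {line_no}: BED12 requires 12 fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"line {line_no}: block count mismatch")
            parts = name.split("|")
            tx_id = parts[0]
            gene_id = parts[1] if len(parts) > 1 else tx_id
            biotype = parts[2] if len(parts) > 2 else "coding"
            exons = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            records.append(
                TranscriptRecord(tx_id, gene_id, chrom, strand, start, end, exons, biotype)
            )
    return records


def write_classes_tsv(classes: Iterable[PositionalClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tcategory\tpartner_id\tevidence_bp\n")
        for c in classes:
            fh.write(
                f"{c.lncrna_id}\t{c.category}\t{c.partner_id or ''}\t"
                f"{'' if c.evidence is None else c.evidence}\n"
            )
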