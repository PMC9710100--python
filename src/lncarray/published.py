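"""Published summary tables from the GSE152931 brainstem comparison study.

The study compared brainstem lncRNA/mRNA expression of DBA/1 mice (prone to
audiogenic seizures with respiratory arrest) against C57BL/6 controls on an
Arraystar mouse lncRNA array.  Its printed result tables serve here as small
real-data inputs: the antisense lncRNA-mRNA pair table (fold changes,
directions and genome relationships), two rows of the lincRNA-neighbor pair
table, and the printed direction-category percentages of the 115
differentially expressed lincRNA-neighbor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PublishedPairRow",
    "ANTISENSE_PAIR_TABLE",
    "LINCRNA_PAIR_EXAMPLES",
    "LINCRNA_DIRECTION_PERCENT",
    "N_DE_LINCRNAS",
    "distinct_antisense_lncrnas",
    "concordant_percent",
]


@dataclass(frozen=True)
class PublishedPairRow:
    """One row of a published lncRNA-mRNA pair table."""

    lncrna_seqname: str
    lncrna_symbol: str
    lncrna_fold_change: float
    lncrna_regulation: str
    relationship: str
    mrna_seqname: str
    mrna_symbol: str
    mrna_fold_change: float
    mrna_regulation: str


# Differentially expressed antisense lncRNAs and their sense coding partners.
ANTISENSE_PAIR_TABLE: tuple[PublishedPairRow, ...] = (
    PublishedPairRow("ENSMUST00000145435", "2010012P19Rik", 6.0917526, "down",
                     "natural_antisense", "NM_001034097", "Tnfsf12-Tnfsf13",
                     2.0415635, "down"),
    PublishedPairRow("AK017289", "AK017289", 5.792853, "up",
                     "natural_antisense", "NM_001267808", "H2-L",
                     2.8392743, "up"),
    PublishedPairRow("AK017289", "AK017289", 5.792853, "up",
                     "natural_antisense", "NM_010380", "H2-D1",
                     2.6094529, "up"),
    PublishedPairRow("AK155933", "AK155933", 4.4353006, "down",
                     "intronic_antisense", "NM_146191", "Lrrk1",
                     2.53359, "down"),
    PublishedPairRow("AK087052", "AK087052", 3.4286643, "up",
                     "intronic_antisense", "NM_001035242", "Trpm3",
                     2.0411979, "down"),
    PublishedPairRow("AK087052", "AK087052", 3.4286643, "up",
                     "intronic_antisense", "NM_001035243", "Trpm3",
                     2.0100955, "down"),
    PublishedPairRow("AK149710", "AK149710", 3.163844, "down",
                     "natural_antisense", "NM_008850", "Pitpna",
                     2.4984672, "down"),
    PublishedPairRow("AK158573", "AK158573", 2.5693914, "down",
                     "natural_antisense", "NM_028803", "Gbe1",
                     2.5839838, "down"),
    PublishedPairRow("ENSMUST00000148180", "Gm15396", 2.5550359, "down",
                     "natural_antisense", "NM_008437", "Napsa",
                     4.8828493, "down"),
    PublishedPairRow("AK007047", "AK007047", 2.510748, "down",
                     "natural_antisense", "NM_001200023", "Zfp963",
                     3.3589015, "up"),
    PublishedPairRow("ENSMUST00000124513", "Gm15247", 2.064782, "down",
                     "natural_antisense", "NM_183151", "Mid1",
                     3.2269554, "down"),
)

# One lincRNA pairing both its downstream and its upstream DE neighbor.
LINCRNA_PAIR_EXAMPLES: tuple[PublishedPairRow, ...] = (
    PublishedPairRow("NR_033305", "AA388235", 66.9199947, "down",
                     "downstream", "NM_010386", "H2-Dma", 2.170267, "up"),
    PublishedPairRow("NR_033305", "AA388235", 66.9199947, "down",
                     "upstream", "NM_019420", "B3galt4", 5.7973092, "down"),
)

# Direction-category percentages printed for the 115 DE lincRNA-neighbor pairs.
LINCRNA_DIRECTION_PERCENT: dict[str, float] = {
    "up_up": 12.9,
    "down_down": 55.6,
    "up_down": 8.0,
    "down_up": 22.5,
}

N_DE_LINCRNAS = 115


def distinct_antisense_lncrnas() -> set[str]:
    """Distinct antisense lncRNA identifiers over the published pair rows."""
    return {row.lncrna_seqname for row in ANTISENSE_PAIR_TABLE}


def concordant_percent(direction_percent: dict[str, float] | None = None) -> float:
    """Concordant total = up/up percent + down/down percent."""
    d = LINCRNA_DIRECTION_PERCENT if direction_percent is None else direction_percent
    return d["up_up"] + d["down_down"]
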