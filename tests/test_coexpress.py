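from fractions import Fraction

import pytest

from lncarray.annotation import CodingIndex, PositionalClass, TranscriptRecord
from lncarray.coexpress import (
    CoexpressionPair,
    EmptyInputError,
    antisense_pairs,
    concordance_summary,
    lincrna_neighbors,
)
from lncarray.diffexpr import DEResult
from lncarray.published import LINCRNA_PAIR_EXAMPLES


def de(tx, fc, regulation, passes=True):
    return DEResult(tx, fc, regulation, 0.01 if passes else 0.5, 0.02,
                    passes_primary=passes, passes_sensitivity=passes)


def tx(tid, strand, start, end, biotype="coding", chrom="chr1"):
    return TranscriptRecord(tid, f"g_{tid}", chrom, strand, start, end,
                            ((start, end),), biotype)


def test_antisense_pairs_follow_published_direction_patterns():
    """Down/down and up/up antisense pairs are both concordant, as in the
    published pair table (2010012P19Rik/Tnfsf12-Tnfsf13 down/down;
    AK017289/H2-L up/up)."""
    classes = [
        PositionalClass("lncA", "natural_antisense", "mA", 120),
        PositionalClass("lncB", "natural_antisense", "mB", 80),
    ]
    results = [de("lncA", 6.09, "down"), de("mA", 2.04, "down"),
               de("lncB", 5.79, "up"), de("mB", 2.83, "up")]
    pairs = antisense_pairs(classes, results)
    assert [(p.lncrna_id, p.mrna_id, p.concordant, p.distance) for p in pairs] == [
        ("lncA", "mA", True, 0), ("lncB", "mB", True, 0)
    ]


def test_antisense_partner_failing_filter_yields_no_pair():
    classes = [PositionalClass("lnc", "natural_antisense", "m", 50)]
    pairs = antisense_pairs(classes, [de("lnc", 4.0, "up"), de("m", 1.2, "up", passes=False)])
    assert pairs == []


def test_antisense_in_intron_labeled_intronic_antisense():
    cod = tx("m", "+", 100, 10_000)
    lnc = tx("lnc", "-", 2_000, 3_000, "lncRNA")
    classes = [PositionalClass("lnc", "nonoverlapping_antisense", "m", 1000)]
    results = [de("lnc", 4.4, "down"), de("m", 2.5, "down")]
    pairs = antisense_pairs(classes, results, records={"m": cod, "lnc": lnc})
    assert pairs[0].relationship == "intronic_antisense"


def test_lincrna_one_neighbor_each_side():
    """A lincRNA between two DE coding genes yields two pairs, like the
    published AA388235 rows (one downstream, one upstream neighbor)."""
    lnc = tx("linc", "+", 1_000_000, 1_002_000, "lncRNA")
    left = tx("mup", "+", 890_000, 900_000)
    right = tx("mdn", "-", 1_202_000, 1_210_000)
    results = [de("linc", 66.9, "down"), de("mup", 5.8, "down"), de("mdn", 2.17, "up")]
    pairs = lincrna_neighbors([lnc], CodingIndex([left, right]), results)
    got = {(p.mrna_id, p.relationship, p.distance) for p in pairs}
    assert got == {("mup", "upstream", 100_000), ("mdn", "downstream", 200_000)}
    # mirrors the published pattern: same lincRNA, both sides, mixed directions
    assert {r.relationship for r in LINCRNA_PAIR_EXAMPLES} == {"upstream", "downstream"}


def test_lincrna_relationship_is_strand_relative():
    lnc = tx("linc", "-", 1_000_000, 1_002_000, "lncRNA")
    right = tx("m", "+", 1_052_000, 1_060_000)
    results = [de("linc", 4.0, "up"), de("m", 3.0, "up")]
    (pair,) = lincrna_neighbors([lnc], CodingIndex([right]), results)
    assert pair.relationship == "upstream"  # gene right of a minus-strand lincRNA


def test_neighbor_outside_window_is_ignored():
    lnc = tx("linc", "+", 1_000_000, 1_002_000, "lncRNA")
    far = tx("m", "+", 1_352_000, 1_360_000)  # 350 kb away
    results = [de("linc", 4.0, "up"), de("m", 3.0, "up")]
    assert lincrna_neighbors([lnc], CodingIndex([far]), results) == []
    # window monotonicity: enlarging the window only adds pairs
    small = lincrna_neighbors([lnc], CodingIndex([far]), results, window=100_000)
    large = lincrna_neighbors([lnc], CodingIndex([far]), results, window=400_000)
    assert set(small) <= set(large) and len(large) == 1


def test_nearest_de_neighbor_chosen_per_side():
    lnc = tx("linc", "+", 1_000_000, 1_002_000, "lncRNA")
    near = tx("m1", "+", 1_052_000, 1_060_000)
    nearer_but_not_de = tx("m2", "+", 1_010_000, 1_020_000)
    results = [de("linc", 4.0, "up"), de("m1", 3.0, "up"),
               de("m2", 1.1, "up", passes=False)]
    (pair,) = lincrna_neighbors([lnc], CodingIndex([near, nearer_but_not_de]), results)
    assert pair.mrna_id == "m1" and pair.distance == 50_000


def _pair(l_reg, m_reg, i=0):
    return CoexpressionPair(f"l{i}", f"m{i}", "downstream", 10, l_reg, m_reg)


def test_concordance_summary_fractions_and_identity():
    pairs = [_pair("down", "down", 0), _pair("down", "up", 1)]
    s = concordance_summary(pairs)
    assert s.frac_down_down == Fraction(1, 2)
    assert s.frac_down_up == Fraction(1, 2)
    assert s.frac_concordant == Fraction(1, 2)
    s2 = concordance_summary([_pair("up", "up", i) for i in range(3)])
    assert s2.frac_concordant == 1
    # closure and the concordant identity hold exactly (rational arithmetic)
    total = s.frac_up_up + s.frac_down_down + s.frac_up_down + s.frac_down_up
    assert total == 1
    assert s.frac_concordant == s.frac_up_up + s.frac_down_down


def test_concordance_summary_empty_input():
    with pytest.raises(EmptyInputError):
        concordance_summary([])


def test_planted_pairs_recovered_from_study(small_study):
    from lncarray.annotation import classify_all
    from lncarray.diffexpr import de_test
    from lncarray.normalize import quantile_normalize

    normalized = quantile_normalize(small_study.matrix)
    results = de_test(normalized, biotype_of=small_study.biotype_of)
    lncs = [r for r in small_study.records if r.biotype == "lncRNA"]
    classes = classify_all(lncs, small_study.records)
    rec_by_id = {r.transcript_id: r for r in small_study.records}
    intergenic = [rec_by_id[c.lncrna_id] for c in classes if c.category == "intergenic"]
    got = {
        (p.lncrna_id, p.mrna_id): p
        for p in lincrna_neighbors(intergenic, small_study.records, results)
    }
    passing = {r.transcript_id for r in results if r.passes_primary}
    planted = [p for p in small_study.truth.true_pairs
               if p.relationship in ("upstream", "downstream")]
    assert planted
    for truth_pair in planted:
        if truth_pair.lncrna_id in passing and truth_pair.mrna_id in passing:
            found = got[(truth_pair.lncrna_id, truth_pair.mrna_id)]
            assert found.relationship == truth_pair.relationship
            assert found.distance == truth_pair.distance
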