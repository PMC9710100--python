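import pytest

from lncarray.annotation import CATEGORIES, classify_all
from lncarray.qpcr import ddct
from lncarray.synthetic_data import (
    ConfigurationError,
    GroundTruth,
    PlacementError,
    SimulationConfig,
    simulate_expression,
    simulate_gene_sets,
    simulate_genome,
    simulate_qpcr,
)


def _cfg(**kw):
    base = dict(
        n_coding=40,
        n_lncrna=20,
        chrom_sizes={"chr1": 12_000_000, "chr2": 12_000_000},
        category_counts={},
        n_lincrna_pairs=0,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        _cfg(n_coding=-1)
    with pytest.raises(ConfigurationError):
        _cfg(planted_de_fraction=1.5)
    with pytest.raises(ConfigurationError):
        _cfg(planted_log2fc=0.5)  # below the FC>=2 identifiability floor
    with pytest.raises(ConfigurationError):
        _cfg(category_counts={"exotic": 1})
    with pytest.raises(ConfigurationError):
        _cfg(n_lncrna=2, category_counts={"intergenic": 5})


def test_expression_shape_and_positivity():
    cfg = _cfg(planted_de_fraction=0.1)
    matrix, truth = simulate_expression(cfg)
    assert matrix.values.shape == (60, 8)
    assert (matrix.values.to_numpy() > 0).all()
    assert set(truth.de_status) == set(matrix.probe_ids)


def test_zero_noise_fold_change_is_exact():
    cfg = _cfg(noise_sd=0.0, planted_de_fraction=0.1, planted_log2fc=2.0)
    matrix, truth = simulate_expression(cfg)
    for tx, status in truth.de_status.items():
        t = matrix.values.loc[tx, matrix.treatment_samples].mean()
        c = matrix.values.loc[tx, matrix.control_samples].mean()
        if status == "up":
            assert t / c == 4.0
        elif status == "down":
            assert c / t == 4.0
        else:
            assert t == c


def test_de_fraction_zero_means_all_null():
    _, truth = simulate_expression(_cfg(planted_de_fraction=0.0))
    assert set(truth.de_status.values()) == {"null"}


def test_expression_determinism():
    a, _ = simulate_expression(_cfg(seed=5))
    b, _ = simulate_expression(_cfg(seed=5))
    assert a.values.equals(b.values)
    c, _ = simulate_expression(_cfg(seed=6))
    assert not a.values.equals(c.values)


def test_genome_plants_every_category_recoverably():
    cfg = _cfg(
        n_lncrna=20,
        category_counts={c: 2 for c in CATEGORIES},
        n_lincrna_pairs=3,
    )
    records, truth = simulate_genome(cfg)
    lncs = [r for r in records if r.biotype == "lncRNA"]
    got = {c.lncrna_id: c.category for c in classify_all(lncs, records)}
    assert truth.true_category  # 12 category plants + 3 pair plants
    for tx, cat in truth.true_category.items():
        assert got[tx] == cat
    counts = {c: 0 for c in CATEGORIES}
    for cat in truth.true_category.values():
        counts[cat] += 1
    assert counts == {
        "sense_overlapping": 2, "intronic": 2, "natural_antisense": 2,
        "nonoverlapping_antisense": 2, "bidirectional": 2,
        "intergenic": 2 + 3,  # lincRNA-pair plants classify intergenic
    }


def test_intergenic_plants_far_from_all_coding():
    cfg = _cfg(category_counts={"intergenic": 5}, n_lncrna=10)
    records, truth = simulate_genome(cfg)
    coding = [r for r in records if r.biotype == "coding"]
    for tx, cat in truth.true_category.items():
        assert cat == "intergenic"
        lnc = next(r for r in records if r.transcript_id == tx)
        for c in coding:  # brute-force distance scan
            if c.chrom != lnc.chrom:
                continue
            gap = max(c.start - lnc.end, lnc.start - c.end)
            assert gap > 300_000


def test_bidirectional_plant_matches_definition():
    cfg = _cfg(category_counts={"bidirectional": 1}, n_lncrna=5, n_coding=10)
    records, truth = simulate_genome(cfg)
    (tx,) = truth.true_category
    lncs = [r for r in records if r.transcript_id == tx]
    cls = classify_all(lncs, records)[0]
    assert cls.category == "bidirectional"
    assert cls.evidence is not None and cls.evidence < 1000


def test_category_counts_all_zero_gives_only_intergenicish_lncs():
    records, truth = simulate_genome(_cfg())
    assert truth.true_category == {}
    assert sum(r.biotype == "coding" for r in records) == 40
    assert sum(r.biotype == "lncRNA" for r in records) == 20


def test_placement_error_when_genome_too_small():
    with pytest.raises(PlacementError):
        simulate_genome(
            _cfg(chrom_sizes={"chr1": 2_000_000}, category_counts={"intergenic": 5},
                 n_lncrna=10)
        )


def test_genome_determinism():
    cfg = _cfg(category_counts={c: 1 for c in CATEGORIES}, n_lincrna_pairs=2)
    a, ta = simulate_genome(cfg)
    b, tb = simulate_genome(cfg)
    assert a == b
    assert ta.true_category == tb.true_category
    assert ta.true_pairs == tb.true_pairs


def test_lincrna_pairs_have_one_neighbor_within_window():
    cfg = _cfg(n_lincrna_pairs=6)
    records, truth = simulate_genome(cfg)
    by_id = {r.transcript_id: r for r in records}
    assert len(truth.true_pairs) == 6
    for pair in truth.true_pairs:
        lnc, cod = by_id[pair.lncrna_id], by_id[pair.mrna_id]
        assert lnc.chrom == cod.chrom
        gap = max(cod.start - lnc.end, lnc.start - cod.end)
        assert gap == pair.distance
        assert 0 < gap < 300_000
        # the planted partner is the only coding gene within the window
        others = [
            c for c in records
            if c.biotype == "coding" and c.chrom == lnc.chrom
            and c.transcript_id != cod.transcript_id
            and max(c.start - lnc.end, lnc.start - c.end) < 300_000
        ]
        assert others == []
        assert pair.concordant == (
            truth.de_status[pair.lncrna_id] == truth.de_status[pair.mrna_id]
        )


def test_concordant_fraction_planted_exactly():
    cfg = _cfg(n_lincrna_pairs=8, concordant_fraction=0.75)
    _, truth = simulate_genome(cfg)
    assert sum(p.concordant for p in truth.true_pairs) == 6


def test_qpcr_zero_noise_recovers_planted_fold_exactly():
    truth = GroundTruth(
        de_status={"up1": "up", "null1": "null"},
        log2fc={"up1": 2.0, "null1": 0.0},
    )
    table = simulate_qpcr(truth, n_replicates=4, noise_sd=0.0, seed=0)
    up = ddct(table, "up1")
    assert up.fold_vs_control == 4.0 and up.direction == "up"
    null = ddct(table, "null1")
    assert null.fold_vs_control == 1.0


def test_qpcr_determinism_and_validation():
    truth = GroundTruth(de_status={"a": "up"}, log2fc={"a": 2.0})
    t1 = simulate_qpcr(truth, seed=3, noise_sd=0.3)
    t2 = simulate_qpcr(truth, seed=3, noise_sd=0.3)
    assert t1.records.equals(t2.records)
    with pytest.raises(ConfigurationError):
        simulate_qpcr(truth, n_replicates=0)
    with pytest.raises(ConfigurationError):
        simulate_qpcr(truth, reference_gene="")


def test_gene_sets_cover_universe_and_enrichment_bias(rng):
    universe = [f"NM_{i:04d}" for i in range(200)]
    de = universe[:40]
    coll = simulate_gene_sets(universe, de, n_sets=10, n_enriched=2, seed=1)
    assert len(coll.sets) == 10
    for members in coll.sets.values():
        assert members <= coll.universe
    de_set = set(de)
    first = coll.sets["SET001"]
    assert len(first & de_set) / len(first) > len(de_set) / len(universe)


def test_study_end_to_end_truth_consistency(small_study):
    truth = small_study.truth
    ids = {r.transcript_id for r in small_study.records}
    assert set(small_study.matrix.probe_ids) == ids
    for pair in truth.true_pairs:
        assert pair.lncrna_id in ids and pair.mrna_id in ids
        assert truth.de_status[pair.lncrna_id] != "null"
        assert truth.de_status[pair.mrna_id] != "null"
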