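import json
import math

import numpy as np
import pandas as pd
import pytest
import yaml

from lncarray.annotation import PositionalClass, TranscriptRecord
from lncarray.diffexpr import DEResult
from lncarray.normalize import ExpressionMatrix
from lncarray.report import (
    LENGTH_BINS,
    PipelineError,
    cluster_order,
    run_pipeline,
    summarize,
)


def _lnc(tid, length, chrom="chr1", start=1000):
    return TranscriptRecord(tid, f"g_{tid}", chrom, "+", start, start + length,
                            ((start, start + length),), "lncRNA")


def _de(tx, reg="up", fc=4.0, p=0.001, passes=True):
    return DEResult(tx, fc, reg, p, 0.01, passes, passes)


def test_length_bins_cover_and_label():
    labels = [name for name, _, _ in LENGTH_BINS]
    assert labels == ["<500", "500-1000", "1000-2000", "2000-3000", ">=3000"]


def test_summary_fractions():
    records = [_lnc("a", 1500), _lnc("b", 2500, chrom="chr4")]
    classes = [PositionalClass("a", "intergenic", None, None),
               PositionalClass("b", "natural_antisense", "m", 10)]
    de = [_de("a", "up"), _de("b", "down")]
    bundle = summarize(classes, de, records)
    assert bundle.length_histogram["all"] == {"1000-2000": 0.5, "2000-3000": 0.5}
    assert bundle.length_histogram["up"] == {"1000-2000": 1.0}
    assert bundle.chrom_distribution["all"] == {"chr1": 0.5, "chr4": 0.5}
    assert bundle.category_fractions["down"] == {"natural_antisense": 1.0}
    for mapping in (bundle.length_histogram, bundle.chrom_distribution,
                    bundle.category_fractions):
        for sub in mapping.values():
            if sub:
                assert math.fsum(sub.values()) == pytest.approx(1.0, abs=1e-9)


def test_summary_counts_only_primary_passing_lncrnas():
    records = [_lnc("a", 1500), _lnc("b", 900)]
    classes = [PositionalClass(t, "intergenic", None, None) for t in "ab"]
    de = [_de("a"), _de("b", passes=False)]
    bundle = summarize(classes, de, records)
    assert bundle.n_de_lncrnas == 1
    assert bundle.volcano_table.shape[0] == 2  # volcano covers all tested


def test_volcano_coordinates_signed():
    records = [_lnc("a", 1500), _lnc("b", 900)]
    classes = [PositionalClass(t, "intergenic", None, None) for t in "ab"]
    de = [_de("a", "up", fc=4.0, p=0.01), _de("b", "down", fc=2.0, p=0.1, passes=False)]
    volcano = summarize(classes, de, records).volcano_table.set_index("transcript_id")
    assert volcano.loc["a", "log2_fold_change"] == pytest.approx(2.0)
    assert volcano.loc["b", "log2_fold_change"] == pytest.approx(-1.0)
    assert volcano.loc["a", "neg_log10_p"] == pytest.approx(2.0)


def _block_matrix():
    """Two expression blocks: rows 0-2 high-in-treatment, rows 3-5 low."""
    up = np.array([[8.0, 8.1, 2.0, 2.1]])
    down = np.array([[2.0, 2.1, 8.0, 8.1]])
    arr = np.vstack([up + i * 0.01 for i in range(3)] + [down + i * 0.01 for i in range(3)])
    ids = [f"u{i}" for i in range(3)] + [f"d{i}" for i in range(3)]
    cols = ["t1", "t2", "c1", "c2"]
    groups = {"t1": "treatment", "t2": "treatment", "c1": "control", "c2": "control"}
    return ExpressionMatrix(pd.DataFrame(2.0 ** arr, index=ids, columns=cols), groups)


def test_cluster_order_groups_planted_blocks():
    rows, cols = cluster_order(_block_matrix())
    assert set(rows[:3]) in ({"u0", "u1", "u2"}, {"d0", "d1", "d2"})
    assert set(cols[:2]) in ({"t1", "t2"}, {"c1", "c2"})
    # deterministic
    assert cluster_order(_block_matrix()) == (rows, cols)


def test_cluster_order_drops_constant_rows():
    m = _block_matrix()
    values = m.values.copy()
    values.loc["flat"] = 16.0
    m2 = ExpressionMatrix(values, dict(m.group_of))
    rows, _ = cluster_order(m2)
    assert "flat" not in rows


def _write_config(tmp_path, **overrides):
    cfg = {
        "seed": 11,
        "output_dir": str(tmp_path / "out"),
        "simulation": {
            "n_coding": 120,
            "n_lncrna": 60,
            "chrom_sizes": {f"chr{i}": 12_000_000 for i in range(1, 7)},
            "category_counts": {
                "sense_overlapping": 3, "intronic": 3, "natural_antisense": 3,
                "nonoverlapping_antisense": 3, "bidirectional": 3, "intergenic": 6,
            },
            "n_lincrna_pairs": 8,
            "planted_de_fraction": 0.2,
        },
        "qpcr": {"n_genes": 5, "noise_sd": 0.1},
        "enrichment": {"n_sets": 8},
    }
    cfg.update(overrides)
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


EXPECTED_OUTPUTS = [
    "expression_raw.tsv", "expression_normalized.tsv", "groups.tsv",
    "annotation.gtf", "annotation.bed", "de_lncrna_all.tsv",
    "de_lncrna_primary.tsv", "de_lncrna_sensitivity.tsv", "de_mrna_all.tsv",
    "de_mrna_primary.tsv", "de_mrna_sensitivity.tsv", "classification.tsv",
    "antisense_pairs.tsv", "lincrna_pairs.tsv", "concordance.json",
    "enrichment_up.tsv", "enrichment_down.tsv", "qpcr_ct.csv",
    "qpcr_relative.tsv", "qpcr_concordance.tsv", "volcano.tsv",
    "summary.json", "run_log.txt",
]


def test_pipeline_smoke_writes_every_output(tmp_path):
    out = run_pipeline(_write_config(tmp_path))
    for name in EXPECTED_OUTPUTS:
        assert (out / name).exists(), name
    summary = json.loads((out / "summary.json").read_text())
    for mapping in ("length_histogram", "chrom_distribution", "category_fractions"):
        for sub in summary[mapping].values():
            if sub:
                assert math.fsum(sub.values()) == pytest.approx(1.0, abs=1e-9)
    concordance = json.loads((out / "concordance.json").read_text())
    for family in concordance.values():
        if family["n_pairs"]:
            assert family["frac_concordant"] == pytest.approx(
                family["frac_up_up"] + family["frac_down_down"], abs=1e-12
            )


def test_pipeline_sensitivity_table_is_fdr_filtered(tmp_path):
    out = run_pipeline(_write_config(tmp_path, de_regime="sensitivity"))
    sens = pd.read_csv(out / "de_lncrna_sensitivity.tsv", sep="\t")
    prim = pd.read_csv(out / "de_lncrna_primary.tsv", sep="\t")
    assert (sens["FDR"] < 0.05).all() and (sens["FoldChange"] >= 2.0).all()
    # sensitivity passes nest inside primary passes when fdr >= p
    if (sens["FDR"] >= sens["P"]).all():
        assert set(sens["Seqname"]) <= set(prim["Seqname"])


def test_pipeline_stage_named_error(tmp_path):
    cfg = tmp_path / "bad.yaml"
    cfg.write_text(yaml.safe_dump({
        "seed": 1,
        "output_dir": str(tmp_path / "out"),
        "inputs": {"expression": "missing.tsv", "groups": "missing.tsv",
                   "annotation": "missing.gtf"},
    }))
    with pytest.raises(PipelineError, match="inputs"):
        run_pipeline(cfg)


def test_cli_run_all_smoke(tmp_path):
    from click.testing import CliRunner

    from lncarray.cli import main

    cfg = _write_config(tmp_path)
    runner = CliRunner()
    result = runner.invoke(main, ["run-all", "--config", str(cfg),
                                  "--out", str(tmp_path / "cli_out")])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "cli_out" / "summary.json").exists()
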