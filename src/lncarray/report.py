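"""Descriptive summaries, clustering order and the end-to-end pipeline.

Summaries mirror the study's descriptive figures as data: the lncRNA length
histogram over fixed bins (<500, 500-1000, 1000-2000, 2000-3000, >=3000 nt),
the chromosome distribution, the six-way positional category fractions (up-
and downregulated reported separately), a volcano table (signed log2 fold
change, -log10 P) and hierarchical-clustering leaf orders (average linkage on
Euclidean distance of row-z-scored log2 values).

`run_pipeline` orchestrates simulation (or file inputs), normalization, DE,
classification, pairing, enrichment, qPCR and summaries from one declarative
YAML config and writes every table to an output directory.  With a fixed
seed the outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__
from .annotation import (
    CodingIndex,
    PositionalClass,
    TranscriptRecord,
    classify_all,
    read_gtf,
    write_bed12,
    write_classes_tsv,
    write_gtf,
)
from .coexpress import (
    NEIGHBOR_WINDOW,
    antisense_pairs,
    concordance_summary,
    lincrna_neighbors,
    write_pairs_tsv,
)
from .diffexpr import DEResult, de_test, write_de_tsv
from .enrich import hypergeom_enrich, read_gmt, split_by_regulation, write_enrichment_tsv
from .normalize import (
    ExpressionMatrix,
    quantile_normalize,
    read_expression_tsv,
    read_groups_tsv,
    write_expression_tsv,
    write_groups_tsv,
)
from .qpcr import concordance_with_array, ddct, read_ct_csv, write_ct_csv, write_relative_tsv
from .synthetic_data import (
    SimulationConfig,
    simulate_gene_sets,
    simulate_qpcr,
    simulate_study,
)

logger = logging.getLogger(__name__)

LENGTH_BINS: tuple[tuple[str, float, float], ...] = (
    ("<500", 0, 500),
    ("500-1000", 500, 1000),
    ("1000-2000", 1000, 2000),
    ("2000-3000", 2000, 3000),
    (">=3000", 3000, math.inf),
)

__all__ = ["LENGTH_BINS", "SummaryBundle", "summarize", "cluster_order",
           "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SummaryBundle:
    """Fractions and coordinates behind the study's descriptive figures.

    Each mapping holds "up", "down" and "all" sub-mappings whose fractions
    sum to 1 over the differentially expressed lncRNAs counted.
    """

    length_histogram: dict[str, dict[str, float]]
    chrom_distribution: dict[str, dict[str, float]]
    category_fractions: dict[str, dict[str, float]]
    volcano_table: pd.DataFrame
    cluster_order: tuple[list[str], list[str]] | None = None
    n_de_lncrnas: int = 0


def _fractions(values: Iterable[str], keys: Sequence[str] | None = None) -> dict[str, float]:
    values = list(values)
    total = len(values)
    if total == 0:
        return {}
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    keys = list(keys) if keys is not None else sorted(counts)
    return {k: counts.get(k, 0) / total for k in keys}


def _length_bin(length: int) -> str:
    for name, lo, hi in LENGTH_BINS:
        if lo <= length < hi:
            return name
    raise AssertionError(length)


def summarize(
    classes: Iterable[PositionalClass],
    de: Iterable[DEResult],
    annotation: Iterable[TranscriptRecord],
) -> SummaryBundle:
    """Descriptive summaries over primary-filter DE lncRNAs."""
    records = {r.transcript_id: r for r in annotation}
    de = list(de)
    category_of = {c.lncrna_id: c.category for c in classes}

    de_lnc = [
        r for r in de
        if r.passes_primary and records.get(r.transcript_id) is not None
        and records[r.transcript_id].biotype == "lncRNA"
    ]
    if not de_lnc:
        logger.warning("no differentially expressed lncRNAs to summarize")

    def by_direction(selector) -> dict[str, dict[str, float]]:
        out = {}
        for key, rows in (
            ("up", [r for r in de_lnc if r.regulation == "up"]),
            ("down", [r for r in de_lnc if r.regulation == "down"]),
            ("all", de_lnc),
        ):
            out[key] = _fractions([selector(r) for r in rows])
        return out

    length_histogram = by_direction(lambda r: _length_bin(records[r.transcript_id].length))
    chrom_distribution = by_direction(lambda r: records[r.transcript_id].chrom)
    category_fractions = by_direction(
        lambda r: category_of.get(r.transcript_id, "intergenic")
    )

    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in de],
                "log2_fold_change": [
                    (1 if r.regulation == "up" else -1) * math.log2(r.fold_change)
                    for r in de
                ],
                "neg_log10_p": [
                    -math.log10(r.p_value) if r.p_value > 0 else math.inf for r in de
                ],
            }
        )
    return SummaryBundle(
        length_histogram=length_histogram,
        chrom_distribution=chrom_distribution,
        category_fractions=category_fractions,
        volcano_table=volcano,
        n_de_lncrnas=len(de_lnc),
    )


def cluster_order(matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Agglomerative leaf orders for transcripts and samples.

    Average linkage on Euclidean distances of row-z-scored log2 intensities;
    zero-variance rows are dropped with a warning.  Deterministic for a fixed
    input.
    """
    log2 = matrix.log2()
    sd = log2.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant transcripts before clustering",
                       int((~keep).sum()))
    log2 = log2.loc[keep]
    if log2.shape[0] < 2 or log2.shape[1] < 2:
        raise ValueError("clustering needs >= 2 transcripts and >= 2 samples")
    z = log2.sub(log2.mean(axis=1), axis=0).div(log2.std(axis=1, ddof=0), axis=0)

    row_order = leaves_list(linkage(z.to_numpy(), method="average", metric="euclidean"))
    col_order = leaves_list(linkage(z.to_numpy().T, method="average", metric="euclidean"))
    return (
        [log2.index[i] for i in row_order],
        [log2.columns[j] for j in col_order],
    )


# ---------------------------------------------------------------------------
# pipeline


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


DEFAULT_THRESHOLDS = {
    "fc_min": 2.0,
    "p_max": 0.05,
    "fdr_max": 0.05,
    "bidirectional_window": 1000,
    "neighbor_window": NEIGHBOR_WINDOW,
}


def run_pipeline(config_path: str | Path, output_dir: str | Path | None = None) -> Path:
    """Run every stage from a YAML config; returns the output directory."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}

    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "lncarray_results"))
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    regime = cfg.get("de_regime", "primary")
    if regime not in ("primary", "sensitivity"):
        raise PipelineError("config", ValueError(f"unknown de_regime {regime!r}"))

    # ---- inputs -----------------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        if "simulation" in cfg:
            sim_cfg = SimulationConfig(**{**(cfg["simulation"] or {}), "seed": seed})
            study = simulate_study(sim_cfg)
            return study.matrix, study.records, study
        paths = cfg.get("inputs") or {}
        for key in ("expression", "groups", "annotation"):
            if key not in paths:
                raise FileNotFoundError(f"config lacks inputs.{key}")
        groups = read_groups_tsv(paths["groups"])
        matrix = read_expression_tsv(paths["expression"], groups)
        records = read_gtf(paths["annotation"])
        return matrix, records, None

    matrix, records, study = load_inputs()
    biotype_of = {r.transcript_id: r.biotype for r in records}
    lncs = [r for r in records if r.biotype == "lncRNA"]
    coding = CodingIndex(records)

    write_expression_tsv(matrix, out / "expression_raw.tsv")
    write_groups_tsv(matrix.group_of, out / "groups.tsv")
    write_gtf(records, out / "annotation.gtf")
    write_bed12(records, out / "annotation.bed")

    # ---- normalization ----------------------------------------------------
    @_stage("normalize")
    def do_normalize():
        normalized = quantile_normalize(matrix)
        write_expression_tsv(normalized, out / "expression_normalized.tsv")
        return normalized

    normalized = do_normalize()

    # ---- differential expression ------------------------------------------
    @_stage("diffexpr")
    def do_de():
        results = de_test(
            normalized,
            biotype_of=biotype_of,
            fc_min=thresholds["fc_min"],
            p_max=thresholds["p_max"],
            fdr_max=thresholds["fdr_max"],
        )
        lnc_res = [r for r in results if biotype_of.get(r.transcript_id) == "lncRNA"]
        mrna_res = [r for r in results if biotype_of.get(r.transcript_id) == "coding"]
        for name, rows in (("lncrna", lnc_res), ("mrna", mrna_res)):
            write_de_tsv(rows, out / f"de_{name}_all.tsv")
            for reg in ("primary", "sensitivity"):
                write_de_tsv(rows, out / f"de_{name}_{reg}.tsv", only_passing=reg)
        return results, lnc_res, mrna_res

    de_results, lnc_results, mrna_results = do_de()

    # ---- classification ----------------------------------------------------
    @_stage("classify")
    def do_classify():
        classes = classify_all(
            lncs, coding, bidirectional_window=thresholds["bidirectional_window"]
        )
        write_classes_tsv(classes, out / "classification.tsv")
        return classes

    classes = do_classify()

    # ---- coexpression pairs -------------------------------------------------
    @_stage("pairs")
    def do_pairs():
        rec_by_id = {r.transcript_id: r for r in records}
        anti = antisense_pairs(classes, de_results, records=rec_by_id)
        intergenic = [
            rec_by_id[c.lncrna_id] for c in classes if c.category == "intergenic"
        ]
        linc = lincrna_neighbors(
            intergenic, coding, de_results, window=thresholds["neighbor_window"]
        )
        write_pairs_tsv(anti, de_results, out / "antisense_pairs.tsv")
        write_pairs_tsv(linc, de_results, out / "lincrna_pairs.tsv")
        payload = {}
        for name, pairs in (("antisense", anti), ("lincrna", linc)):
            if pairs:
                s = concordance_summary(pairs)
                payload[name] = {
                    "n_pairs": s.n_pairs,
                    "frac_up_up": float(s.frac_up_up),
                    "frac_down_down": float(s.frac_down_down),
                    "frac_up_down": float(s.frac_up_down),
                    "frac_down_up": float(s.frac_down_up),
                    "frac_concordant": float(s.frac_concordant),
                }
            else:
                payload[name] = {"n_pairs": 0}
        (out / "concordance.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return anti, linc

    anti_pairs, linc_pairs = do_pairs()

    # ---- enrichment ---------------------------------------------------------
    @_stage("enrich")
    def do_enrich():
        universe = [r.transcript_id for r in records if r.biotype == "coding"]
        up, down = split_by_regulation(mrna_results)
        if "simulation" in cfg:
            enr_cfg = cfg.get("enrichment") or {}
            collection = simulate_gene_sets(
                universe,
                de_genes=sorted(up | down),
                n_sets=int(enr_cfg.get("n_sets", 20)),
                seed=seed + 3,
            )
        else:
            gmt = (cfg.get("inputs") or {}).get("gene_sets")
            if gmt is None:
                logger.info("no gene sets supplied; enrichment skipped")
                return None
            collection = read_gmt(gmt, universe)
        for name, genes in (("up", up), ("down", down)):
            if genes:
                write_enrichment_tsv(
                    hypergeom_enrich(genes, collection), out / f"enrichment_{name}.tsv"
                )
        return collection

    do_enrich()

    # ---- qPCR ---------------------------------------------------------------
    @_stage("qpcr")
    def do_qpcr():
        qcfg = cfg.get("qpcr") or {}
        if "simulation" in cfg:
            if study is None:
                return None
            rng = np.random.default_rng(seed + 4)
            de_ids = sorted(
                tx for tx, s in study.truth.de_status.items() if s != "null"
            )
            n_genes = min(int(qcfg.get("n_genes", 9)), len(de_ids))
            genes = sorted(rng.choice(de_ids, size=n_genes, replace=False)) if n_genes else []
            table = simulate_qpcr(
                study.truth,
                n_replicates=int(qcfg.get("n_replicates", 4)),
                noise_sd=float(qcfg.get("noise_sd", 0.25)),
                seed=seed + 5,
                genes=genes,
            )
        else:
            ct_path = (cfg.get("inputs") or {}).get("ct_table")
            if ct_path is None:
                logger.info("no Ct table supplied; qPCR skipped")
                return None
            table = read_ct_csv(ct_path, qcfg.get("reference_gene", "Gapdh"))
        write_ct_csv(table, out / "qpcr_ct.csv")
        rels = [ddct(table, g) for g in table.genes]
        write_relative_tsv(rels, out / "qpcr_relative.tsv")
        conc = concordance_with_array(rels, de_results)
        pd.DataFrame(
            {"gene_id": list(conc), "concordant_with_array": [conc[g] for g in conc]}
        ).to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False)
        return rels

    do_qpcr()

    # ---- summaries ----------------------------------------------------------
    @_stage("summarize")
    def do_summary():
        bundle = summarize(classes, [*lnc_results, *mrna_results], records)
        de_ids = [r.transcript_id for r in de_results if r.passes_primary]
        if len(de_ids) >= 2:
            bundle.cluster_order = cluster_order(normalized.subset(de_ids))
        bundle.volcano_table.to_csv(out / "volcano.tsv", sep="\t", index=False)
        payload = {
            "n_de_lncrnas": bundle.n_de_lncrnas,
            "length_histogram": bundle.length_histogram,
            "chrom_distribution": bundle.chrom_distribution,
            "category_fractions": bundle.category_fractions,
            "cluster_transcript_order": bundle.cluster_order[0] if bundle.cluster_order else [],
            "cluster_sample_order": bundle.cluster_order[1] if bundle.cluster_order else [],
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return bundle

    do_summary()

    log_lines = [
        f"lncarray {__version__}",
        f"seed: {seed}",
        f"regime: {regime}",
        f"thresholds: {json.dumps(thresholds, sort_keys=True)}",
        f"config: {json.dumps(cfg, sort_keys=True, default=str)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline complete: %s", out)
    return out
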