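"""Synthetic two-strain expression study with known ground truth.

Emulates the design of the original experiment — two inbred mouse strains
(DBA/1-like "treatment" vs C57BL/6-like "control"), four arrays per group —
with log-normal intensities, planted fold changes in both directions, a toy
genome in which every positional lncRNA category is planted so the classifier
must recover it, planted lincRNA-neighbor pairs with a known
direction-concordance fraction, and matching qPCR Ct tables.

All randomness flows from ``SimulationConfig.seed`` through a single
:class:`numpy.random.Generator`; identical configs give byte-identical
outputs.

Geometry of the toy genome: planted structures live in private 1 Mb blocks so
ground truth is unambiguous — a category plant shares its block only with its
partner coding gene; ``intergenic`` plants sit mid-block, > 300 kb from every
coding gene; lincRNA-pair plants sit mid-block with exactly one coding
neighbor at a planted gap < 300 kb.  Background coding genes and lncRNAs are
packed into shared blocks at a 20 kb minimum spacing (no accidental overlap
or bidirectional geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, TranscriptRecord
from .normalize import CONTROL, TREATMENT, ExpressionMatrix
from .qpcr import CtTable

BLOCK = 1_000_000  # bp; one planted unit per block
_PACK_GAP = 20_000  # bp between packed background genes
_PACK_START = 10_000
_PACK_END = 980_000

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedPair",
    "SimulatedStudy",
    "simulate_expression",
    "simulate_genome",
    "simulate_gene_sets",
    "simulate_qpcr",
    "simulate_study",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


class PlacementError(ValueError):
    """Raised when the toy genome cannot hold the requested structures."""


def _default_chrom_sizes() -> dict[str, int]:
    sizes = {f"chr{i}": 15_000_000 for i in range(1, 20)}
    sizes["chrX"] = 15_000_000
    return sizes


def _default_category_counts() -> dict[str, int]:
    return {
        "sense_overlapping": 20,
        "intronic": 10,
        "natural_antisense": 12,
        "nonoverlapping_antisense": 8,
        "bidirectional": 10,
        "intergenic": 60,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults are the study conditions: 4 samples per group, fold-change
    effects of 2^2 = 4 (comfortably above the FC >= 2 filter), microarray-like
    log2 intensities around 8 with noise_sd in log2 units, and a concordant
    fraction of 0.685 for planted cis pairs (the fraction reported for the
    real lincRNA-neighbor pairs).  Transcript counts are a desk-scale
    stand-in for the 24,881-coding / 35,923-lncRNA array.
    """

    n_coding: int = 1500
    n_lncrna: int = 500
    n_samples_per_group: int = 4
    planted_de_fraction: float = 0.05
    planted_log2fc: float = 2.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 8.0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    category_counts: dict[str, int] = field(default_factory=_default_category_counts)
    n_lincrna_pairs: int = 40
    concordant_fraction: float = 0.685
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_lncrna", "n_samples_per_group", "n_lincrna_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_samples_per_group < 1:
            raise ConfigurationError("n_samples_per_group must be >= 1")
        for name in ("planted_de_fraction", "concordant_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.planted_log2fc < 1.0:
            raise ConfigurationError(
                "planted_log2fc must be >= 1 so planted effects exceed FC >= 2"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.category_counts.values()):
            raise ConfigurationError("category counts must be >= 0")
        if not self.chrom_sizes:
            raise ConfigurationError("chrom_sizes must be non-empty")
        n_partnered = sum(
            self.category_counts.get(c, 0) for c in CATEGORIES if c != "intergenic"
        )
        if n_partnered + self.n_lincrna_pairs > self.n_coding:
            raise ConfigurationError("n_coding too small for the planted partners")
        if sum(self.category_counts.values()) + self.n_lincrna_pairs > self.n_lncrna:
            raise ConfigurationError("n_lncrna too small for the planted categories")


@dataclass(frozen=True)
class PlantedPair:
    """One planted cis pair with its intended direction pattern."""

    lncrna_id: str
    mrna_id: str
    relationship: str  # natural_antisense / nonoverlapping_antisense / upstream / downstream
    concordant: bool
    distance: int  # bp boundary gap, 0 for overlapping relationships


@dataclass
class GroundTruth:
    """Planted truth for a simulated study.

    ``de_status`` maps every transcript to "up", "down" or "null";
    ``log2fc`` holds the signed planted log2 fold change (0 for null);
    ``true_category`` maps each planted lncRNA to its positional category;
    ``true_pairs`` lists planted cis pairs with their concordance flags.
    """

    de_status: dict[str, str] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    true_category: dict[str, str] = field(default_factory=dict)
    true_pairs: list[PlantedPair] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    records: list[TranscriptRecord]
    matrix: ExpressionMatrix
    truth: GroundTruth
    biotype_of: dict[str, str]


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    config: SimulationConfig,
    transcript_ids: Sequence[str] | None = None,
    forced_status: Mapping[str, str] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a probe x sample intensity matrix with planted fold changes.

    Null transcripts share a log-normal intensity model (Gaussian on log2,
    exponentiated); DE transcripts are shifted by +/- ``planted_log2fc`` in
    the treatment group.  ``forced_status`` pins the direction of specific
    transcripts (used when the matrix accompanies a simulated genome); the
    remaining DE transcripts, up to ``planted_de_fraction`` of the total, are
    drawn at random with equiprobable directions.
    """
    rng = np.random.default_rng(config.seed)
    if transcript_ids is None:
        ids = [f"NM_{i:06d}" for i in range(1, config.n_coding + 1)]
        ids += [f"NR_{i:06d}" for i in range(1, config.n_lncrna + 1)]
    else:
        ids = list(transcript_ids)
    n = len(ids)
    if n == 0:
        raise ConfigurationError("no transcripts to simulate")

    forced = dict(forced_status or {})
    unknown = set(forced) - set(ids)
    if unknown:
        raise ConfigurationError(f"forced transcripts not simulated: {sorted(unknown)}")

    n_de = max(len(forced), int(round(config.planted_de_fraction * n)))
    status = {tx: "null" for tx in ids}
    status.update(forced)
    free = [tx for tx in ids if tx not in forced]
    extra = n_de - len(forced)
    if extra > 0:
        chosen = rng.choice(len(free), size=min(extra, len(free)), replace=False)
        directions = rng.random(len(chosen)) < 0.5
        for idx, is_up in zip(chosen, directions):
            status[free[idx]] = "up" if is_up else "down"

    sign = {"up": 1.0, "down": -1.0, "null": 0.0}
    log2fc = {tx: sign[status[tx]] * config.planted_log2fc for tx in ids}

    n_per = config.n_samples_per_group
    samples = [f"D1_{i + 1}" for i in range(n_per)] + [f"B6_{i + 1}" for i in range(n_per)]
    group_of = {s: (TREATMENT if s.startswith("D1") else CONTROL) for s in samples}

    baseline = rng.normal(config.baseline_log2_mean, 1.5, size=n)
    shift = np.array([log2fc[tx] for tx in ids])
    log2_means = np.column_stack(
        [baseline + shift] * n_per + [baseline] * n_per
    )
    noise = (
        rng.normal(0.0, config.noise_sd, size=log2_means.shape)
        if config.noise_sd > 0
        else 0.0
    )
    values = pd.DataFrame(2.0 ** (log2_means + noise), index=ids, columns=samples)
    matrix = ExpressionMatrix(values, group_of)
    return matrix, GroundTruth(de_status=status, log2fc=log2fc)


# ---------------------------------------------------------------------------
# genome

def _coding_exons(start: int, length: int) -> tuple[tuple[int, int], ...]:
    """Three exons spanning [start, start+length) with two introns."""
    e1 = (start, start + length // 5)
    e2 = (start + 2 * length // 5, start + 3 * length // 5)
    e3 = (start + 4 * length // 5, start + length)
    return (e1, e2, e3)


class _BlockAllocator:
    def __init__(self, chrom_sizes: Mapping[str, int]):
        self._blocks: list[tuple[str, int]] = []
        for chrom in chrom_sizes:
            for b in range(chrom_sizes[chrom] // BLOCK):
                self._blocks.append((chrom, b * BLOCK))
        self._next = 0

    def take(self) -> tuple[str, int]:
        if self._next >= len(self._blocks):
            raise PlacementError(
                "chromosomes too short to place the requested structures"
            )
        chrom, start = self._blocks[self._next]
        self._next += 1
        return chrom, start


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Build a toy annotation planting every requested positional category.

    Each planted lncRNA is placed so the positional classifier must recover
    its category; ``intergenic`` plants lie > 300 kb and > 1000 bp from every
    coding gene; lincRNA-pair plants (see ``n_lincrna_pairs``) are intergenic
    by classification but carry exactly one coding neighbor at a planted
    boundary gap drawn from [5, 250] kb.  The ground truth also pins DE
    directions for every planted lncRNA and pair partner so the downstream
    pairing stages see the planted concordance pattern.
    """
    rng = np.random.default_rng(config.seed + 1)
    alloc = _BlockAllocator(config.chrom_sizes)

    records: list[TranscriptRecord] = []
    truth = GroundTruth()

    coding_idx = 0
    lnc_idx = 0

    def next_coding() -> tuple[str, str]:
        nonlocal coding_idx
        coding_idx += 1
        return f"NM_{coding_idx:06d}", f"GC{coding_idx:06d}"

    def next_lnc() -> tuple[str, str]:
        nonlocal lnc_idx
        lnc_idx += 1
        return f"NR_{lnc_idx:06d}", f"GL{lnc_idx:06d}"

    # planted units in a seed-shuffled order so categories spread over chroms
    units: list[tuple[str, int]] = []
    for cat in CATEGORIES:
        units += [(cat, i) for i in range(config.category_counts.get(cat, 0))]
    units += [("lincrna_pair", i) for i in range(config.n_lincrna_pairs)]
    units = [units[i] for i in rng.permutation(len(units))] if units else []

    antisense_pairs: list[tuple[str, str, str]] = []  # (lnc, mrna, relationship)
    lincrna_pairs: list[tuple[str, str, str, int]] = []  # + relationship, distance

    def rand_dir() -> str:
        return "up" if rng.random() < 0.5 else "down"

    for cat, _ in units:
        chrom, u = alloc.take()
        cs = "+" if rng.random() < 0.5 else "-"
        if cat == "intergenic":
            length = int(rng.integers(400, 4000))
            ls = "+" if rng.random() < 0.5 else "-"
            s = u + 500_000
            lnc_tx, lnc_gene = next_lnc()
            records.append(
                TranscriptRecord(lnc_tx, lnc_gene, chrom, ls, s, s + length,
                                 ((s, s + length),), "lncRNA")
            )
            truth.true_category[lnc_tx] = "intergenic"
            truth.de_status[lnc_tx] = rand_dir()
            continue
        if cat == "lincrna_pair":
            lnc_tx, lnc_gene = next_lnc()
            cod_tx, cod_gene = next_coding()
            s = u + 350_000
            lnc_len = int(rng.integers(400, 4000))
            records.append(
                TranscriptRecord(lnc_tx, lnc_gene, chrom, "+", s, s + lnc_len,
                                 ((s, s + lnc_len),), "lncRNA")
            )
            gap = int(rng.integers(5_000, 250_001))
            glen = 20_000
            if rng.random() < 0.5:  # coding downstream of the + strand lincRNA
                gstart = s + lnc_len + gap
                relationship = "downstream"
            else:
                gstart = s - gap - glen
                relationship = "upstream"
            records.append(
                TranscriptRecord(cod_tx, cod_gene, chrom, cs, gstart, gstart + glen,
                                 _coding_exons(gstart, glen), "coding")
            )
            truth.true_category[lnc_tx] = "intergenic"
            lincrna_pairs.append((lnc_tx, cod_tx, relationship, gap))
            continue

        # categories defined relative to one partner coding gene
        cod_tx, cod_gene = next_coding()
        gstart = u + 10_000
        glen = 20_000
        records.append(
            TranscriptRecord(cod_tx, cod_gene, chrom, cs, gstart, gstart + glen,
                             _coding_exons(gstart, glen), "coding")
        )
        anti = "-" if cs == "+" else "+"
        lnc_tx, lnc_gene = next_lnc()
        if cat == "sense_overlapping":
            s, e, ls = u + 11_000, u + 13_000, cs
        elif cat == "intronic":
            s, e, ls = u + 15_000, u + 17_000, cs
        elif cat == "natural_antisense":
            s, e, ls = u + 11_000, u + 13_000, anti
        elif cat == "nonoverlapping_antisense":
            s, e, ls = u + 15_000, u + 17_000, anti
        elif cat == "bidirectional":
            if cs == "+":
                s, e, ls = u + 5_000, u + 9_600, "-"  # 5' gap 400 bp
            else:
                s, e, ls = u + 30_400, u + 35_000, "+"
        else:  # pragma: no cover - exhaustive over CATEGORIES
            raise AssertionError(cat)
        records.append(
            TranscriptRecord(lnc_tx, lnc_gene, chrom, ls, s, e, ((s, e),), "lncRNA")
        )
        truth.true_category[lnc_tx] = cat
        truth.de_status[lnc_tx] = rand_dir()
        if cat in ("natural_antisense", "nonoverlapping_antisense"):
            antisense_pairs.append((lnc_tx, cod_tx, cat))

    # direction-concordance planting: exact counts per pair family
    def plant_directions(pairs: list, distances: bool) -> None:
        n = len(pairs)
        if n == 0:
            return
        n_conc = int(round(config.concordant_fraction * n))
        flags = np.array([True] * n_conc + [False] * (n - n_conc))
        flags = flags[rng.permutation(n)]
        for item, conc in zip(pairs, flags):
            if distances:
                lnc_tx, cod_tx, relationship, dist = item
            else:
                lnc_tx, cod_tx, relationship = item
                dist = 0
            lnc_dir = truth.de_status.get(lnc_tx) or rand_dir()
            mrna_dir = lnc_dir if conc else ("down" if lnc_dir == "up" else "up")
            truth.de_status[lnc_tx] = lnc_dir
            truth.de_status[cod_tx] = mrna_dir
            truth.true_pairs.append(
                PlantedPair(lnc_tx, cod_tx, relationship, bool(conc), dist)
            )

    plant_directions(antisense_pairs, distances=False)
    plant_directions(lincrna_pairs, distances=True)

    # background transcripts packed into shared blocks
    def pack(n: int, draw, place) -> None:
        if n == 0:
            return
        cur_chrom, cur_u = alloc.take()
        cur = cur_u + _PACK_START
        for _ in range(n):
            span, params = draw()
            if cur + span > cur_u + _PACK_END:
                cur_chrom, cur_u = alloc.take()
                cur = cur_u + _PACK_START
            place(cur_chrom, cur, span, params)
            cur += span + _PACK_GAP

    def draw_coding() -> tuple[int, str]:
        glen = int(rng.integers(5_000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        return glen, strand

    def place_coding(chrom: str, at: int, glen: int, strand: str) -> None:
        tx, gene = next_coding()
        records.append(
            TranscriptRecord(tx, gene, chrom, strand, at, at + glen,
                             _coding_exons(at, glen), "coding")
        )

    def draw_lnc() -> tuple[int, str]:
        length = int(2 ** rng.uniform(math.log2(300), math.log2(5000)))
        strand = "+" if rng.random() < 0.5 else "-"
        return length, strand

    def place_lnc(chrom: str, at: int, length: int, strand: str) -> None:
        tx, gene = next_lnc()
        records.append(
            TranscriptRecord(tx, gene, chrom, strand, at, at + length,
                             ((at, at + length),), "lncRNA")
        )

    pack(config.n_coding - coding_idx, draw_coding, place_coding)
    pack(config.n_lncrna - lnc_idx, draw_lnc, place_lnc)

    records.sort(key=lambda r: (r.chrom, r.start, r.transcript_id))
    return records, truth


# ---------------------------------------------------------------------------
# gene sets

def simulate_gene_sets(
    universe: Sequence[str],
    de_genes: Sequence[str] = (),
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    n_enriched: int = 2,
    enriched_de_fraction: float = 0.5,
    seed: int = 0,
):
    """Random gene sets over *universe*, a few biased toward *de_genes*.

    The first ``n_enriched`` sets draw ``enriched_de_fraction`` of their
    members from the DE list (true over-representation); the rest are uniform
    draws (null sets).  Returns a :class:`lncarray.enrich.GeneSetCollection`.
    """
    from .enrich import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(universe)
    de = [g for g in de_genes if g in set(universe)]
    non_de = sorted(set(universe) - set(de))
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        if i < n_enriched and de:
            n_from_de = min(len(de), int(round(enriched_de_fraction * size)))
            members = list(rng.choice(de, size=n_from_de, replace=False))
            members += list(
                rng.choice(non_de, size=min(size - n_from_de, len(non_de)), replace=False)
            )
        else:
            members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets[f"SET{i + 1:03d}"] = frozenset(members)
    return GeneSetCollection(sets, frozenset(universe))


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(
    de_truth: GroundTruth,
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    reference_gene: str = "Gapdh",
) -> CtTable:
    """Simulate a Ct table consistent with planted fold changes.

    Ct is modeled as ``offset - log2(abundance) + noise`` so the 2^-ddCt
    identity is exact at zero noise; higher planted expression gives lower Ct.
    The reference gene is measured in every sample.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if not reference_gene:
        raise ConfigurationError("a reference gene is required")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = sorted(de_truth.de_status)
    samples = [(f"qD1_{i + 1}", TREATMENT) for i in range(n_replicates)]
    samples += [(f"qB6_{i + 1}", CONTROL) for i in range(n_replicates)]

    offset = 35.0
    base = {g: float(rng.uniform(4.0, 12.0)) for g in genes}
    rows = []
    for sample, group in samples:
        ref_ct = offset - 10.0 + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"sample_id": sample, "group": group,
                     "gene_id": reference_gene, "ct": ref_ct})
        for g in genes:
            log2_abund = base[g]
            if group == TREATMENT:
                log2_abund += de_truth.log2fc.get(g, 0.0)
            ct = offset - log2_abund + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"sample_id": sample, "group": group, "gene_id": g, "ct": ct})
    return CtTable(pd.DataFrame(rows), reference_gene)


# ---------------------------------------------------------------------------
# full study

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Genome + matching expression matrix with merged ground truth."""
    records, genome_truth = simulate_genome(config)
    ids = [r.transcript_id for r in records]
    forced = {tx: d for tx, d in genome_truth.de_status.items() if d != "null"}
    matrix, expr_truth = simulate_expression(
        replace(config, seed=config.seed + 2), transcript_ids=ids, forced_status=forced
    )
    truth = GroundTruth(
        de_status=expr_truth.de_status,
        log2fc=expr_truth.log2fc,
        true_category=genome_truth.true_category,
        true_pairs=genome_truth.true_pairs,
    )
    biotype_of = {r.transcript_id: r.biotype for r in records}
    return SimulatedStudy(config, records, matrix, truth, biotype_of)
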