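"""Hypergeometric over-representation analysis against GMT gene sets.

For a DE gene list of size n drawn from a measured universe of size N, a set
with K members gets the upper-tail hypergeometric probability
P(X >= k) of observing at least the k hits seen, an enrichment score
(k/n)/(K/N), and a BH-adjusted q value over all sets in the collection.
The universe is the measured transcript set (array-conditioned), not the
whole genome.  Up- and downregulated lists are analyzed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import DEResult, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "hypergeom_enrich",
    "split_by_regulation",
    "read_gmt",
    "write_gmt",
    "write_enrichment_tsv",
]


class EmptyInputError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a measurement universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.sets = {
            name: frozenset(members) & self.universe
            for name, members in self.sets.items()
        }


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int  # hits in the DE list
    K: int  # set size
    n: int  # DE list size
    N: int  # universe size
    p_value: float
    fdr: float

    @property
    def enrichment_score(self) -> float:
        if self.K == 0 or self.n == 0:
            return 0.0
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_enrich(
    de_genes: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentRecord]:
    """One record per set, sorted by (p, -enrichment score, name).

    Genes outside the universe are dropped with a warning.
    """
    if not collection.universe:
        raise EmptyInputError("empty universe")
    genes = set(de_genes)
    outside = genes - collection.universe
    if outside:
        logger.warning("%d DE genes outside the universe dropped", len(outside))
        genes &= collection.universe
    if not genes:
        raise EmptyInputError("empty DE gene list")

    N, n = len(collection.universe), len(genes)
    raw = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(genes & members)
        p = 1.0 if K == 0 else float(hypergeom.sf(k - 1, N, K, n))
        raw.append((name, k, K, p))
    p_adj = bh_fdr([p for _, _, _, p in raw]) if raw else []
    records = [
        EnrichmentRecord(name, k, K, n, N, p, float(q))
        for (name, k, K, p), q in zip(raw, p_adj)
    ]
    records.sort(key=lambda r: (r.p_value, -r.enrichment_score, r.set_name))
    return records


def split_by_regulation(de: Iterable[DEResult]) -> tuple[set[str], set[str]]:
    """Disjoint (up, down) id sets over primary-filter passes."""
    up, down = set(), set()
    for r in de:
        if not r.passes_primary:
            continue
        (up if r.regulation == "up" else down).add(r.transcript_id)
    return up, down


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file (set name, description, members, tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {line_no}: GMT needs name, description, members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets, frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def write_enrichment_tsv(records: Iterable[EnrichmentRecord], path: str | Path) -> None:
    rows = [
        {
            "set_name": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "enrichment_score": r.enrichment_score,
            "p_value": r.p_value, "fdr": r.fdr,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["set_name", "k", "K", "n", "N", "enrichment_score", "p_value", "fdr"],
    ).to_csv(path, sep="\t", index=False)
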