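"""Relative quantification from qPCR Ct tables (2^-ddCt).

Expression of each target gene is normalized to an internal reference gene
(GAPDH in the original design) and reported relative to the control group,
whose mean relative expression is set to exactly 1: per sample,
dCt = Ct(target) - Ct(reference), the per-sample linear value is 2^-dCt, and
all values are divided by the control-group arithmetic mean.  At zero noise
this coincides with the classical 2^-ddCt formula with group-mean centering;
under noise the division guarantees the control mean is exactly 1.
Amplification efficiency is assumed to be 2.0 (perfect doubling).

Technical replicates (several Ct rows for one sample/gene) are averaged
before dCt is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .diffexpr import DEResult
from .normalize import CONTROL, TREATMENT

logger = logging.getLogger(__name__)

__all__ = ["CtTable", "RelativeExpression", "ddct", "concordance_with_array",
           "read_ct_csv", "write_ct_csv", "write_relative_tsv"]


class CtDataError(ValueError):
    """Raised when a Ct table violates its contract."""


@dataclass
class CtTable:
    """Long-format Ct measurements with a designated reference gene.

    ``records`` columns: sample_id, group (treatment/control), gene_id, ct.
    """

    records: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene_id", "ct"}
        if not required.issubset(self.records.columns):
            raise CtDataError(f"Ct table needs columns {sorted(required)}")
        if not (self.records["ct"] > 0).all():
            raise CtDataError("Ct values must be positive")
        bad = set(self.records["group"]) - {TREATMENT, CONTROL}
        if bad:
            raise CtDataError(f"unknown groups: {sorted(bad)}")
        samples = set(self.records["sample_id"])
        with_ref = set(
            self.records.loc[self.records["gene_id"] == self.reference_gene, "sample_id"]
        )
        if samples - with_ref:
            raise CtDataError(
                f"reference gene {self.reference_gene!r} missing in samples "
                f"{sorted(samples - with_ref)}"
            )

    def mean_ct(self) -> pd.DataFrame:
        """Technical replicates averaged: one row per (sample, gene)."""
        return (
            self.records.groupby(["sample_id", "group", "gene_id"], as_index=False)["ct"]
            .mean()
        )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.records["gene_id"]) - {self.reference_gene})


@dataclass(frozen=True)
class RelativeExpression:
    """Reference-normalized expression of one gene, control mean == 1."""

    gene_id: str
    fold_vs_control: float
    direction: str  # "up" | "down"
    per_sample_values: tuple[tuple[str, str, float], ...]  # (sample, group, value)


def ddct(table: CtTable, gene_id: str) -> RelativeExpression:
    """Relative expression of *gene_id* vs the control group."""
    means = table.mean_ct()
    ref = means[means["gene_id"] == table.reference_gene].set_index("sample_id")["ct"]
    tgt = means[means["gene_id"] == gene_id]
    if tgt.empty:
        raise CtDataError(f"gene {gene_id!r} absent from Ct table")
    for grp in (TREATMENT, CONTROL):
        if not (tgt["group"] == grp).any():
            raise CtDataError(f"gene {gene_id!r} has no {grp} samples")

    dct = tgt["ct"].to_numpy() - ref.loc[tgt["sample_id"]].to_numpy()
    linear = 2.0 ** (-dct)
    is_control = (tgt["group"] == CONTROL).to_numpy()
    rel = linear / linear[is_control].mean()

    fold = float(rel[~is_control].mean()) if (~is_control).any() else 1.0
    per_sample = tuple(
        (s, g, float(v))
        for s, g, v in zip(tgt["sample_id"], tgt["group"], rel)
    )
    return RelativeExpression(
        gene_id=gene_id,
        fold_vs_control=fold,
        direction="up" if fold >= 1.0 else "down",
        per_sample_values=per_sample,
    )


def concordance_with_array(
    rel: Iterable[RelativeExpression], de: Iterable[DEResult]
) -> dict[str, bool]:
    """True per gene iff the qPCR direction matches the array regulation."""
    de_by_id: Mapping[str, DEResult] = {r.transcript_id: r for r in de}
    out: dict[str, bool] = {}
    for r in rel:
        hit = de_by_id.get(r.gene_id)
        if hit is None:
            logger.warning("gene %s absent from array results; excluded", r.gene_id)
            continue
        out[r.gene_id] = r.direction == hit.regulation
    return out


def read_ct_csv(path: str | Path, reference_gene: str) -> CtTable:
    df = pd.read_csv(path)
    return CtTable(df, reference_gene)


def write_ct_csv(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def write_relative_tsv(rels: Iterable[RelativeExpression], path: str | Path) -> None:
    rows = [
        {"gene_id": r.gene_id, "fold_vs_control": r.fold_vs_control,
         "direction": r.direction}
        for r in rels
    ]
    pd.DataFrame(rows, columns=["gene_id", "fold_vs_control", "direction"]).to_csv(
        path, sep="\t", index=False
    )
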