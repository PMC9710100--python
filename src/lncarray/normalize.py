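"""Expression-matrix container and quantile normalization.

The quantile-normalization procedure equalizes the intensity distribution of
every array in a probe x sample matrix: each column is sorted ascending, the
mean across columns is taken at every rank, each value is replaced by the mean
for its rank, and the column is restored to its original probe order.  After
the transform every sample shares the same multiset of values (the rank-mean
vector) while within-column ranks are preserved.

Normalization operates on raw linear intensities; log2 transformation for
testing happens downstream (see :mod:`lncarray.diffexpr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TREATMENT = "treatment"
CONTROL = "control"

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "write_groups_tsv",
    "TREATMENT",
    "CONTROL",
]


class DataError(ValueError):
    """Raised when an input table violates the matrix contract."""


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity table with a two-group sample design.

    Parameters
    ----------
    values
        DataFrame of strictly positive intensities; index = probe/transcript
        ids (unique), columns = sample ids (unique).
    group_of
        Mapping from every sample id to ``"treatment"`` or ``"control"``.
    """

    values: pd.DataFrame
    group_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise DataError("duplicate probe ids")
        if v.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        if v.isna().to_numpy().any():
            raise DataError("missing values in expression matrix")
        if not (v.to_numpy(dtype=float) > 0).all():
            raise DataError("intensities must be strictly positive")
        missing = set(v.columns) - set(self.group_of)
        if missing:
            raise DataError(f"samples without a group label: {sorted(missing)}")
        bad = {g for g in self.group_of.values() if g not in (TREATMENT, CONTROL)}
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    @property
    def treatment_samples(self) -> list[str]:
        return self.samples_in(TREATMENT)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(CONTROL)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(probe_ids)
        return ExpressionMatrix(self.values.loc[ids], dict(self.group_of))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a quantile-normalized copy of *matrix*.

    Every output column holds the same values — the per-rank means of the
    column-sorted input — rearranged to the input's within-column order.
    Tied input values receive the mean of the rank-means of their tied
    positions, which makes the result independent of the arbitrary sort order
    among ties and makes the transform idempotent.
    """
    v = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = v.shape
    if n_probes == 0 or n_samples == 0:
        raise DataError("empty expression matrix")
    if n_samples == 1:
        return ExpressionMatrix(matrix.values.copy(), dict(matrix.group_of))

    # mean across samples at each ascending rank
    rank_means = np.sort(v, axis=0).mean(axis=1)

    out = np.empty_like(v)
    for j in range(n_samples):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_probes)
        assigned[order] = rank_means
        # average the rank-means over tied input values
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n_probes:
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned

    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, dict(matrix.group_of))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: first column transcript id, header = samples."""
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")


def read_expression_tsv(
    path: str | Path, group_of: Mapping[str, str]
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return ExpressionMatrix(values, dict(group_of))


def write_groups_tsv(group_of: Mapping[str, str], path: str | Path) -> None:
    """Two-column sample-to-group mapping (sample_id, group)."""
    df = pd.DataFrame(
        {"sample_id": list(group_of), "group": [group_of[s] for s in group_of]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise DataError("group mapping must have columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))
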