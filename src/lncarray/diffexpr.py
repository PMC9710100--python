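"""Two-group differential expression with fold-change / P / FDR filters.

Per transcript: linear fold change between group means of normalized
intensities (reported >= 1 with an up/down label, treatment vs control),
a Welch unequal-variance t-test on log2 intensities, and Benjamini-Hochberg
FDR.  Two filter regimes are applied:

* primary      — fold change >= 2.0 and P < 0.05
* sensitivity  — fold change >= 2.0 and FDR < 0.05

lncRNAs and mRNAs are corrected as separate BH families by default (they are
reported as separate result sets); pass ``fdr_family="joint"`` for a single
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import ExpressionMatrix

FC_MIN = 2.0
P_MAX = 0.05
FDR_MAX = 0.05

__all__ = ["DEResult", "fold_change", "de_test", "bh_fdr", "write_de_tsv",
           "FC_MIN", "P_MAX", "FDR_MAX"]


class StatisticsError(ValueError):
    """Raised when the design cannot support the requested statistic."""


@dataclass(frozen=True)
class DEResult:
    """Per-transcript differential-expression outcome."""

    transcript_id: str
    fold_change: float  # linear ratio >= 1, direction in `regulation`
    regulation: str  # "up" | "down" (treatment vs control)
    p_value: float
    fdr: float
    passes_primary: bool
    passes_sensitivity: bool


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    matrix: ExpressionMatrix, transcript_id: str
) -> tuple[float, str]:
    """Linear fold change and direction for one transcript.

    Ratio of group arithmetic means; when the treatment mean is at least the
    control mean the result is (treat/ctrl, "up"), otherwise (ctrl/treat,
    "down").  Equal means give (1.0, "up") by convention.
    """
    row = matrix.values.loc[transcript_id]
    t_mean = row[matrix.treatment_samples].mean()
    c_mean = row[matrix.control_samples].mean()
    return _fc_from_means(float(t_mean), float(c_mean))


def _fc_from_means(t_mean: float, c_mean: float) -> tuple[float, str]:
    if t_mean <= 0 and c_mean <= 0:
        raise StatisticsError("undefined ratio: both group means are zero")
    if t_mean >= c_mean:
        return t_mean / c_mean, "up"
    return c_mean / t_mean, "down"


def de_test(
    matrix: ExpressionMatrix,
    biotype_of: Mapping[str, str] | None = None,
    fc_min: float = FC_MIN,
    p_max: float = P_MAX,
    fdr_max: float = FDR_MAX,
    fdr_family: str = "by_class",
) -> list[DEResult]:
    """Welch t-test on log2 intensities plus FC/P/FDR filter flags.

    Parameters
    ----------
    biotype_of
        Optional transcript -> {"coding", "lncRNA"} mapping used to correct
        the two RNA classes as separate BH families.  Without it (or with
        ``fdr_family="joint"``) a single family is used.
    """
    t_cols = matrix.treatment_samples
    c_cols = matrix.control_samples
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise StatisticsError("each group needs >= 2 samples for a variance estimate")

    values = matrix.values
    t_lin = values[t_cols].to_numpy(dtype=float)
    c_lin = values[c_cols].to_numpy(dtype=float)
    t_mean = t_lin.mean(axis=1)
    c_mean = c_lin.mean(axis=1)

    up = t_mean >= c_mean
    with np.errstate(divide="ignore"):
        fc = np.where(up, t_mean / c_mean, c_mean / t_mean)

    t_log = np.log2(t_lin)
    c_log = np.log2(c_lin)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a scipy precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(t_log, c_log, axis=1, equal_var=False).pvalue
    # zero variance in both groups: the test is degenerate; call means apart
    # certain (p=0) and equal means null (p=1)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(t_log.mean(axis=1), c_log.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)

    ids = matrix.probe_ids
    fdr = np.empty_like(p)
    if fdr_family == "by_class" and biotype_of is not None:
        classes = np.array([biotype_of.get(i, "coding") for i in ids])
        for cls in np.unique(classes):
            mask = classes == cls
            fdr[mask] = bh_fdr(p[mask])
    elif fdr_family in ("joint", "by_class"):
        fdr = bh_fdr(p)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")

    results = []
    for i, tx in enumerate(ids):
        results.append(
            DEResult(
                transcript_id=tx,
                fold_change=float(fc[i]),
                regulation="up" if up[i] else "down",
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                passes_primary=bool(fc[i] >= fc_min and p[i] < p_max),
                passes_sensitivity=bool(fc[i] >= fc_min and fdr[i] < fdr_max),
            )
        )
    return results


def write_de_tsv(
    results: Iterable[DEResult],
    path: str | Path,
    symbols: Mapping[str, str] | None = None,
    only_passing: str | None = None,
) -> None:
    """Write DE results as TSV (Seqname, GeneSymbol, FoldChange, Regulation, P, FDR).

    ``only_passing`` filters to "primary" or "sensitivity" passes.
    """
    rows = []
    for r in results:
        if only_passing == "primary" and not r.passes_primary:
            continue
        if only_passing == "sensitivity" and not r.passes_sensitivity:
            continue
        rows.append(
            {
                "Seqname": r.transcript_id,
                "GeneSymbol": (symbols or {}).get(r.transcript_id, r.transcript_id),
                "FoldChange": r.fold_change,
                "Regulation": r.regulation,
                "P": r.p_value,
                "FDR": r.fdr,
            }
        )
    pd.DataFrame(
        rows, columns=["Seqname", "GeneSymbol", "FoldChange", "Regulation", "P", "FDR"]
    ).to_csv(path, sep="\t", index=False)
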