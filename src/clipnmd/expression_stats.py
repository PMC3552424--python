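"""Steady-state expression screen and small quantification utilities.

The screen works on a gene x sample matrix of log2 intensities with WT/DKO
genotype labels: quantile normalization, per-gene log2(WT/DKO) as a difference
of replicate medians, a classical equal-variance two-sided Student's t-test,
and the conjunction significance rule |log2FC| > 0.3 AND p < 0.05. No multiple
testing correction enters the significance call; a Benjamini-Hochberg column is
attached for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

WT, DKO = "WT", "DKO"


@dataclass(frozen=True)
class DiffExprRecord:
    gene_id: str
    log2fc: float          # median(WT) - median(DKO), log2 scale
    p_value: float
    q_value: float         # BH-adjusted, informational only
    significant: bool
    direction: str         # "up-in-WT" | "down-in-WT"


@dataclass(frozen=True)
class DeltaIRecord:
    exon_id: str
    inclusion_1: float
    exclusion_1: float
    inclusion_2: float
    exclusion_2: float

    @property
    def i1(self) -> float:
        return self.inclusion_1 / (self.inclusion_1 + self.exclusion_1)

    @property
    def i2(self) -> float:
        return self.inclusion_2 / (self.inclusion_2 + self.exclusion_2)

    @property
    def delta_i(self) -> float:
        """Inclusion-fraction difference, condition 1 minus condition 2."""
        return self.i1 - self.i2


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean sorted distribution (ties averaged).

    After normalization all columns share one multiset of values: the row-wise
    mean of the per-column sorted values. Row and column order are preserved.
    """
    arr = matrix.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties avg
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential_genes(matrix: pd.DataFrame, genotypes: Sequence[str],
                       lfc: float = 0.3, alpha: float = 0.05,
                       summary: str = "median") -> list[DiffExprRecord]:
    """Per-gene WT-vs-DKO screen on a normalized log2-intensity matrix.

    Records come back sorted by |log2FC| descending (the screen's ranking).
    """
    genotypes = list(genotypes)
    if len(genotypes) != matrix.shape[1]:
        raise ValueError("one genotype label per sample column required")
    wt_cols = [i for i, g in enumerate(genotypes) if g == WT]
    dko_cols = [i for i, g in enumerate(genotypes) if g == DKO]
    if len(wt_cols) < 2 or len(dko_cols) < 2:
        raise ValueError("need >=2 replicates per genotype for the t-test")
    agg = np.median if summary == "median" else np.mean
    wt = matrix.iloc[:, wt_cols].to_numpy(dtype=float)
    dko = matrix.iloc[:, dko_cols].to_numpy(dtype=float)
    log2fc = agg(wt, axis=1) - agg(dko, axis=1)
    with warnings.catch_warnings():
        # zero-variance genes yield nan p-values, mapped to 1.0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(wt, dko, axis=1, equal_var=True)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance identical groups -> no call
    q = multipletests(p, method="fdr_bh")[1]
    records = []
    for gid, fc, pv, qv in zip(matrix.index, log2fc, p, q):
        records.append(DiffExprRecord(
            gene_id=str(gid), log2fc=float(fc), p_value=float(pv),
            q_value=float(qv),
            significant=bool(abs(fc) > lfc and pv < alpha),
            direction="up-in-WT" if fc > 0 else "down-in-WT"))
    records.sort(key=lambda r: (-abs(r.log2fc), r.gene_id))
    return records


def diffexpr_frame(records: Sequence[DiffExprRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def ddct_fold(ct_target_wt: float, ct_ref_wt: float,
              ct_target_dko: float, ct_ref_dko: float) -> float:
    """Relative WT/DKO mRNA level from qPCR cycle thresholds: 2^(-ddCt)."""
    ddct = (ct_target_wt - ct_ref_wt) - (ct_target_dko - ct_ref_dko)
    return float(2.0 ** (-ddct))


def delta_i_table(records: Sequence[DeltaIRecord],
                  thresholds: Sequence[float]) -> dict[float, int]:
    """Count of exons with |dI| >= t for each threshold t (monotone in t)."""
    return {float(t): sum(1 for r in records if abs(r.delta_i) >= t)
            for t in thresholds}
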