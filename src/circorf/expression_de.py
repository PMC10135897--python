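"""Expression pipeline: log2 RPM, quantile normalization, sample and
variability filters, rank-sum differential expression with BH adjustment.

The DE test is a two-sided Wilcoxon rank-sum (Mann-Whitney) with normal
approximation and tie correction; significance requires both the BH-adjusted
p below ``alpha`` and an absolute log2 fold change of at least ``lfc_min``.
Quartiles use linear (type-7) interpolation, which matters at IQR boundary
cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("cancer", "normal")


@dataclass
class FilterParams:
    pseudocount: float = 1.0
    alpha: float = 0.05
    lfc_min: float = 1.0
    iqr_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DEResult:
    circ_id: str
    log2fc: float  # mean(cancer) - mean(normal) on the log2 scale
    p: float
    p_adj: float
    significant: bool


def to_log2_rpm(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count * 1e6 / library_size + pseudocount), column-wise.

    When *library_sizes* is None the per-sample column sums are used (the
    backsplice dialect carries no true library sizes).
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        bad = library_sizes.index[(library_sizes <= 0) | library_sizes.isna()].tolist()
        raise ValueError(f"non-positive or missing library size for samples: {bad}")
    rpm = counts * 1e6 / library_sizes
    return np.log2(rpm + pseudocount)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical column distributions via rank means.

    The reference distribution is the row-wise mean of the column-sorted
    input; ties within a column receive the mean of the reference values at
    the tied ranks (average-rank interpolation).
    """
    values = matrix.to_numpy(dtype=float)
    n_rows = values.shape[0]
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    rank_grid = np.arange(1, n_rows + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, rank_grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_samples(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep samples whose total expression exceeds the across-sample median."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    totals = matrix.sum(axis=0)
    median = float(totals.median())
    if (totals == totals.iloc[0]).all():
        warnings.warn("all sample totals identical; retaining all samples")
        return matrix.copy()
    keep = totals[totals > median].index
    return matrix[keep]


def filter_variable(matrix: pd.DataFrame, iqr_min: float = 0.5) -> pd.DataFrame:
    """Rows with IQR (Q3 - Q1, linear interpolation) strictly above iqr_min."""
    if matrix.shape[1] < 4:
        raise ValueError("need >= 4 samples for a meaningful IQR")
    q1, q3 = np.percentile(matrix.to_numpy(dtype=float), [25, 75], axis=1)
    return matrix[(q3 - q1) > iqr_min]


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    p_adj = multipletests(pvalues, method="fdr_bh")[1]
    return p_adj


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    params: FilterParams | None = None,
) -> list[DEResult]:
    """Per-row two-sided Wilcoxon rank-sum with BH adjustment and FC gating."""
    params = params or FilterParams()
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    cancer_cols = groups[groups == "cancer"].index
    normal_cols = groups[groups == "normal"].index
    if len(cancer_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("both groups need >= 2 samples")
    x = matrix[cancer_cols].to_numpy(dtype=float)
    y = matrix[normal_cols].to_numpy(dtype=float)
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    # vectorized over rows: asymptotic Mann-Whitney with tie correction
    _, pvals = stats.mannwhitneyu(
        x, y, axis=1, alternative="two-sided", method="asymptotic"
    )
    p_adj = benjamini_hochberg(pvals)
    results = []
    for i, circ_id in enumerate(matrix.index):
        sig = bool(p_adj[i] < params.alpha and abs(log2fc[i]) >= params.lfc_min)
        results.append(
            DEResult(
                circ_id=str(circ_id),
                log2fc=float(log2fc[i]),
                p=float(pvals[i]),
                p_adj=float(p_adj[i]),
                significant=sig,
            )
        )
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.circ_id, r.log2fc, r.p, r.p_adj, r.significant) for r in results],
        columns=["circ_id", "log2fc", "p", "p_adj", "significant"],
    )


def volcano_table(results: list[DEResult], params: FilterParams | None = None) -> pd.DataFrame:
    """Plot-ready table: log2FC, -log10 adjusted p, three-way color class."""
    params = params or FilterParams()
    rows = []
    for r in results:
        if r.p_adj < params.alpha and abs(r.log2fc) >= params.lfc_min:
            color = "significant"
        elif abs(r.log2fc) < params.lfc_min:
            color = "low_lfc"
        else:
            color = "high_padj"
        with np.errstate(divide="ignore"):
            neglog = float(-np.log10(r.p_adj)) if r.p_adj > 0 else np.inf
        rows.append((r.circ_id, r.log2fc, neglog, color))
    return pd.DataFrame(rows, columns=["circ_id", "log2fc", "neg_log10_p_adj", "class"])
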