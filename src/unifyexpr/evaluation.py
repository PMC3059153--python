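"""Precision and accuracy statistics for competing expression summaries.

Given several candidate gene-expression summaries of the same samples (single
platforms, plain averages, factor-analysis scores), these statistics compare
them on equal footing:

* pooled replicate variance — within-replicate-set variability, the precision
  of a summary;
* sum of squared differences (SSD) to a standardized reference matrix (e.g.
  sequencing-based log counts), the accuracy of a summary;
* log2 fold change between two sample groups;
* ROC / AUC of a per-gene ranking statistic against externally supplied
  truth labels.

All comparisons are on per-gene standardized values (mean 0, SD 1 across
samples) so that summaries with different natural scales are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

__all__ = [
    "ReplicateDesign",
    "GroupDesign",
    "RocResult",
    "standardize_genes",
    "log2_counts",
    "median_normalize",
    "pooled_variance",
    "pooled_sd",
    "ssd_to_reference",
    "log2_fold_change",
    "group_t_statistic",
    "roc_curve",
]


@dataclass(frozen=True)
class ReplicateDesign:
    """Disjoint sets of technical-replicate sample IDs, each of size >= 2."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValueError(f"replicate set {g} has fewer than 2 samples")
            for s in g:
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one replicate set")
                seen.add(s)

    def validate_against(self, columns: Sequence[str]) -> None:
        missing = [s for g in self.groups for s in g if s not in set(columns)]
        if missing:
            raise ValueError(f"replicate samples absent from matrix: {missing}")


@dataclass(frozen=True)
class GroupDesign:
    """Two disjoint, non-empty sample groups for a two-group comparison."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError("groups overlap")


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def standardize_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization to mean 0, SD 1 (denominator n-1) across samples."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])[:5]
        raise ValueError(f"zero variance for gene(s): {bad}")
    return values.sub(mu, axis=0).div(sd, axis=0)


def log2_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count + pseudocount) transform for a sequencing reference."""
    return np.log2(counts + pseudocount)


def median_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median (column-wise location normalization)."""
    return values.sub(values.median(axis=0), axis=1)


def pooled_variance(summary: pd.DataFrame, design: ReplicateDesign) -> pd.Series:
    """Pooled within-replicate-set variance per gene.

    ``s^2 = sum_i sum_r (y_ir - ybar_i)^2 / sum_i (n_i - 1)`` over replicate
    sets i; the input should be standardized per gene so that summaries are
    comparable.
    """
    design.validate_against(summary.columns)
    num = pd.Series(0.0, index=summary.index)
    dof = 0
    for g in design.groups:
        block = summary[list(g)]
        dev = block.sub(block.mean(axis=1), axis=0)
        num = num + (dev**2).sum(axis=1)
        dof += len(g) - 1
    return num / dof


def pooled_sd(summary: pd.DataFrame, design: ReplicateDesign) -> pd.Series:
    """Square root of :func:`pooled_variance` (the reported precision measure)."""
    return np.sqrt(pooled_variance(summary, design))


def ssd_to_reference(summary: pd.DataFrame, reference: pd.DataFrame) -> pd.Series:
    """Per-gene sum of squared differences to a standardized reference.

    Genes and samples must match; both matrices are expected to already be
    standardized per gene.  For standardized n-vectors the SSD equals
    ``2 (n-1) (1 - r)`` with r the sample correlation, so ranking summaries by
    SSD is ranking them by correlation with the reference.
    """
    if list(summary.index) != list(reference.index):
        raise ValueError("gene sets/order differ between summary and reference")
    if list(summary.columns) != list(reference.columns):
        raise ValueError("sample sets/order differ between summary and reference")
    return ((summary - reference) ** 2).sum(axis=1)


def log2_fold_change(values: pd.DataFrame, design: GroupDesign) -> pd.Series:
    """Difference of group means of log2 values: mean(group1) - mean(group2)."""
    for g in (design.group1, design.group2):
        missing = [s for s in g if s not in values.columns]
        if missing:
            raise ValueError(f"group samples absent from matrix: {missing}")
    return values[list(design.group1)].mean(axis=1) - values[list(design.group2)].mean(axis=1)


def group_t_statistic(values: pd.DataFrame, design: GroupDesign) -> pd.Series:
    """Welch two-sample t statistic per gene (group1 vs group2).

    Zero pooled variance yields an infinite statistic with the sign of the
    mean difference (0 when the means also coincide); reported as-is rather
    than raising, so degenerate genes stay visible in rankings.
    """
    g1, g2 = list(design.group1), list(design.group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples for a t statistic")
    a, b = values[g1], values[g2]
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = a.var(axis=1, ddof=1) / len(g1) + b.var(axis=1, ddof=1) / len(g2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t[(se2 == 0) & (diff == 0)] = 0.0
    t[(se2 == 0) & (diff > 0)] = np.inf
    t[(se2 == 0) & (diff < 0)] = -np.inf
    return t


def roc_curve(statistics: pd.Series, truth: pd.Series) -> RocResult:
    """ROC curve and trapezoidal AUC of |statistic| against truth labels.

    ``truth`` holds one of "positive", "negative" or "excluded" per gene;
    excluded genes are ignored.  The ranking score is the absolute value of
    the statistic (two-sided differential expression).  Raises ``ValueError``
    unless at least one positive and one negative remain.
    """
    truth = truth.reindex(statistics.index)
    keep = truth.isin(["positive", "negative"])
    y = (truth[keep] == "positive").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one positive and one negative label")
    score = statistics[keep].abs().to_numpy(dtype=float)
    finite = score[np.isfinite(score)]
    finite_max = float(finite.max()) if finite.size else 1.0
    score = np.nan_to_num(score, nan=0.0, posinf=finite_max * 2 + 1, neginf=0.0)
    fpr, tpr, _ = _skmetrics.roc_curve(y, score)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_skmetrics.auc(fpr, tpr)))
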