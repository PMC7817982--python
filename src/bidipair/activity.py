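"""Rank-based transcriptional activity scoring.

Expression values are ranked low-to-high within each sample (ties get the
average rank); a gene's activity in a condition is the median of its ranks
across that condition's samples, scaled to (0, 1] by dividing by the number
of genes.  Being rank-based, the score is invariant to any strictly
monotone per-sample transformation of the expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ActivityComparison", "rank_within_sample", "activity_score", "compare_activity"]


@dataclass
class ActivityComparison:
    statistic: float
    p_value: float
    median_difference: float
    paired: bool
    test: str


def rank_within_sample(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample ranks 1..G, lowest value -> rank 1, ties averaged."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("expression matrix contains missing values; complete it first")
    return values.rank(axis=0, method="average", ascending=True)


def activity_score(ranks: pd.DataFrame, samples: list[str] | None = None) -> pd.Series:
    """Median per-sample rank across the chosen samples, divided by gene count."""
    sub = ranks if samples is None else ranks[samples]
    if sub.shape[1] == 0:
        raise ValueError("no samples selected for activity scoring")
    n_genes = sub.shape[0]
    return sub.median(axis=1) / n_genes


def condition_activity(matrix: ExpressionMatrix, condition: str,
                       tumor_type: str | None = None) -> pd.Series:
    """Activity scores for one condition (optionally one tumor type)."""
    samples = matrix.samples_in(condition, tumor_type)
    if not samples:
        raise ValueError(f"no samples for condition={condition!r}")
    ranks = rank_within_sample(matrix.values[samples])
    return activity_score(ranks)


def compare_activity(scores_a: pd.Series, scores_b: pd.Series,
                     paired: bool = False) -> ActivityComparison:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) comparison of two
    activity-score vectors; reports the median difference a - b."""
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValueError("score vectors must be non-empty")
    if paired:
        if not scores_a.index.equals(scores_b.index):
            common = scores_a.index.intersection(scores_b.index)
            if len(common) != len(scores_a) or len(common) != len(scores_b):
                raise ValueError("paired comparison requires identical gene ids")
            scores_b = scores_b.loc[scores_a.index]
        diffs = scores_a.to_numpy() - scores_b.to_numpy()
        if np.all(diffs == 0):
            return ActivityComparison(0.0, 1.0, 0.0, True, "wilcoxon-signed-rank")
        stat, p = stats.wilcoxon(diffs)
        med = float(np.median(diffs))
        return ActivityComparison(float(stat), float(p), med, True, "wilcoxon-signed-rank")
    stat, p = stats.mannwhitneyu(scores_a.to_numpy(), scores_b.to_numpy(),
                                 alternative="two-sided")
    med = float(np.median(scores_a.to_numpy()) - np.median(scores_b.to_numpy()))
    return ActivityComparison(float(stat), float(p), med, False, "wilcoxon-rank-sum")
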