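"""Pairwise co-expression, differential co-expression and shifted-pair calls.

For every gene pair the Pearson correlation coefficient (PCC) of the two
genes' expression profiles is computed separately in normal and cancer
samples.  Differential co-expression is delta = PCC(cancer) - PCC(normal),
tested against zero with a paired Wilcoxon signed-rank test.  The pair
universe is split at the median normal-state PCC into LC (below) and HC
(at or above) subsets, and "shifted" pairs are those lowly co-expressed in
normal but highly correlated in cancer:

    shifted  <=>  pcc_normal < median(pcc_normal)  and
                  pcc_cancer >= median(pcc_cancer)

Both thresholds are medians of the same pair universe they are applied to
(data-derived, with optional fixed overrides to reproduce published cuts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_pairs import GenePair
from .gene_set_stats import EnrichmentResult, GeneSet, hk_subgroup_counts, subgroup_homogeneity_test
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftThresholds",
    "DifferentialCoexpression",
    "pair_correlation",
    "differential_coexpression",
    "split_lc_hc",
    "find_shifted_pairs",
    "shifted_hk_enrichment",
]


@dataclass
class ShiftThresholds:
    t_normal: float
    t_cancer: float


@dataclass
class DifferentialCoexpression:
    """Per-pair correlation table plus the paired signed-rank test on deltas."""

    table: pd.DataFrame  # index (gene_a, gene_b); pcc_normal, pcc_cancer, delta
    mean_delta: float
    median_delta: float
    statistic: float | None
    p_value: float | None


def pair_correlation(matrix: ExpressionMatrix, pairs: list[GenePair],
                     condition: str, tumor_type: str | None = None) -> pd.Series:
    """Pearson correlation of each pair's two genes over condition samples.

    Pairs with a gene missing from the matrix or with constant expression are
    excluded with a warning.  Requires at least 3 samples.
    """
    sub = matrix.condition_values(condition, tumor_type)
    if sub.shape[1] < 3:
        raise ValueError(f"condition {condition!r} has {sub.shape[1]} samples; need >= 3")
    present = set(sub.index)
    keys, rows_a, rows_b = [], [], []
    for p in pairs:
        a, b = p.gene_a.gene_id, p.gene_b.gene_id
        if a not in present or b not in present:
            logger.warning("pair %s|%s missing from expression matrix; skipped", a, b)
            continue
        keys.append((a, b))
        rows_a.append(a)
        rows_b.append(b)
    if not keys:
        return pd.Series(dtype=float)
    xa = sub.loc[rows_a].to_numpy(dtype=float)
    xb = sub.loc[rows_b].to_numpy(dtype=float)
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    sa = np.sqrt((xa**2).sum(axis=1))
    sb = np.sqrt((xb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = (xa * xb).sum(axis=1) / (sa * sb)
    out = pd.Series(pcc, index=pd.MultiIndex.from_tuples(keys, names=["gene_a", "gene_b"]))
    bad = out.index[out.isna()]
    for a, b in bad:
        logger.warning("pair %s|%s has undefined PCC (constant gene) in %s; excluded",
                       a, b, condition)
    return out.dropna()


def differential_coexpression(pcc_normal: pd.Series,
                              pcc_cancer: pd.Series) -> DifferentialCoexpression:
    """delta = PCC(cancer) - PCC(normal) per pair + paired Wilcoxon test vs 0."""
    if not pcc_normal.index.sort_values().equals(pcc_cancer.index.sort_values()):
        raise ValueError("normal and cancer correlations cover different pair universes")
    pcc_cancer = pcc_cancer.loc[pcc_normal.index]
    delta = pcc_cancer - pcc_normal
    table = pd.DataFrame({"pcc_normal": pcc_normal, "pcc_cancer": pcc_cancer, "delta": delta})
    if len(delta) < 2:
        logger.warning("fewer than 2 pairs; signed-rank test skipped")
        stat = p = None
    elif np.all(delta.to_numpy() == 0):
        stat, p = 0.0, 1.0
    else:
        s, pv = stats.wilcoxon(delta.to_numpy())
        stat, p = float(s), float(pv)
    return DifferentialCoexpression(
        table=table,
        mean_delta=float(delta.mean()),
        median_delta=float(delta.median()),
        statistic=stat,
        p_value=p,
    )


def split_lc_hc(pcc_normal: pd.Series) -> tuple[pd.Series, float]:
    """LC iff pcc_normal < median, HC otherwise; returns labels and the median."""
    if len(pcc_normal) < 2:
        raise ValueError("need at least 2 pairs to split")
    t_normal = float(pcc_normal.median())
    labels = pd.Series(np.where(pcc_normal < t_normal, "LC", "HC"), index=pcc_normal.index)
    return labels, t_normal


def find_shifted_pairs(pcc_normal: pd.Series, pcc_cancer: pd.Series,
                       t_normal: float | None = None,
                       t_cancer: float | None = None) -> tuple[pd.Series, ShiftThresholds]:
    """Boolean shifted flag per pair plus the thresholds used.

    Thresholds default to the medians of each condition's PCC over the pair
    universe; explicit values override (e.g. to reproduce published cuts).
    """
    pcc_cancer = pcc_cancer.loc[pcc_normal.index]
    tn = float(pcc_normal.median()) if t_normal is None else float(t_normal)
    tc = float(pcc_cancer.median()) if t_cancer is None else float(t_cancer)
    shifted = (pcc_normal < tn) & (pcc_cancer >= tc)
    return shifted, ShiftThresholds(t_normal=tn, t_cancer=tc)


def shifted_hk_enrichment(shifted_pairs: list[GenePair], all_pairs: list[GenePair],
                          hk: GeneSet) -> EnrichmentResult:
    """Housekeeping enrichment of shifted pairs: goodness-of-fit of the shifted
    (0,1,2)-HK counts against the background subgroup proportions."""
    focus = hk_subgroup_counts(shifted_pairs, hk)
    background = hk_subgroup_counts(all_pairs, hk)
    return subgroup_homogeneity_test(
        [focus[0], focus[1], focus[2]],
        [background[0], background[1], background[2]],
    )
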