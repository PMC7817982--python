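"""Enhancer-RNA target assignment and gain/loss of shared-enhancer regulation.

Enhancer activation is proxied by eRNA expression.  An eRNA is a candidate
regulator of an H2H gene when its interval lies within 1 Mb of the pair's
genomic block (the span from the leftmost to the rightmost coordinate of the
two genes; distance 0 when overlapping), and becomes an assigned target when
Spearman rho >= 0.3 with BH FDR < 0.05 over the condition's samples — the
same gates as TF inference.  A pair is "enhancer-regulated" in a condition
when at least one eRNA is assigned to both of its genes; comparing the two
conditions assigns each pair one category: both, loss (normal-only), gain
(cancer-only) or none.

Differentially expressed eRNAs are called from tumor-normal paired samples:
expressed (value > 0 in both members) in >= 3 pairs, |mean log2 fold change|
> log2(1.5) and BH-adjusted paired t-test p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman_matrix
from .annotation_pairs import GenePair
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EnhancerRecord",
    "pair_block",
    "block_distance",
    "assign_enhancer_targets",
    "enhancer_regulated_pairs",
    "differential_ernas",
    "categorize_pair_regulation",
]


@dataclass(frozen=True)
class EnhancerRecord:
    """One eRNA locus (1-based inclusive coordinates)."""

    erna_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.erna_id}: start > end")


def pair_block(pair: GenePair) -> tuple[str, int, int]:
    """Genomic span of the two gene bodies."""
    a, b = pair.gene_a, pair.gene_b
    if a.chrom != b.chrom:
        raise ValueError(f"pair {pair.key} spans chromosomes; no block defined")
    return a.chrom, min(a.start, b.start), max(a.end, b.end)


def block_distance(erna: EnhancerRecord, pair: GenePair) -> int | None:
    """Gap between the eRNA interval and the pair block; 0 when overlapping,
    None when on different chromosomes."""
    chrom, lo, hi = pair_block(pair)
    if erna.chrom != chrom:
        return None
    if erna.end < lo:
        return lo - erna.end
    if erna.start > hi:
        return erna.start - hi
    return 0


def assign_enhancer_targets(ernas: Sequence[EnhancerRecord], erna_expr: pd.DataFrame,
                            pairs: Sequence[GenePair], matrix: ExpressionMatrix,
                            condition: str, max_dist: int = 1_000_000,
                            rho_min: float = 0.3, q_max: float = 0.05) -> pd.DataFrame:
    """eRNA-gene assignment table (erna_id, gene, condition, rho, q, distance).

    Candidates are eRNA x gene combinations where the eRNA lies within
    ``max_dist`` of the gene's pair block; Spearman + BH over all candidates
    of the condition.
    """
    sub = matrix.condition_values(condition)
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples for enhancer-target assignment")
    samples = list(sub.columns)
    missing = [s for s in samples if s not in erna_expr.columns]
    if missing:
        raise ValueError(f"{len(missing)} condition samples absent from eRNA expression")

    # candidate combos, deduplicated over pairs sharing a gene
    combos: dict[tuple[str, str], int] = {}
    for p in pairs:
        for e in ernas:
            d = block_distance(e, p)
            if d is None or d > max_dist:
                continue
            for g in (p.gene_a.gene_id, p.gene_b.gene_id):
                if g not in sub.index or e.erna_id not in erna_expr.index:
                    continue
                key = (e.erna_id, g)
                combos[key] = min(combos.get(key, d), d)
    if not combos:
        return pd.DataFrame(columns=["erna_id", "gene", "condition", "rho", "q", "distance"])

    keys = sorted(combos)
    e_ids = sorted({k[0] for k in keys})
    g_ids = sorted({k[1] for k in keys})
    x = erna_expr.loc[e_ids, samples].to_numpy(dtype=float).T
    y = sub.loc[g_ids].to_numpy(dtype=float).T
    rho, p = spearman_matrix(x, y)
    ei = {e: i for i, e in enumerate(e_ids)}
    gi = {g: i for i, g in enumerate(g_ids)}
    rows = np.array([ei[k[0]] for k in keys])
    cols = np.array([gi[k[1]] for k in keys])
    rho_v = rho[rows, cols]
    p_v = p[rows, cols]
    ok = ~np.isnan(rho_v)
    q_v = np.full(len(keys), np.nan)
    q_v[ok] = bh_adjust(p_v[ok])
    keep = ok & (rho_v >= rho_min) & (q_v < q_max)
    return pd.DataFrame({
        "erna_id": [keys[i][0] for i in np.nonzero(keep)[0]],
        "gene": [keys[i][1] for i in np.nonzero(keep)[0]],
        "condition": condition,
        "rho": rho_v[keep],
        "q": q_v[keep],
        "distance": [combos[keys[i]] for i in np.nonzero(keep)[0]],
    })


def enhancer_regulated_pairs(assignments: pd.DataFrame,
                             pairs: Sequence[GenePair]) -> set[tuple[str, str]]:
    """Pairs where one eRNA is assigned to both genes in the condition."""
    if len(assignments) == 0:
        return set()
    by_gene: dict[str, set[str]] = {}
    for _, row in assignments.iterrows():
        by_gene.setdefault(row["gene"], set()).add(row["erna_id"])
    out: set[tuple[str, str]] = set()
    for p in pairs:
        a, b = p.gene_a.gene_id, p.gene_b.gene_id
        if by_gene.get(a, set()) & by_gene.get(b, set()):
            out.add(p.key)
    return out


def differential_ernas(erna_expr: pd.DataFrame, matrix: ExpressionMatrix,
                       fc_log2: float = float(np.log2(1.5)), q_max: float = 0.05,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Differentially expressed eRNAs from tumor-normal paired samples.

    Returns a table (erna_id, n_pairs, log2_fc, p, q, direction) of eRNAs
    passing the expression gate; ``direction`` is 'up'/'down' for DE calls
    and 'ns' otherwise.
    """
    sample_pairs = matrix.paired_samples()
    usable = [(n, c) for n, c in sample_pairs
              if n in erna_expr.columns and c in erna_expr.columns]
    if len(usable) < 3:
        raise ValueError("need >= 3 complete tumor-normal paired samples")
    normal_cols = [n for n, _ in usable]
    cancer_cols = [c for _, c in usable]
    vn = erna_expr[normal_cols].to_numpy(dtype=float)
    vc = erna_expr[cancer_cols].to_numpy(dtype=float)
    expressed = (vn > 0) & (vc > 0)

    rows = []
    for i, erna_id in enumerate(erna_expr.index):
        mask = expressed[i]
        n_ok = int(mask.sum())
        if n_ok < 3:
            continue
        ln = np.log2(vn[i, mask] + pseudocount)
        lc = np.log2(vc[i, mask] + pseudocount)
        diffs = lc - ln
        l2fc = float(diffs.mean())
        if np.allclose(diffs, diffs[0]):
            p = 1.0 if np.allclose(diffs, 0) else 0.0
        else:
            _, p = stats.ttest_rel(lc, ln)
        rows.append((erna_id, n_ok, l2fc, float(p)))
    if not rows:
        return pd.DataFrame(columns=["erna_id", "n_pairs", "log2_fc", "p", "q", "direction"])
    table = pd.DataFrame(rows, columns=["erna_id", "n_pairs", "log2_fc", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    de = (table["log2_fc"].abs() > fc_log2) & (table["q"] < q_max)
    table["direction"] = np.where(de & (table["log2_fc"] > 0), "up",
                                  np.where(de & (table["log2_fc"] < 0), "down", "ns"))
    return table


def categorize_pair_regulation(regulated_normal: set[tuple[str, str]],
                               regulated_cancer: set[tuple[str, str]],
                               pairs: Sequence[GenePair]) -> pd.Series:
    """Category per pair: both / loss (normal-only) / gain (cancer-only) / none."""
    cats = {}
    for p in pairs:
        in_n = p.key in regulated_normal
        in_c = p.key in regulated_cancer
        cats[p.key] = "both" if in_n and in_c else "loss" if in_n else \
                      "gain" if in_c else "none"
    idx = pd.MultiIndex.from_tuples(list(cats), names=["gene_a", "gene_b"])
    return pd.Series(list(cats.values()), index=idx, dtype=object)


def delta_by_category(categories: pd.Series, delta: pd.Series) -> pd.DataFrame:
    """Mean differential co-expression per regulation category, with rank-sum
    p-values of each category against the 'none' background."""
    common = categories.index.intersection(delta.index)
    cats = categories.loc[common]
    d = delta.loc[common]
    rows = []
    none_vals = d[cats == "none"].to_numpy()
    for cat in ("gain", "loss", "both", "none"):
        vals = d[cats == cat].to_numpy()
        if len(vals) == 0:
            continue
        if cat != "none" and len(none_vals) > 0 and len(vals) > 0:
            _, p = stats.mannwhitneyu(vals, none_vals, alternative="two-sided")
        else:
            p = float("nan")
        rows.append((cat, len(vals), float(np.mean(vals)), float(p)))
    return pd.DataFrame(rows, columns=["category", "n", "mean_delta", "p_vs_none"])
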