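"""Transcription-factor target inference and TF-similarity of gene pairs.

A TF is called a putative regulator of a gene in one condition when the
Spearman correlation of their expression profiles is at least ``rho_min``
(0.3 by default, positive regulation as written; a flag switches to
|rho|) with a Benjamini-Hochberg FDR below ``q_max`` (0.05), the FDR family
being all regulator x gene combinations tested within that condition.

TF similarity of a pair is the Jaccard index of the two genes' regulator
sets — the fraction of shared TFs among the union — undefined when both
sets are empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman_matrix
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TfSimilarity",
    "infer_regulator_targets",
    "assignments_from_edges",
    "tf_similarity",
    "pair_tf_similarity",
    "similarity_correlation_association",
]


@dataclass
class TfSimilarity:
    similarity: float
    defined: bool


def infer_regulator_targets(matrix: ExpressionMatrix, regulator_ids: list[str],
                            condition: str, tumor_type: str | None = None,
                            rho_min: float = 0.3, q_max: float = 0.05,
                            absolute: bool = False) -> pd.DataFrame:
    """Regulator-target edge table for one condition.

    Returns a DataFrame with columns (regulator, gene, condition, rho, q)
    containing every combination passing the correlation and FDR gates.
    """
    sub = matrix.condition_values(condition, tumor_type)
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples for regulator inference")
    regs = []
    for r in regulator_ids:
        if r in sub.index:
            regs.append(r)
        else:
            logger.warning("regulator %s absent from expression matrix; skipped", r)
    if not regs:
        return pd.DataFrame(columns=["regulator", "gene", "condition", "rho", "q"])
    genes = list(sub.index)
    x = sub.loc[regs].to_numpy(dtype=float).T   # samples x regulators
    y = sub.to_numpy(dtype=float).T             # samples x genes
    rho, p = spearman_matrix(x, y)

    reg_index = {g: i for i, g in enumerate(genes)}
    self_mask = np.zeros_like(rho, dtype=bool)
    for i, r in enumerate(regs):
        self_mask[i, reg_index[r]] = True
    valid = ~np.isnan(rho) & ~self_mask

    q = np.full_like(p, np.nan)
    q[valid] = bh_adjust(p[valid])

    effect = np.abs(rho) if absolute else rho
    keep = valid & (effect >= rho_min) & (q < q_max)
    ri, gi = np.nonzero(keep)
    return pd.DataFrame({
        "regulator": [regs[i] for i in ri],
        "gene": [genes[j] for j in gi],
        "condition": condition,
        "rho": rho[keep],
        "q": q[keep],
    })


def assignments_from_edges(edges: pd.DataFrame) -> dict[str, frozenset[str]]:
    """gene -> set of its assigned regulators."""
    out: dict[str, frozenset[str]] = {}
    if len(edges) == 0:
        return out
    for gene, grp in edges.groupby("gene"):
        out[str(gene)] = frozenset(grp["regulator"])
    return out


def tf_similarity(regulators_a: frozenset[str] | set[str],
                  regulators_b: frozenset[str] | set[str]) -> TfSimilarity:
    """Jaccard index of two regulator sets; undefined when both are empty."""
    a, b = set(regulators_a), set(regulators_b)
    union = a | b
    if not union:
        return TfSimilarity(similarity=float("nan"), defined=False)
    return TfSimilarity(similarity=len(a & b) / len(union), defined=True)


def pair_tf_similarity(pairs: list, assignments: dict[str, frozenset[str]]) -> pd.Series:
    """TF similarity per pair; pairs with an empty union are dropped (logged)."""
    keys, vals = [], []
    for p in pairs:
        a, b = p.gene_a.gene_id, p.gene_b.gene_id
        sim = tf_similarity(assignments.get(a, frozenset()), assignments.get(b, frozenset()))
        if not sim.defined:
            logger.info("pair %s|%s has no assigned regulators; similarity undefined", a, b)
            continue
        keys.append((a, b))
        vals.append(sim.similarity)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(keys, names=["gene_a", "gene_b"])
                     if keys else pd.MultiIndex.from_arrays([[], []], names=["gene_a", "gene_b"]),
                     dtype=float)


def similarity_correlation_association(similarity: pd.Series,
                                       pcc: pd.Series) -> tuple[float, float]:
    """Spearman association between pair TF similarity and pair expression
    correlation across the pair universe.  Returns (rho, p); (nan, nan) when
    the association is undefined (an all-tied vector)."""
    common = similarity.index.intersection(pcc.index)
    if len(common) < 3:
        raise ValueError("need >= 3 pairs with defined similarity")
    s = similarity.loc[common].to_numpy(dtype=float)
    c = pcc.loc[common].to_numpy(dtype=float)
    if np.all(s == s[0]) or np.all(c == c[0]):
        logger.warning("all-tied vector; similarity association undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(s, c)
    return float(rho), float(p)
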