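"""Overlap of H2H genes/pairs with labeled gene sets and chi-squared enrichment.

Covers three questions asked of a pair catalog: what fraction of a gene set
(housekeeping, mitochondrial, cancer) sits in H2H organization relative to
the genome-wide background (2x2 chi-squared); how pairs distribute over the
0/1/2-housekeeping-gene subgroups; and whether a focus subset of pairs
(e.g. shifted pairs) departs from the background subgroup proportions
(goodness-of-fit chi-squared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .annotation_pairs import GenePair

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "overlap_enrichment",
    "hk_subgroup_counts",
    "annotate_hk_counts",
    "subgroup_homogeneity_test",
]


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.label!r} is empty")

    @classmethod
    def from_iterable(cls, label: str, members: Iterable[str]) -> "GeneSet":
        return cls(label=label, members=frozenset(members))

    def restricted_to(self, universe: Iterable[str]) -> "GeneSet":
        """Intersect with the analysis universe; dropped identifiers are logged."""
        uni = frozenset(universe)
        kept = self.members & uni
        dropped = len(self.members) - len(kept)
        if dropped:
            logger.info("gene set %r: %d of %d identifiers absent from universe, dropped",
                        self.label, dropped, len(self.members))
        if not kept:
            raise ValueError(f"gene set {self.label!r} has no identifiers in the universe")
        return GeneSet(label=self.label, members=kept)


@dataclass
class EnrichmentResult:
    observed_proportion: float
    background_proportion: float
    statistic: float
    p_value: float
    counts: tuple[int, ...]
    label: str = ""


def overlap_enrichment(gene_set: GeneSet, h2h_genes: Iterable[str],
                       universe: Iterable[str], correction: bool = False) -> EnrichmentResult:
    """2x2 chi-squared test of gene-set membership against H2H membership.

    Reports the proportion of the gene set found in H2H organization and the
    H2H proportion of the whole universe as background.  Yates continuity
    correction is off by default.
    """
    uni = frozenset(universe)
    gs = gene_set.restricted_to(uni)
    h2h = frozenset(h2h_genes) & uni
    in_set_in_h2h = len(gs.members & h2h)
    in_set_out = len(gs.members) - in_set_in_h2h
    out_set_in_h2h = len(h2h - gs.members)
    out_set_out = len(uni) - in_set_in_h2h - in_set_out - out_set_in_h2h
    table = np.array([[in_set_in_h2h, in_set_out], [out_set_in_h2h, out_set_out]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("degenerate 2x2 table (an all-zero margin)")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return EnrichmentResult(
        observed_proportion=in_set_in_h2h / len(gs.members),
        background_proportion=len(h2h) / len(uni),
        statistic=float(stat),
        p_value=float(p),
        counts=(in_set_in_h2h, in_set_out, out_set_in_h2h, out_set_out),
        label=gs.label,
    )


def hk_subgroup_counts(pairs: Sequence[GenePair], hk: GeneSet) -> dict[int, int]:
    """Partition pairs by the number of member genes in ``hk`` (0, 1 or 2)."""
    counts = {0: 0, 1: 0, 2: 0}
    for p in pairs:
        k = int(p.gene_a.gene_id in hk.members) + int(p.gene_b.gene_id in hk.members)
        counts[k] += 1
    return counts


def annotate_hk_counts(pairs: Sequence[GenePair], hk: GeneSet) -> list[GenePair]:
    """Return pairs with ``hk_count`` filled in."""
    out = []
    for p in pairs:
        k = int(p.gene_a.gene_id in hk.members) + int(p.gene_b.gene_id in hk.members)
        out.append(GenePair(gene_a=p.gene_a, gene_b=p.gene_b, pair_class=p.pair_class,
                            tss_distance=p.tss_distance, promoter=p.promoter,
                            biotype_label=p.biotype_label, hk_count=k))
    return out


def subgroup_homogeneity_test(counts_focus: Sequence[int],
                              counts_background: Sequence[int]) -> EnrichmentResult:
    """Goodness-of-fit chi-squared of a focus count vector against background
    proportions (expected = focus total x background fractions)."""
    obs = np.asarray(counts_focus, dtype=float)
    bg = np.asarray(counts_background, dtype=float)
    if obs.shape != bg.shape:
        raise ValueError("focus and background vectors differ in length")
    if obs.sum() <= 0 or bg.sum() <= 0:
        raise ValueError("count vectors must have positive totals")
    if (obs < 0).any() or (bg < 0).any():
        raise ValueError("counts must be non-negative")
    expected = obs.sum() * bg / bg.sum()
    if (expected == 0).any():
        raise ValueError("expected count of 0 in a cell; pool cells before testing")
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=len(obs) - 1))
    return EnrichmentResult(
        observed_proportion=float(obs[-1] / obs.sum()),
        background_proportion=float(bg[-1] / bg.sum()),
        statistic=stat,
        p_value=p,
        counts=tuple(int(c) for c in counts_focus),
    )
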