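"""Head-to-head (H2H) gene-pair discovery from gene-level GTF annotation.

Two neighboring genes form an H2H pair when they sit on opposite DNA strands,
are transcribed divergently, and their transcription start sites (TSSs) lie
within ``max_distance`` bp (1 kb by default), sharing a putative bidirectional
promoter — the interval between the two TSSs.  Pairs where one gene body is
entirely contained in the other are excluded, as is the mitochondrial genome.

Coordinate conventions: GTF is 1-based inclusive and all internal intervals
stay 1-based inclusive; BED export converts to 0-based half-open.

The module also builds the two control sets used throughout the analysis:
adjacent pairs (consecutive genes on the same strand) and random pairs
(genes separated by at least one other gene, or on different chromosomes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenePair",
    "DistanceHistogram",
    "parse_gene_annotation",
    "compute_tss",
    "find_h2h_pairs",
    "classify_pair_biotype",
    "find_adjacent_pairs",
    "sample_random_pairs",
    "bin_tss_distances",
    "export_promoters",
]

MITO_CHROMS = {"chrM", "chrMT", "M", "MT"}

#: canonical biotype vocabulary; anything unmapped collapses to "other"
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "antisense": "antisense",
    "antisense_RNA": "antisense",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "miRNA": "miRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "misc_RNA": "misc_RNA",
}

#: display order inside a pair label; protein coding always listed first
_BIOTYPE_PRIORITY = [
    "protein_coding", "antisense", "lncRNA", "pseudogene", "miRNA",
    "snoRNA", "snRNA", "misc_RNA", "other",
]
_BIOTYPE_DISPLAY = {"protein_coding": "protein coding"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return compute_tss(self)


@dataclass(frozen=True)
class GenePair:
    """Two genes with a pair class, TSS distance and shared-promoter interval."""

    gene_a: GeneRecord
    gene_b: GeneRecord
    pair_class: str  # H2H | adjacent | random
    tss_distance: int | None = None
    promoter: tuple[str, int, int] | None = None  # chrom, lower TSS, upper TSS
    biotype_label: str | None = None
    hk_count: int | None = None

    def __post_init__(self) -> None:
        if self.gene_a.gene_id == self.gene_b.gene_id:
            raise ValueError("a pair must join two distinct genes")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a.gene_id, self.gene_b.gene_id)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.key)


@dataclass
class DistanceHistogram:
    """TSS-distance tally in fixed-width bins starting at 1 bp."""

    bin_edges: list[tuple[int, int]]
    counts: list[int]
    subset: str = "all pairs"

    @property
    def total(self) -> int:
        return int(sum(self.counts))


# ---------------------------------------------------------------------------
# parsing


def parse_gene_annotation(source: str | Path | TextIO | Iterable[str]) -> list[GeneRecord]:
    """Parse gene-feature rows of a GTF stream into a gene catalog.

    Mitochondrial records are dropped, genes without a usable strand are
    rejected with a warning, and a duplicate gene_id raises.
    """
    if isinstance(source, (str, Path)) and "\t" not in str(source):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = list(source)

    catalog: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or not fields[3].isdigit() or not fields[4].isdigit():
            raise ValueError(f"malformed GTF row at line {lineno}: expected 9 "
                             f"tab-separated fields with integer coordinates")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises bare Exception subclasses
            raise ValueError(f"malformed GTF row at line {lineno}: {exc}") from exc
        if feat.featuretype != "gene":
            continue
        if feat.seqid in MITO_CHROMS:
            continue
        attrs = feat.attributes
        gene_id = (attrs.get("gene_id") or [None])[0]
        if gene_id is None:
            raise ValueError(f"line {lineno}: gene row without gene_id attribute")
        if feat.strand not in ("+", "-"):
            logger.warning("line %d: gene %s has strand %r, record rejected",
                           lineno, gene_id, feat.strand)
            continue
        if gene_id in seen:
            raise ValueError(f"line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or ["protein_coding"])[0]
        catalog.append(GeneRecord(gene_id=gene_id, chrom=feat.seqid,
                                  start=feat.start, end=feat.end,
                                  strand=feat.strand, biotype=biotype))
    return catalog


def compute_tss(gene: GeneRecord) -> int:
    """TSS = 5' end of the gene: start on '+', end on '-'."""
    return gene.start if gene.strand == "+" else gene.end


# ---------------------------------------------------------------------------
# H2H discovery


def _is_nested(a: GeneRecord, b: GeneRecord) -> bool:
    return (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end)


def is_h2h_candidate(a: GeneRecord, b: GeneRecord, max_distance: int = 1000) -> bool:
    """Pair predicate: opposite strands, same chromosome, divergent, non-nested,
    1 <= |dTSS| <= max_distance.

    Overlapping gene bodies are allowed (only full containment is excluded),
    but a disjoint arrangement with the minus-strand gene entirely downstream
    of the plus-strand gene is convergent (tail-to-tail) and rejected.
    """
    if a.chrom != b.chrom or a.strand == b.strand:
        return False
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    d = abs(compute_tss(plus) - compute_tss(minus))
    if not (1 <= d <= max_distance):
        return False
    if _is_nested(a, b):
        return False
    if plus.end < minus.start:  # convergent: bodies disjoint, minus gene downstream
        return False
    return True


def _make_h2h_pair(a: GeneRecord, b: GeneRecord) -> GenePair:
    first, second = sorted((a, b), key=lambda g: (compute_tss(g), g.gene_id))
    return GenePair(
        gene_a=first,
        gene_b=second,
        pair_class="H2H",
        tss_distance=abs(compute_tss(a) - compute_tss(b)),
        promoter=(a.chrom, min(compute_tss(a), compute_tss(b)),
                  max(compute_tss(a), compute_tss(b))),
        biotype_label=classify_pair_biotype_from(a.biotype, b.biotype),
    )


def find_h2h_pairs(catalog: Sequence[GeneRecord], max_distance: int = 1000) -> list[GenePair]:
    """Discover H2H pairs with a 1-to-1 greedy-nearest partner assignment.

    Candidate enumeration uses a sorted-TSS window per chromosome (each minus
    gene is tested only against plus genes whose TSS lies within
    ``max_distance``), then candidates are consumed greedily by smallest TSS
    distance, ties broken by the smaller promoter coordinate and gene ids so
    the result is deterministic.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    by_chrom: dict[str, tuple[list[GeneRecord], list[GeneRecord]]] = {}
    for g in catalog:
        plus, minus = by_chrom.setdefault(g.chrom, ([], []))
        (plus if g.strand == "+" else minus).append(g)

    candidates: list[tuple[int, int, str, str, GeneRecord, GeneRecord]] = []
    for _, (plus, minus) in by_chrom.items():
        if not plus or not minus:
            continue
        plus.sort(key=compute_tss)
        plus_tss = np.array([compute_tss(g) for g in plus])
        for m in minus:
            t = compute_tss(m)
            lo = int(np.searchsorted(plus_tss, t - max_distance, side="left"))
            hi = int(np.searchsorted(plus_tss, t + max_distance, side="right"))
            for p in plus[lo:hi]:
                if is_h2h_candidate(p, m, max_distance):
                    d = abs(compute_tss(p) - t)
                    promoter_lo = min(compute_tss(p), t)
                    ia, ib = sorted((p.gene_id, m.gene_id))
                    candidates.append((d, promoter_lo, ia, ib, p, m))

    candidates.sort(key=lambda c: c[:4])
    used: set[str] = set()
    pairs: list[GenePair] = []
    for _, _, _, _, p, m in candidates:
        if p.gene_id in used or m.gene_id in used:
            continue
        used.add(p.gene_id)
        used.add(m.gene_id)
        pairs.append(_make_h2h_pair(p, m))
    return pairs


# ---------------------------------------------------------------------------
# biotype labels


def _canonical_biotype(raw: str, biotype_map: dict[str, str] | None = None) -> str:
    mapping = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    if raw not in mapping:
        logger.warning("unknown biotype %r grouped as 'other'", raw)
        return "other"
    return mapping[raw]


def classify_pair_biotype_from(biotype_a: str, biotype_b: str,
                               biotype_map: dict[str, str] | None = None) -> str:
    """Canonical ordered pair label, e.g. ``protein coding – antisense``.

    Protein coding is listed first when present; otherwise the fixed
    vocabulary order applies, so the label is symmetric in its inputs.
    """
    ca = _canonical_biotype(biotype_a, biotype_map)
    cb = _canonical_biotype(biotype_b, biotype_map)
    order = {name: i for i, name in enumerate(_BIOTYPE_PRIORITY)}
    first, second = sorted((ca, cb), key=lambda b: order.get(b, len(order)))
    da = _BIOTYPE_DISPLAY.get(first, first)
    db = _BIOTYPE_DISPLAY.get(second, second)
    return f"{da} – {db}"


def classify_pair_biotype(pair: GenePair,
                          biotype_map: dict[str, str] | None = None) -> str:
    return classify_pair_biotype_from(pair.gene_a.biotype, pair.gene_b.biotype, biotype_map)


# ---------------------------------------------------------------------------
# control pair sets


def find_adjacent_pairs(catalog: Sequence[GeneRecord]) -> list[GenePair]:
    """Consecutive same-strand genes per chromosome (no intervening gene)."""
    pairs: list[GenePair] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in catalog:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (compute_tss(g), g.gene_id))
        for left, right in zip(genes, genes[1:]):
            if left.strand == right.strand:
                pairs.append(GenePair(
                    gene_a=left, gene_b=right, pair_class="adjacent",
                    tss_distance=abs(compute_tss(left) - compute_tss(right)),
                    biotype_label=classify_pair_biotype_from(left.biotype, right.biotype),
                ))
    return pairs


def _tss_rank_index(catalog: Sequence[GeneRecord]) -> dict[str, tuple[str, int]]:
    """gene_id -> (chrom, rank of its TSS among genes of that chromosome)."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in catalog:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[str, int]] = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (compute_tss(g), g.gene_id))
        for rank, g in enumerate(genes):
            index[g.gene_id] = (chrom, rank)
    return index


def is_separated(a: GeneRecord, b: GeneRecord,
                 rank_index: dict[str, tuple[str, int]]) -> bool:
    """Random-control predicate: different chromosomes, or at least one gene
    lying between the two in TSS order."""
    ca, ra = rank_index[a.gene_id]
    cb, rb = rank_index[b.gene_id]
    return ca != cb or abs(ra - rb) >= 2


def sample_random_pairs(catalog: Sequence[GeneRecord], n: int, seed: int) -> list[GenePair]:
    """Sample ``n`` distinct random pairs separated by >= 1 intervening gene
    (or on different chromosomes), reproducibly for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    genes = list(catalog)
    if len(genes) < 3:
        raise ValueError("catalog must contain at least 3 genes")
    rank_index = _tss_rank_index(genes)
    per_chrom: dict[str, int] = {}
    for g in genes:
        per_chrom[g.chrom] = per_chrom.get(g.chrom, 0) + 1
    total_pairs = math.comb(len(genes), 2)
    non_separated = sum(m - 1 for m in per_chrom.values())
    available = total_pairs - non_separated
    if n > available:
        raise ValueError(f"requested {n} random pairs but only {available} exist")

    rng = np.random.default_rng(seed)
    genes_sorted = sorted(genes, key=lambda g: g.gene_id)
    chosen: set[frozenset[str]] = set()
    pairs: list[GenePair] = []
    if n > available // 2:
        # dense request: enumerate all valid pairs and sample exactly
        all_valid = [(i, j) for i in range(len(genes_sorted))
                     for j in range(i + 1, len(genes_sorted))
                     if is_separated(genes_sorted[i], genes_sorted[j], rank_index)]
        idx = rng.choice(len(all_valid), size=n, replace=False)
        picks = [all_valid[k] for k in sorted(int(i) for i in idx)]
    else:
        picks = []
        while len(picks) < n:
            i, j = rng.integers(0, len(genes_sorted), size=2)
            if i == j:
                continue
            i, j = (int(min(i, j)), int(max(i, j)))
            a, b = genes_sorted[i], genes_sorted[j]
            key = frozenset((a.gene_id, b.gene_id))
            if key in chosen or not is_separated(a, b, rank_index):
                continue
            chosen.add(key)
            picks.append((i, j))
    for i, j in picks:
        a, b = genes_sorted[i], genes_sorted[j]
        pairs.append(GenePair(gene_a=a, gene_b=b, pair_class="random",
                              biotype_label=classify_pair_biotype_from(a.biotype, b.biotype)))
    return pairs


# ---------------------------------------------------------------------------
# summaries and export


def bin_tss_distances(pairs: Iterable[GenePair], bin_width: int = 100,
                      max_distance: int = 1000, subset: str = "all pairs") -> DistanceHistogram:
    """Tally TSS distances into [1,100], [101,200], ... bins."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    distances = []
    for p in pairs:
        if p.tss_distance is None:
            logger.warning("pair %s|%s has no TSS distance; excluded from histogram",
                           p.gene_a.gene_id, p.gene_b.gene_id)
            continue
        distances.append(p.tss_distance)
    n_bins = math.ceil(max_distance / bin_width)
    edges = [(i * bin_width + 1, (i + 1) * bin_width) for i in range(n_bins)]
    counts = [0] * n_bins
    for d in distances:
        if 1 <= d <= n_bins * bin_width:
            counts[(d - 1) // bin_width] += 1
    return DistanceHistogram(bin_edges=edges, counts=counts, subset=subset)


def export_promoters(pairs: Iterable[GenePair], output: str | Path | TextIO) -> None:
    """Write bidirectional promoters as BED6 (0-based half-open).

    name = geneA|geneB, score = TSS distance, strand '.'.
    """
    own = isinstance(output, (str, Path))
    handle = open(output, "w") if own else output  # type: ignore[arg-type]
    try:
        for p in pairs:
            if p.promoter is None:
                raise ValueError(f"pair {p.key} has no promoter interval (not H2H?)")
            chrom, lo, hi = p.promoter
            handle.write(f"{chrom}\t{lo - 1}\t{hi}\t{p.gene_a.gene_id}|{p.gene_b.gene_id}"
                         f"\t{p.tss_distance}\t.\n")
    finally:
        if own:
            handle.close()


def read_promoters(source: str | Path | TextIO) -> list[tuple[str, int, int, str, int]]:
    """Read a promoter BED6 back to 1-based inclusive intervals."""
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source  # type: ignore[arg-type]
    try:
        out = []
        for line in handle:
            if not line.strip():
                continue
            chrom, start0, end0, name, score = line.split("\t")[:5]
            out.append((chrom, int(start0) + 1, int(end0), name, int(score)))
        return out
    finally:
        if own:
            handle.close()
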