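"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bidipair.annotation_pairs import GeneRecord


# ---------------------------------------------------------------------------
# independent brute-force H2H oracle (exhaustive all-pairs, no shortcuts)


def _oracle_tss(g: GeneRecord) -> int:
    return g.start if g.strand == "+" else g.end


def oracle_is_candidate(a: GeneRecord, b: GeneRecord, max_distance: int = 1000) -> bool:
    if a.chrom != b.chrom or a.strand == b.strand:
        return False
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    d = abs(_oracle_tss(plus) - _oracle_tss(minus))
    if d < 1 or d > max_distance:
        return False
    a_in_b = b.start <= a.start and a.end <= b.end
    b_in_a = a.start <= b.start and b.end <= a.end
    if a_in_b or b_in_a:
        return False
    if plus.end < minus.start:
        return False
    return True


def brute_force_h2h(catalog, max_distance: int = 1000):
    """Exhaustive O(n^2) candidate enumeration + independent greedy matching.

    Returns {frozenset(gene ids): tss_distance}.
    """
    cands = []
    genes = list(catalog)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if oracle_is_candidate(a, b, max_distance):
                d = abs(_oracle_tss(a) - _oracle_tss(b))
                lo = min(_oracle_tss(a), _oracle_tss(b))
                ia, ib = sorted((a.gene_id, b.gene_id))
                cands.append((d, lo, ia, ib))
    cands.sort()
    used, result = set(), {}
    for d, lo, ia, ib in cands:
        if ia in used or ib in used:
            continue
        used.update((ia, ib))
        result[frozenset((ia, ib))] = d
    return result


def random_catalog(rng: np.random.Generator, n_genes: int = 500,
                   n_chroms: int = 2, span: int = 400_000) -> list[GeneRecord]:
    """Dense random catalog (overlaps, nestings, competing partners)."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(1, span))
        length = int(rng.integers(100, 3000))
        genes.append(GeneRecord(
            gene_id=f"R{i:05d}",
            chrom=f"chr{1 + int(rng.integers(0, n_chroms))}",
            start=start, end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            biotype="protein_coding"))
    return genes


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def planted_dataset():
    """One medium synthetic dataset shared across read-only tests."""
    from bidipair import synthetic_data as syn

    gtf, truth = syn.generate_annotation(n_genes=200, h2h_fraction=0.4,
                                         seed=11, nested_decoys=2)
    matrix = syn.generate_expression(truth, n_normal=150, n_cancer=150,
                                     pcc_normal=0.2, pcc_cancer=0.5, seed=12)
    return gtf, truth, matrix
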