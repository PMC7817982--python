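"""Gene-catalog parsing, H2H discovery, control sets, histograms, BED export."""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bidipair import annotation_pairs as ap
from bidipair.annotation_pairs import GeneRecord

from conftest import brute_force_h2h, random_catalog


TOY_GTF = """\
chr1\tsrc\tgene\t100\t900\t.\t+\t.\tgene_id "A"; gene_type "protein_coding";
chr1\tsrc\tgene\t2000\t3000\t.\t-\t.\tgene_id "B"; gene_type "antisense";
chrM\tsrc\tgene\t10\t500\t.\t+\t.\tgene_id "MT1"; gene_type "protein_coding";
"""


def g(gene_id, chrom, start, end, strand, biotype="protein_coding"):
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end,
                      strand=strand, biotype=biotype)


class TestParsing:
    def test_mitochondrial_genome_excluded(self):
        catalog = ap.parse_gene_annotation(TOY_GTF)
        assert [r.gene_id for r in catalog] == ["A", "B"]
        assert catalog[0].start == 100 and catalog[0].end == 900

    def test_missing_strand_rejected_with_warning(self, caplog):
        gtf = TOY_GTF + 'chr1\tsrc\tgene\t5000\t6000\t.\t.\t.\tgene_id "C";\n'
        with caplog.at_level("WARNING"):
            catalog = ap.parse_gene_annotation(gtf)
        assert "C" not in {r.gene_id for r in catalog}
        assert any("strand" in rec.message for rec in caplog.records)

    def test_duplicate_gene_id_raises(self):
        gtf = TOY_GTF + 'chr2\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "A";\n'
        with pytest.raises(ValueError, match="duplicate"):
            ap.parse_gene_annotation(gtf)

    def test_malformed_row_names_line_number(self):
        with pytest.raises(ValueError, match="line 4"):
            ap.parse_gene_annotation(TOY_GTF + "not a gtf row\n")

    def test_synthetic_gtf_round_trips_generator_truth(self):
        from bidipair import synthetic_data as syn

        gtf, truth = syn.generate_annotation(n_genes=50, h2h_fraction=0.2, seed=3)
        catalog = ap.parse_gene_annotation(gtf)
        got = {(r.gene_id, r.start, r.end, r.strand) for r in catalog}
        want = {(r.gene_id, int(r.start), int(r.end), r.strand)
                for r in truth.genes.itertuples()}
        assert got == want


@pytest.mark.parametrize("strand,start,end,expected", [
    ("+", 100, 900, 100),
    ("-", 100, 900, 900),
    ("-", 5, 5, 5),
])
def test_tss_is_five_prime_end(strand, start, end, expected):
    assert ap.compute_tss(g("x", "chr1", start, end, strand)) == expected


class TestH2HDiscovery:
    def test_divergent_pair_within_threshold(self):
        cat = [g("A", "chr1", 1000, 2000, "-"), g("B", "chr1", 2500, 4000, "+")]
        pairs = ap.find_h2h_pairs(cat)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.tss_distance == 500
        assert p.promoter == ("chr1", 2000, 2500)

    def test_distance_over_threshold_excluded(self):
        cat = [g("A", "chr1", 1000, 2000, "-"), g("B", "chr1", 3100, 4000, "+")]
        assert ap.find_h2h_pairs(cat) == []

    def test_nested_gene_excluded(self):
        cat = [g("A", "chr1", 1000, 5000, "+"), g("B", "chr1", 2000, 3000, "-")]
        assert ap.find_h2h_pairs(cat) == []

    def test_convergent_disjoint_arrangement_excluded(self):
        # plus gene upstream, minus gene strictly downstream: tail-to-tail
        cat = [g("A", "chr1", 3000, 3200, "+"), g("B", "chr1", 3300, 3600, "-")]
        assert ap.find_h2h_pairs(cat) == []

    def test_empty_catalog_gives_empty_set(self):
        assert ap.find_h2h_pairs([]) == []

    def test_equivalent_to_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            cat = random_catalog(rng, n_genes=200)
            got = {frozenset(p.key): p.tss_distance for p in ap.find_h2h_pairs(cat)}
            assert got == brute_force_h2h(cat)

    def test_each_gene_in_at_most_one_pair(self):
        rng = np.random.default_rng(7)
        cat = random_catalog(rng, n_genes=300)
        pairs = ap.find_h2h_pairs(cat)
        ids = [gid for p in pairs for gid in p.key]
        assert len(ids) == len(set(ids))
        assert all(1 <= p.tss_distance <= 1000 for p in pairs)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        cat = random_catalog(rng, n_genes=150)
        shifted = [g(r.gene_id, r.chrom, r.start + 10_000, r.end + 10_000, r.strand)
                   for r in cat]
        before = {frozenset(p.key): p.tss_distance for p in ap.find_h2h_pairs(cat)}
        after = {frozenset(p.key): p.tss_distance for p in ap.find_h2h_pairs(shifted)}
        assert before == after

    def test_strand_mirror_isomorphism(self):
        rng = np.random.default_rng(9)
        cat = random_catalog(rng, n_genes=150)
        pivot = 1_000_000
        mirrored = [g(r.gene_id, r.chrom, pivot - r.end, pivot - r.start,
                      "+" if r.strand == "-" else "-") for r in cat]
        before = {frozenset(p.key): p.tss_distance for p in ap.find_h2h_pairs(cat)}
        after = {frozenset(p.key): p.tss_distance for p in ap.find_h2h_pairs(mirrored)}
        assert before == after


class TestBiotypeLabels:
    @pytest.mark.parametrize("ba,bb,label", [
        ("protein_coding", "antisense", "protein coding – antisense"),
        ("antisense", "protein_coding", "protein coding – antisense"),
        ("protein_coding", "protein_coding", "protein coding – protein coding"),
        ("lincRNA", "protein_coding", "protein coding – lncRNA"),
    ])
    def test_canonical_ordering(self, ba, bb, label):
        assert ap.classify_pair_biotype_from(ba, bb) == label

    def test_unknown_biotype_grouped_as_other(self, caplog):
        with caplog.at_level("WARNING"):
            label = ap.classify_pair_biotype_from("vault_RNA", "weird")
        assert label == "other – other"

    def test_label_frequencies_match_generator_truth(self):
        from bidipair import synthetic_data as syn

        gtf, truth = syn.generate_annotation(n_genes=300, h2h_fraction=0.5, seed=5)
        pairs = ap.find_h2h_pairs(ap.parse_gene_annotation(gtf))
        got = {}
        for p in pairs:
            got[p.biotype_label] = got.get(p.biotype_label, 0) + 1
        bio = dict(zip(truth.genes["gene_id"], truth.genes["biotype"]))
        want = {}
        for r in truth.pairs.itertuples():
            label = ap.classify_pair_biotype_from(bio[r.gene_a], bio[r.gene_b])
            want[label] = want.get(label, 0) + 1
        assert got == want


class TestAdjacentPairs:
    def test_three_same_strand_genes_give_two_pairs(self):
        cat = [g("A", "chr1", 100, 200, "+"), g("B", "chr1", 5000, 6000, "+"),
               g("C", "chr1", 9000, 9500, "+")]
        assert len(ap.find_adjacent_pairs(cat)) == 2

    def test_alternating_strands_give_none(self):
        cat = [g("A", "chr1", 100, 200, "+"), g("B", "chr1", 5000, 6000, "-"),
               g("C", "chr1", 9000, 9500, "+")]
        assert ap.find_adjacent_pairs(cat) == []

    def test_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(10)
        cat = random_catalog(rng, n_genes=200)
        got = {frozenset(p.key) for p in ap.find_adjacent_pairs(cat)}
        # independent oracle: sort by TSS per chromosome, pair equal-strand neighbors
        by_chrom = {}
        for r in cat:
            by_chrom.setdefault(r.chrom, []).append(r)
        want = set()
        for genes in by_chrom.values():
            genes.sort(key=lambda x: (x.start if x.strand == "+" else x.end, x.gene_id))
            for a, b in zip(genes, genes[1:]):
                if a.strand == b.strand:
                    want.add(frozenset((a.gene_id, b.gene_id)))
        assert got == want


class TestRandomPairs:
    def test_two_gene_catalog_errors(self):
        cat = [g("A", "chr1", 100, 200, "+"), g("B", "chr1", 5000, 6000, "+")]
        with pytest.raises(ValueError):
            ap.sample_random_pairs(cat, 1, seed=0)

    def test_same_seed_reproduces_pairs(self):
        rng = np.random.default_rng(11)
        cat = random_catalog(rng, n_genes=100)
        first = [p.key for p in ap.sample_random_pairs(cat, 50, seed=123)]
        second = [p.key for p in ap.sample_random_pairs(cat, 50, seed=123)]
        assert first == second

    def test_separation_predicate_never_violated(self):
        rng = np.random.default_rng(12)
        cat = random_catalog(rng, n_genes=120)
        rank = ap._tss_rank_index(cat)
        pairs = ap.sample_random_pairs(cat, 2000, seed=1)
        assert len({p.gene_ids for p in pairs}) == 2000
        for p in pairs:
            ca, ra = rank[p.gene_a.gene_id]
            cb, rb = rank[p.gene_b.gene_id]
            assert ca != cb or abs(ra - rb) >= 2

    def test_requesting_more_than_available_errors(self):
        cat = [g("A", "chr1", 100, 200, "+"), g("B", "chr1", 5000, 6000, "+"),
               g("C", "chr2", 100, 200, "-")]
        # valid pairs: A-C, B-C (A-B are neighbors) -> 2 available
        assert len(ap.sample_random_pairs(cat, 2, seed=0)) == 2
        with pytest.raises(ValueError, match="only 2"):
            ap.sample_random_pairs(cat, 3, seed=0)


class TestDistanceHistogram:
    def _pairs_with_distances(self, distances):
        out = []
        for i, d in enumerate(distances):
            a = g(f"m{i}", "chr1", 1000 * (i + 1) * 10, 1000 * (i + 1) * 10 + 100, "-")
            b = g(f"p{i}", "chr1", a.end + d, a.end + d + 100, "+")
            out.append(ap.GenePair(gene_a=a, gene_b=b, pair_class="H2H", tss_distance=d))
        return out

    def test_direct_count(self):
        hist = ap.bin_tss_distances(self._pairs_with_distances([50, 150, 99]))
        assert hist.counts[0] == 2 and hist.counts[1] == 1
        assert hist.bin_edges[0] == (1, 100)

    def test_empty_input_all_zero(self):
        hist = ap.bin_tss_distances([])
        assert hist.total == 0 and all(c == 0 for c in hist.counts)

    @given(st.lists(st.integers(min_value=1, max_value=1000), max_size=60),
           st.sampled_from([50, 100, 250]))
    @settings(derandomize=True, max_examples=100)
    def test_counts_conserve_total_for_any_distances(self, distances, width):
        hist = ap.bin_tss_distances(self._pairs_with_distances(distances),
                                    bin_width=width)
        assert hist.total == len(distances)

    def test_matches_tally_oracle_and_conserves_total(self):
        rng = np.random.default_rng(13)
        distances = [int(d) for d in rng.integers(1, 1001, size=500)]
        hist = ap.bin_tss_distances(self._pairs_with_distances(distances))
        assert hist.total == 500
        for (lo, hi), count in zip(hist.bin_edges, hist.counts):
            assert count == sum(1 for d in distances if lo <= d <= hi)


class TestPromoterExport:
    def test_bed_coordinate_conversion(self):
        cat = [g("A", "chr1", 1000, 2000, "-"), g("B", "chr1", 2500, 4000, "+")]
        pairs = ap.find_h2h_pairs(cat)
        buf = io.StringIO()
        ap.export_promoters(pairs, buf)
        assert buf.getvalue() == "chr1\t1999\t2500\tA|B\t500\t.\n"

    def test_empty_set_writes_empty_file(self, tmp_path):
        path = tmp_path / "prom.bed"
        ap.export_promoters([], path)
        assert path.read_text() == ""

    def test_round_trip_reproduces_intervals(self):
        rng = np.random.default_rng(14)
        cat = random_catalog(rng, n_genes=200)
        pairs = ap.find_h2h_pairs(cat)
        assert pairs, "fixture must contain at least one pair"
        buf = io.StringIO()
        ap.export_promoters(pairs, buf)
        buf.seek(0)
        back = ap.read_promoters(buf)
        assert [(c, lo, hi) for c, lo, hi, _, _ in back] == [p.promoter for p in pairs]
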