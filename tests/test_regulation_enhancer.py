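"""eRNA target assignment, differential eRNAs, gain/loss categories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bidipair import regulation_enhancer as renh
from bidipair import synthetic_data as syn
from bidipair.annotation_pairs import GeneRecord, GenePair
from bidipair.matrix import ExpressionMatrix
from bidipair.regulation_enhancer import EnhancerRecord


def h2h_pair(id_a="A", id_b="B", chrom="chr1", start=10_000):
    a = GeneRecord(gene_id=id_a, chrom=chrom, start=start, end=start + 1000, strand="-")
    b = GeneRecord(gene_id=id_b, chrom=chrom, start=start + 1500, end=start + 2500,
                   strand="+")
    return GenePair(gene_a=a, gene_b=b, pair_class="H2H", tss_distance=500)


def expr_matrix(values: dict[str, np.ndarray], conditions=None) -> ExpressionMatrix:
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, index=samples).T
    meta = pd.DataFrame({"sample": samples,
                         "condition": conditions or (["cancer"] * n)})
    return ExpressionMatrix(values=df, meta=meta)


class TestBlockDistance:
    def test_overlap_is_zero(self):
        p = h2h_pair()
        assert renh.block_distance(EnhancerRecord("e", "chr1", 10_500, 10_900), p) == 0

    def test_gap_measured_from_block_edge(self):
        p = h2h_pair()  # block chr1:10000-12500
        assert renh.block_distance(EnhancerRecord("e", "chr1", 20_000, 20_400), p) == 7500

    def test_other_chromosome_is_none(self):
        p = h2h_pair()
        assert renh.block_distance(EnhancerRecord("e", "chr2", 10_500, 10_900), p) is None


class TestAssignment:
    def test_distant_erna_generates_no_candidate(self):
        rng = np.random.default_rng(0)
        p = h2h_pair()
        e = EnhancerRecord("e1", "chr1", 3_000_000, 3_000_400)  # ~3 Mb away
        m = expr_matrix({"A": rng.random(50), "B": rng.random(50)})
        erna = pd.DataFrame([rng.random(50)], index=["e1"], columns=m.samples)
        out = renh.assign_enhancer_targets([e], erna, [p], m, "cancer")
        assert len(out) == 0

    def test_overlapping_monotone_erna_assigned(self):
        rng = np.random.default_rng(1)
        sig = rng.random(60)
        p = h2h_pair()
        e = EnhancerRecord("e1", "chr1", 10_500, 10_900)
        m = expr_matrix({"A": np.exp(sig), "B": rng.random(60)})
        erna = pd.DataFrame([sig], index=["e1"], columns=m.samples)
        out = renh.assign_enhancer_targets([e], erna, [p], m, "cancer")
        row = out[out["gene"] == "A"]
        assert len(row) == 1
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        assert row["distance"].iloc[0] == 0

    def test_distance_gate_monotone(self):
        """Enlarging max_dist never removes an assignment."""
        rng = np.random.default_rng(2)
        sig = rng.random(80)
        pairs = [h2h_pair("A", "B", start=10_000), h2h_pair("C", "D", start=500_000)]
        ernas = [EnhancerRecord("e1", "chr1", 100_000, 100_400),
                 EnhancerRecord("e2", "chr1", 560_000, 560_400)]
        m = expr_matrix({"A": np.exp(sig), "B": sig + rng.random(80),
                         "C": rng.random(80), "D": 2 * sig})
        erna = pd.DataFrame([sig, sig + 0.01 * rng.random(80)],
                            index=["e1", "e2"], columns=m.samples)
        small = renh.assign_enhancer_targets(ernas, erna, pairs, m, "cancer",
                                             max_dist=100_000)
        large = renh.assign_enhancer_targets(ernas, erna, pairs, m, "cancer",
                                             max_dist=1_000_000)
        assert set(zip(small["erna_id"], small["gene"])) <= \
               set(zip(large["erna_id"], large["gene"]))


class TestRegulatedPairs:
    def test_no_shared_erna_not_included(self):
        p = h2h_pair()
        assignments = pd.DataFrame({"erna_id": ["e1", "e2"], "gene": ["A", "B"],
                                    "condition": "cancer", "rho": 0.5, "q": 0.01,
                                    "distance": 0})
        assert renh.enhancer_regulated_pairs(assignments, [p]) == set()

    def test_shared_erna_included(self):
        p = h2h_pair()
        assignments = pd.DataFrame({"erna_id": ["e1", "e1"], "gene": ["A", "B"],
                                    "condition": "cancer", "rho": 0.5, "q": 0.01,
                                    "distance": 0})
        assert renh.enhancer_regulated_pairs(assignments, [p]) == {("A", "B")}


class TestDifferentialErnas:
    def _paired_matrix(self, n_pairs=20):
        samples = [f"N{i}" for i in range(n_pairs)] + [f"C{i}" for i in range(n_pairs)]
        meta = pd.DataFrame({
            "sample": samples,
            "condition": ["normal"] * n_pairs + ["cancer"] * n_pairs,
            "paired_case": [f"case{i}" for i in range(n_pairs)] * 2,
        })
        values = pd.DataFrame(np.ones((1, 2 * n_pairs)), index=["g"], columns=samples)
        return ExpressionMatrix(values=values, meta=meta), samples, n_pairs

    def test_identical_tumor_and_normal_not_de(self):
        m, samples, n = self._paired_matrix()
        erna = pd.DataFrame([[5.0] * (2 * n)], index=["e1"], columns=samples)
        out = renh.differential_ernas(erna, m)
        assert out["direction"].iloc[0] == "ns"
        assert out["log2_fc"].iloc[0] == pytest.approx(0.0)

    def test_two_fold_increase_called_up(self):
        rng = np.random.default_rng(3)
        m, samples, n = self._paired_matrix()
        base = rng.uniform(5, 10, n)
        vals = np.concatenate([base, 2.0 * base]) * np.exp(rng.normal(0, 0.05, 2 * n))
        erna = pd.DataFrame([vals], index=["e1"], columns=samples)
        out = renh.differential_ernas(erna, m)
        assert out["direction"].iloc[0] == "up"

    def test_erna_expressed_in_two_pairs_excluded(self):
        m, samples, n = self._paired_matrix()
        vals = np.zeros(2 * n)
        vals[0] = vals[n] = 5.0      # pair 0 expressed in both members
        vals[1] = vals[n + 1] = 50.0  # pair 1: huge fold change
        erna = pd.DataFrame([vals], index=["e1"], columns=samples)
        out = renh.differential_ernas(erna, m)
        assert len(out) == 0


class TestCategories:
    def test_membership_categories(self):
        pairs = [h2h_pair("A", "B"), h2h_pair("C", "D"), h2h_pair("E", "F"),
                 h2h_pair("G", "H")]
        cats = renh.categorize_pair_regulation(
            regulated_normal={("A", "B"), ("C", "D")},
            regulated_cancer={("A", "B"), ("E", "F")}, pairs=pairs)
        assert cats[("A", "B")] == "both"
        assert cats[("C", "D")] == "loss"
        assert cats[("E", "F")] == "gain"
        assert cats[("G", "H")] == "none"

    def test_categories_partition_pairs(self):
        rng = np.random.default_rng(4)
        pairs = [h2h_pair(f"a{i}", f"b{i}", start=10_000 + 100_000 * i)
                 for i in range(30)]
        reg_n = {p.key for p in pairs if rng.random() < 0.4}
        reg_c = {p.key for p in pairs if rng.random() < 0.4}
        cats = renh.categorize_pair_regulation(reg_n, reg_c, pairs)
        assert len(cats) == len(pairs)
        assert set(cats.unique()) <= {"both", "loss", "gain", "none"}


def test_planted_gain_pairs_recovered_with_largest_delta():
    """Full synthetic round trip: planted gain pairs are recovered by the
    assignment + shared-eRNA + category chain, and the gain category shows
    the largest mean differential co-expression."""
    from bidipair import coexpression as coex

    _, truth = syn.generate_annotation(n_genes=150, h2h_fraction=0.5, seed=10)
    matrix = syn.generate_expression(truth, n_normal=300, n_cancer=300,
                                     pcc_normal=0.0, pcc_cancer=0.0, seed=11)
    _, erna_table, matrix = syn.generate_regulators_and_enhancers(
        truth, matrix, n_tfs=2, targets_per_tf=2, effect_size=0.6,
        n_gain_pairs=6, n_loss_pairs=6, n_both_pairs=4, n_decoy_ernas=8, seed=12)
    records = [EnhancerRecord(erna_id=str(i), chrom=r.chrom, start=int(r.start),
                              end=int(r.end))
               for i, r in erna_table[["chrom", "start", "end"]].iterrows()]
    erna_expr = erna_table.drop(columns=["chrom", "start", "end"])
    pairs = truth.pair_records()
    reg = {}
    for cond in ("normal", "cancer"):
        assign = renh.assign_enhancer_targets(records, erna_expr, pairs, matrix, cond)
        reg[cond] = renh.enhancer_regulated_pairs(assign, pairs)
    cats = renh.categorize_pair_regulation(reg["normal"], reg["cancer"], pairs)

    planted = truth.enhancers
    key_of = {int(r.pair_id): (r.gene_a, r.gene_b) for r in truth.pairs.itertuples()}
    gain_keys = {key_of[int(r.pair_id)] for r in planted.itertuples()
                 if r.driven_condition == "gain"}
    recovered = sum(1 for k in gain_keys if cats[k] == "gain")
    assert recovered / len(gain_keys) >= 0.8

    pn = coex.pair_correlation(matrix, pairs, "normal")
    pc = coex.pair_correlation(matrix, pairs, "cancer")
    delta = (pc - pn).dropna()
    summary = renh.delta_by_category(cats, delta)
    means = dict(zip(summary["category"], summary["mean_delta"]))
    assert means["gain"] == max(means.values())
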