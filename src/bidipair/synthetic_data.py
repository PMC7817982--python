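"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the real inputs of the analysis — a gene-level GTF,
gene x sample expression for normal and cancer conditions, regulator lists,
eRNA coordinates/expression and survival tables — while recording a truth
table of everything it planted, so discovery and inference can be scored
exactly.

Key modelling choices
---------------------
* Annotation: genes are laid out along synthetic chromosomes with
  inter-entity gaps larger than the H2H distance threshold, so the only
  H2H pairs are the planted ones (plus optional nested decoys, which the
  discovery rules must reject).  TSS distances follow a mixture law whose
  mass concentrates below 400 bp with a peak in [1, 100].
* Expression: a Gaussian copula with log-normal marginals — i.e. values are
  exp(mu_g + sigma_g * z) with z latent standard normal, correlated within a
  pair.  The latent correlation is calibrated in closed form so that the
  *observable* Pearson correlation of the log-normal values matches the
  planted per-condition target.  Per-gene mu encodes the planted activity
  ordering; housekeeping genes get a higher location and lower dispersion.
* Regulators: TF targets receive a latent component of their TF's latent
  score; the mixing weight is calibrated (rho_latent = 2 sin(pi rho_s / 6))
  so the planted Spearman correlation equals the requested effect size.
  Enhancer-driven pairs share a latent eRNA factor only in the designated
  condition, producing gain/loss-of-regulation ground truth.
* Survival: exponential event times whose hazard is multiplied by the
  planted hazard ratio whenever the pair score is 1; independent exponential
  censoring calibrated to the requested censoring fraction.

Everything is driven by one integer seed and regenerates bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation_pairs import GeneRecord, GenePair, classify_pair_biotype_from
from .matrix import ExpressionMatrix

__all__ = [
    "TruthTable",
    "generate_annotation",
    "generate_expression",
    "generate_regulators_and_enhancers",
    "generate_survival",
    "latent_rho_for_pearson",
    "latent_rho_for_spearman",
    "default_distance_law",
]

DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.55,
    "antisense": 0.20,
    "lincRNA": 0.12,
    "processed_pseudogene": 0.08,
    "miRNA": 0.05,
}


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic dataset."""

    genes: pd.DataFrame   # gene_id, chrom, start, end, strand, biotype, role, pair_id, hk, mito, cancer
    pairs: pd.DataFrame   # pair_id, gene_a, gene_b, tss_distance (+ planted pcc columns later)
    seed: int
    params: dict = field(default_factory=dict)
    regulators: list[str] = field(default_factory=list)
    tf_edges: pd.DataFrame | None = None
    enhancers: pd.DataFrame | None = None
    activity_mu: pd.Series | None = None
    hazard_ratios: pd.Series | None = None

    def gene_records(self) -> list[GeneRecord]:
        return [GeneRecord(gene_id=r.gene_id, chrom=r.chrom, start=int(r.start),
                           end=int(r.end), strand=r.strand, biotype=r.biotype)
                for r in self.genes.itertuples()]

    def pair_records(self) -> list[GenePair]:
        by_id = {g.gene_id: g for g in self.gene_records()}
        out = []
        for r in self.pairs.itertuples():
            a, b = by_id[r.gene_a], by_id[r.gene_b]
            out.append(GenePair(gene_a=a, gene_b=b, pair_class="H2H",
                                tss_distance=int(r.tss_distance),
                                promoter=(a.chrom, min(a.tss, b.tss), max(a.tss, b.tss)),
                                biotype_label=classify_pair_biotype_from(a.biotype, b.biotype)))
        return out


# ---------------------------------------------------------------------------
# calibration helpers


def latent_rho_for_pearson(r: float, sigma_a: float, sigma_b: float) -> float:
    """Latent normal correlation giving observable Pearson ``r`` between
    log-normal variables exp(mu + sigma * z)."""
    if r == 0:
        return 0.0
    scale = np.sqrt(np.expm1(sigma_a**2) * np.expm1(sigma_b**2))
    arg = 1.0 + r * scale
    if arg <= 0:
        raise ValueError(f"target Pearson {r} unreachable with sigmas ({sigma_a}, {sigma_b})")
    rho = np.log(arg) / (sigma_a * sigma_b)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"target Pearson {r} needs latent correlation {rho:.3f} outside [-1,1]")
    return float(rho)


def latent_rho_for_spearman(rho_s: float) -> float:
    """Latent normal correlation giving Spearman ``rho_s`` between any
    monotone transforms of a bivariate normal."""
    if not -1.0 < rho_s < 1.0:
        raise ValueError("Spearman effect size must lie in (-1, 1)")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def default_distance_law(rng: np.random.Generator) -> int:
    """TSS-distance sampler: mass concentrated below 400 bp, peak in [1, 100]."""
    if rng.random() < 0.15:
        return int(rng.integers(1, 101))
    return int(rng.integers(1, 1001))


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(n_genes: int = 1000, h2h_fraction: float = 0.3,
                        seed: int = 0, n_chroms: int = 2,
                        max_distance: int = 1000,
                        distance_law: Callable[[np.random.Generator], int] | None = None,
                        biotype_mix: dict[str, float] | None = None,
                        hk_rate: float = 0.2, hk_rate_pairs: float | None = None,
                        mito_rate: float = 0.05, cancer_rate: float = 0.03,
                        nested_decoys: int = 0,
                        gene_length: tuple[int, int] = (200, 2000)) -> tuple[str, TruthTable]:
    """Synthetic gene-level GTF plus its truth table.

    ``h2h_fraction`` is the fraction of genes belonging to a planted H2H
    pair; remaining genes are placed as isolated singletons (or nested-decoy
    host/inner configurations) that the discovery predicates must not pair.
    """
    if not 0.0 <= h2h_fraction <= 1.0:
        raise ValueError("h2h_fraction must be in [0, 1]")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    law = distance_law or default_distance_law
    mix = biotype_mix or DEFAULT_BIOTYPE_MIX
    biotypes = list(mix)
    bio_p = np.array([mix[b] for b in biotypes], dtype=float)
    bio_p = bio_p / bio_p.sum()
    hk_rate_pairs = hk_rate if hk_rate_pairs is None else hk_rate_pairs

    n_pairs = int(n_genes * h2h_fraction) // 2
    n_decoy_genes = 2 * nested_decoys
    n_singles = n_genes - 2 * n_pairs - n_decoy_genes
    if n_singles < 0:
        raise ValueError("n_genes too small for the requested pairs and decoys")

    def glen() -> int:
        return int(rng.integers(gene_length[0], gene_length[1] + 1))

    gene_rows: list[dict] = []
    pair_rows: list[dict] = []
    gid = 0

    def new_id() -> str:
        nonlocal gid
        gid += 1
        return f"G{gid:05d}"

    # entity plan: pairs, singles and decoys interleaved deterministically
    entities = (["pair"] * n_pairs) + (["single"] * n_singles) + (["decoy"] * nested_decoys)
    entities = [entities[i] for i in rng.permutation(len(entities))]

    cursors = {f"chr{c + 1}": 10_000 for c in range(n_chroms)}
    chrom_cycle = sorted(cursors)
    for k, kind in enumerate(entities):
        chrom = chrom_cycle[k % n_chroms]
        cur = cursors[chrom]
        if kind == "pair":
            d = int(law(rng))
            if not 1 <= d <= max_distance:
                raise ValueError("distance law produced a value outside [1, max_distance]")
            lm, lp = glen(), glen()
            minus = dict(gene_id=new_id(), chrom=chrom, start=cur, end=cur + lm,
                         strand="-", biotype=str(rng.choice(biotypes, p=bio_p)),
                         role="pair", pair_id=len(pair_rows))
            tss_m = minus["end"]
            plus = dict(gene_id=new_id(), chrom=chrom, start=tss_m + d,
                        end=tss_m + d + lp, strand="+",
                        biotype=str(rng.choice(biotypes, p=bio_p)),
                        role="pair", pair_id=len(pair_rows))
            # gene_a = lower TSS (matches discovery output ordering)
            pair_rows.append(dict(pair_id=len(pair_rows), gene_a=minus["gene_id"],
                                  gene_b=plus["gene_id"], tss_distance=d))
            gene_rows.extend([minus, plus])
            cur = plus["end"]
        elif kind == "single":
            ln = glen()
            gene_rows.append(dict(gene_id=new_id(), chrom=chrom, start=cur, end=cur + ln,
                                  strand=str(rng.choice(["+", "-"])),
                                  biotype=str(rng.choice(biotypes, p=bio_p)),
                                  role="single", pair_id=-1))
            cur = cur + ln
        else:  # nested decoy: inner gene fully inside host, opposite strand,
               # TSS distance within threshold -> must be rejected by discovery
            dd = int(rng.integers(150, max_distance))
            host_len = dd + int(rng.integers(500, 2000))
            host = dict(gene_id=new_id(), chrom=chrom, start=cur, end=cur + host_len,
                        strand="+", biotype="protein_coding", role="decoy_host", pair_id=-1)
            inner = dict(gene_id=new_id(), chrom=chrom, start=cur + 50, end=cur + dd,
                         strand="-", biotype="antisense", role="decoy_inner", pair_id=-1)
            gene_rows.extend([host, inner])
            cur = host["end"]
        cursors[chrom] = cur + int(rng.integers(max_distance + 200, max_distance + 2000))

    genes = pd.DataFrame(gene_rows)
    is_pair = genes["role"] == "pair"
    genes["hk"] = np.where(is_pair, rng.random(len(genes)) < hk_rate_pairs,
                           rng.random(len(genes)) < hk_rate)
    genes["mito"] = rng.random(len(genes)) < mito_rate
    genes["cancer"] = rng.random(len(genes)) < cancer_rate

    lines = []
    for r in genes.itertuples():
        attrs = f'gene_id "{r.gene_id}"; gene_type "{r.biotype}";'
        lines.append(f"{r.chrom}\tsynthetic\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}")
    gtf = "\n".join(lines) + ("\n" if lines else "")

    truth = TruthTable(genes=genes, pairs=pd.DataFrame(
        pair_rows, columns=["pair_id", "gene_a", "gene_b", "tss_distance"]),
        seed=seed,
        params=dict(n_genes=n_genes, h2h_fraction=h2h_fraction, n_chroms=n_chroms,
                    max_distance=max_distance, hk_rate=hk_rate,
                    hk_rate_pairs=hk_rate_pairs, mito_rate=mito_rate,
                    cancer_rate=cancer_rate, nested_decoys=nested_decoys))
    return gtf, truth


# ---------------------------------------------------------------------------
# expression


def _pair_targets(values, n_pairs: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_pairs, float(arr))
    if arr.shape != (n_pairs,):
        raise ValueError(f"expected {n_pairs} per-pair correlation targets")
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("target correlations must lie in (-1, 1)")
    return arr


def generate_expression(truth: TruthTable, n_normal: int = 200, n_cancer: int = 200,
                        pcc_normal=0.2, pcc_cancer=0.4, seed: int = 0,
                        sigma_log: float = 0.5, mu_range: tuple[float, float] = (0.5, 4.0),
                        hk_mu_boost: float = 1.0, hk_sigma_factor: float = 0.6,
                        paired_fraction: float = 0.5,
                        tumor_types: Sequence[str] = ("TT1",)) -> ExpressionMatrix:
    """Expression matrix with planted per-pair, per-condition Pearson correlation.

    Records the planted targets into ``truth.pairs`` (columns pcc_normal /
    pcc_cancer) and the per-gene log-location into ``truth.activity_mu``;
    the planted activity ordering is the ordering of mu.
    """
    genes = truth.genes
    g = len(genes)
    n_pairs = len(truth.pairs)
    rng = np.random.default_rng(seed)
    targets_n = _pair_targets(pcc_normal, n_pairs)
    targets_c = _pair_targets(pcc_cancer, n_pairs)

    mu = rng.permutation(np.linspace(mu_range[0], mu_range[1], g))
    sigma = np.full(g, sigma_log)
    hk = genes["hk"].to_numpy()
    mu = mu + hk * hk_mu_boost
    sigma = np.where(hk, sigma * hk_sigma_factor, sigma)

    gene_pos = {gene_id: i for i, gene_id in enumerate(genes["gene_id"])}

    def latent(n_samples: int, targets: np.ndarray) -> np.ndarray:
        z = rng.standard_normal((g, n_samples))
        for r in truth.pairs.itertuples():
            ia, ib = gene_pos[r.gene_a], gene_pos[r.gene_b]
            rho = latent_rho_for_pearson(float(targets[r.pair_id]), sigma[ia], sigma[ib])
            zb = rho * z[ia] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_samples)
            z[ib] = zb
        return z

    z_n = latent(n_normal, targets_n)
    z_c = latent(n_cancer, targets_c)
    x_n = np.exp(mu[:, None] + sigma[:, None] * z_n)
    x_c = np.exp(mu[:, None] + sigma[:, None] * z_c)

    normal_samples = [f"N{i:04d}" for i in range(n_normal)]
    cancer_samples = [f"C{i:04d}" for i in range(n_cancer)]
    values = pd.DataFrame(np.hstack([x_n, x_c]), index=list(genes["gene_id"]),
                          columns=normal_samples + cancer_samples)

    n_paired = int(paired_fraction * min(n_normal, n_cancer))
    paired = {}
    for i in range(n_paired):
        paired[normal_samples[i]] = f"case{i:04d}"
        paired[cancer_samples[i]] = f"case{i:04d}"
    tts = list(tumor_types)
    meta = pd.DataFrame({
        "sample": normal_samples + cancer_samples,
        "condition": ["normal"] * n_normal + ["cancer"] * n_cancer,
        "tumor_type": [tts[i % len(tts)] for i in range(n_normal)]
                      + [tts[i % len(tts)] for i in range(n_cancer)],
        "paired_case": [paired.get(s) for s in normal_samples + cancer_samples],
    })

    truth.pairs["pcc_normal"] = targets_n
    truth.pairs["pcc_cancer"] = targets_c
    truth.activity_mu = pd.Series(mu, index=list(genes["gene_id"]), name="mu")
    truth.params.update(dict(n_normal=n_normal, n_cancer=n_cancer, sigma_log=sigma_log,
                             hk_mu_boost=hk_mu_boost, hk_sigma_factor=hk_sigma_factor,
                             paired_fraction=paired_fraction))
    return ExpressionMatrix(values=values, meta=meta)


# ---------------------------------------------------------------------------
# regulators and enhancers


def generate_regulators_and_enhancers(truth: TruthTable, matrix: ExpressionMatrix,
                                      n_tfs: int = 10, targets_per_tf: int = 5,
                                      effect_size: float = 0.6,
                                      n_gain_pairs: int = 0, n_loss_pairs: int = 0,
                                      n_both_pairs: int = 0, n_decoy_ernas: int = 10,
                                      n_de_up: int = 0, n_de_down: int = 0,
                                      de_fold_change: float = 2.0,
                                      erna_sigma: float = 0.5,
                                      seed: int = 0) -> tuple[list[str], pd.DataFrame, ExpressionMatrix]:
    """Plant TF-target edges and enhancer-driven pairs; emit eRNA annotation.

    Returns (regulator id list, eRNA coordinate/expression table pair as a
    DataFrame with genomic columns plus per-sample expression columns, and
    the updated expression matrix).  Planted edges land in ``truth.tf_edges``
    and planted enhancers (with their driven pair and condition) in
    ``truth.enhancers``.
    """
    if not 0.0 <= effect_size < 1.0:
        raise ValueError("effect_size must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    values = matrix.values.copy()
    mu = truth.activity_mu
    if mu is None:
        raise ValueError("generate_expression must run before regulator planting")
    sigma = pd.Series(np.where(genes["hk"].to_numpy(),
                               truth.params["sigma_log"] * truth.params["hk_sigma_factor"],
                               truth.params["sigma_log"]),
                      index=list(genes["gene_id"]))

    singles = [r.gene_id for r in genes.itertuples() if r.role == "single"]
    needed = n_tfs * (1 + targets_per_tf)
    if len(singles) < needed:
        raise ValueError(f"need {needed} singleton genes for TF planting, have {len(singles)}")
    order = [singles[i] for i in rng.permutation(len(singles))]
    tf_ids = order[:n_tfs]
    target_pool = order[n_tfs:needed]

    cond_samples = {c: matrix.samples_in(c) for c in ("normal", "cancer")}
    rho_l = latent_rho_for_spearman(effect_size) if effect_size > 0 else 0.0

    def gene_latent(gene_id: str, samples: list[str]) -> np.ndarray:
        return ((np.log(values.loc[gene_id, samples].to_numpy(dtype=float))
                 - mu[gene_id]) / sigma[gene_id])

    edges = []
    for i, tf in enumerate(tf_ids):
        for target in target_pool[i * targets_per_tf:(i + 1) * targets_per_tf]:
            for cond, samples in cond_samples.items():
                if effect_size > 0:
                    z_tf = gene_latent(tf, samples)
                    z = rho_l * z_tf + np.sqrt(1 - rho_l**2) * rng.standard_normal(len(samples))
                    values.loc[target, samples] = np.exp(mu[target] + sigma[target] * z)
                edges.append(dict(regulator=tf, gene=target, condition=cond,
                                  spearman=effect_size))
    truth.tf_edges = pd.DataFrame(edges, columns=["regulator", "gene", "condition", "spearman"])
    truth.regulators = tf_ids

    # --- enhancers -------------------------------------------------------
    n_driven = n_gain_pairs + n_loss_pairs + n_both_pairs
    pair_ids = list(truth.pairs["pair_id"])
    if n_driven > len(pair_ids):
        raise ValueError("more enhancer-driven pairs requested than planted pairs")
    chosen = [pair_ids[i] for i in rng.permutation(len(pair_ids))[:n_driven]]
    roles = (["gain"] * n_gain_pairs + ["loss"] * n_loss_pairs + ["both"] * n_both_pairs)

    all_samples = list(values.columns)
    erna_rows = []
    erna_expr = {}
    eid = 0

    def erna_coords(pair_id: int | None) -> tuple[str, int, int]:
        if pair_id is None:  # decoy far from every pair block
            chrom = f"chr{1 + eid % truth.params.get('n_chroms', 2)}"
            far = int(genes.loc[genes.chrom == chrom, "end"].max()) + 2_000_000 + 5_000 * eid
            return chrom, far, far + 400
        prow = truth.pairs.loc[truth.pairs.pair_id == pair_id].iloc[0]
        sub = genes[genes["gene_id"].isin([prow.gene_a, prow.gene_b])]
        chrom = sub.iloc[0].chrom
        anchor = int(sub["end"].max()) + int(rng.integers(10_000, 500_000))
        return chrom, anchor, anchor + 400

    def add_erna(pair_id: int | None, driven_condition: str | None) -> str:
        nonlocal eid
        erna_id = f"E{eid:04d}"
        eid += 1
        chrom, start, end = erna_coords(pair_id)
        mu_e = float(rng.uniform(1.0, 3.0))
        expr = np.exp(mu_e + erna_sigma * rng.standard_normal(len(all_samples)))
        erna_expr[erna_id] = pd.Series(expr, index=all_samples)
        erna_rows.append(dict(erna_id=erna_id, chrom=chrom, start=start, end=end,
                              pair_id=-1 if pair_id is None else pair_id,
                              driven_condition=driven_condition or "none",
                              mu=mu_e, de_direction="none"))
        return erna_id

    for pair_id, role in zip(chosen, roles):
        conditions = {"gain": ["cancer"], "loss": ["normal"], "both": ["normal", "cancer"]}[role]
        erna_id = add_erna(pair_id, role)
        prow = truth.pairs.loc[truth.pairs.pair_id == pair_id].iloc[0]
        for cond in conditions:
            samples = cond_samples[cond]
            e_latent = rng.standard_normal(len(samples))
            erna_expr[erna_id].loc[samples] = np.exp(
                erna_rows[-1]["mu"] + erna_sigma * e_latent)
            for gene_id in (prow.gene_a, prow.gene_b):
                z = rho_l * e_latent + np.sqrt(1 - rho_l**2) * rng.standard_normal(len(samples))
                values.loc[gene_id, samples] = np.exp(mu[gene_id] + sigma[gene_id] * z)

    for _ in range(n_decoy_ernas):
        add_erna(None, None)

    # differential-expression planting: multiply cancer samples
    de_targets = [r["erna_id"] for r in erna_rows]
    de_targets = [de_targets[i] for i in rng.permutation(len(de_targets))[:n_de_up + n_de_down]]
    cancer_cols = cond_samples["cancer"]
    for j, erna_id in enumerate(de_targets):
        fold = de_fold_change if j < n_de_up else 1.0 / de_fold_change
        erna_expr[erna_id].loc[cancer_cols] *= fold
        for row in erna_rows:
            if row["erna_id"] == erna_id:
                row["de_direction"] = "up" if fold > 1 else "down"

    enhancers = pd.DataFrame(erna_rows, columns=["erna_id", "chrom", "start", "end",
                                                 "pair_id", "driven_condition", "mu",
                                                 "de_direction"])
    truth.enhancers = enhancers
    expr_table = pd.DataFrame(erna_expr).T
    expr_table.index.name = "erna_id"
    updated = ExpressionMatrix(values=values, meta=matrix.meta.reset_index())
    return tf_ids, pd.concat([enhancers.set_index("erna_id")[["chrom", "start", "end"]],
                              expr_table], axis=1), updated


# ---------------------------------------------------------------------------
# survival


def generate_survival(scores: pd.DataFrame, hazard_ratios, seed: int = 0,
                      baseline_hazard: float = np.log(2) / 1000.0,
                      censoring_rate: float = 0.3,
                      endpoints: Sequence[str] = ("OS", "DFS"),
                      truth: TruthTable | None = None) -> pd.DataFrame:
    """Survival table with planted per-pair hazard ratios.

    ``scores`` is a pairs x samples 0/1 frame; each sample's hazard is
    ``baseline * prod_p HR_p**score_p``, event times exponential, censoring
    independent exponential with rate set so the expected censored fraction
    is ``censoring_rate``.  One record per sample per endpoint.
    """
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    hr = np.asarray(hazard_ratios, dtype=float)
    if hr.ndim == 0:
        hr = np.full(len(scores), float(hr))
    if (hr <= 0).any():
        raise ValueError("hazard ratios must be positive")
    if hr.shape != (len(scores),):
        raise ValueError("one hazard ratio per score row required")
    rng = np.random.default_rng(seed)
    s = scores.to_numpy(dtype=float)
    log_h = np.log(baseline_hazard) + (np.log(hr)[:, None] * s).sum(axis=0)
    hazard = np.exp(log_h)
    rows = []
    for endpoint in endpoints:
        t_event = rng.exponential(1.0 / hazard)
        if censoring_rate > 0:
            lam_c = hazard.mean() * censoring_rate / (1.0 - censoring_rate)
            t_cens = rng.exponential(1.0 / lam_c, size=len(hazard))
        else:
            t_cens = np.full(len(hazard), np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for sample, t, e in zip(scores.columns, time, event):
            rows.append(dict(sample=sample, time=float(t), event=int(e), endpoint=endpoint))
    if truth is not None:
        truth.hazard_ratios = pd.Series(hr, index=scores.index, name="hazard_ratio")
    return pd.DataFrame(rows)
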