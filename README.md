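# bidipair

Head-to-head (H2H) gene pairs — two neighboring genes on opposite DNA
strands, transcribed divergently with transcription start sites (TSSs)
within 1 kb — share a bidirectional promoter and tend to be co-expressed.
`bidipair` is a pipeline for studying how that co-regulation changes
between normal and cancer tissue: it discovers H2H pairs from a gene-level
GTF, quantifies each pair's expression correlation per condition, flags
pairs whose co-expression *shifts* in cancer, attributes co-regulation to
shared transcription factors and enhancers (via eRNA expression), and
evaluates pairs as prognostic biomarkers.

It is written for computational biologists working with bulk tumor/normal
expression cohorts (TCGA-style matrices) plus standard genome annotation,
and ships a synthetic-data module that generates every input with planted
ground truth, so the whole pipeline is testable offline.

## What it computes

* **Pair discovery** — gene-level TSSs (start on `+`, end on `-`); an H2H
  pair requires opposite strands, divergent orientation, 1 ≤ |ΔTSS| ≤ 1 kb,
  and no full nesting of one gene body in the other. Partner conflicts are
  resolved greedily by smallest TSS distance. Adjacent (same-strand
  neighbor) and random (separated) pair sets serve as controls, and the
  bidirectional promoter (the inter-TSS interval) is exported as BED.
* **Transcriptional activity** — expression values are ranked low-to-high
  within each sample; a gene's activity is its median rank across a
  condition's samples divided by the gene count, giving a score in (0, 1]
  that is invariant to monotone normalization.
* **Differential co-expression** — per-pair Pearson correlation r in each
  condition; Δ = r_cancer − r_normal, tested with a paired Wilcoxon
  signed-rank test. Pairs split at the normal-state median into LC/HC, and
  **shifted pairs** satisfy r_normal < median(r_normal) and
  r_cancer ≥ median(r_cancer). Housekeeping enrichment of shifted pairs is
  tested with a goodness-of-fit χ² on the (0, 1, 2)-housekeeping-gene
  subgroup counts.
* **Regulator inference** — a TF (or eRNA within 1 Mb of the pair's genomic
  block) is a putative regulator of a gene when Spearman ρ ≥ 0.3 with
  Benjamini–Hochberg FDR < 0.05 across all tested combinations in a
  condition. Pair TF similarity is the Jaccard index of the two genes'
  regulator sets; pairs regulated by a shared enhancer in one condition
  only are classified gain/loss-of-regulation.
* **Prognosis** — each pair yields a binary per-sample score (1 iff the
  first gene out-expresses the second), the sole covariate of a univariate
  Cox proportional-hazards fit plus a log-rank test per endpoint (OS, DFS);
  a pair significant for either endpoint is called prognostic.

## Worked example

```python
import numpy as np
from bidipair import synthetic_data as syn, annotation_pairs as ap, coexpression as coex

gtf, truth = syn.generate_annotation(n_genes=400, h2h_fraction=0.4, seed=0)
pairs = ap.find_h2h_pairs(ap.parse_gene_annotation(gtf))
print("H2H pairs:", len(pairs))

m = syn.generate_expression(truth, n_normal=300, n_cancer=300,
                            pcc_normal=0.2, pcc_cancer=0.4, seed=1)
pr = truth.pair_records()
rn = coex.pair_correlation(m, pr, "normal")
rc = coex.pair_correlation(m, pr, "cancer")
diff = coex.differential_coexpression(rn, rc.loc[rn.index])
shifted, thr = coex.find_shifted_pairs(rn, rc.loc[rn.index])
print(f"mean delta = {diff.mean_delta:.3f}, signed-rank p = {diff.p_value:.2e}")
print(f"medians: normal = {thr.t_normal:.3f}, cancer = {thr.t_cancer:.3f}; "
      f"shifted: {int(shifted.sum())} of {len(shifted)}")
```

prints

```
H2H pairs: 80
mean delta = 0.204, signed-rank p = 7.85e-15
medians: normal = 0.207, cancer = 0.405; shifted: 21 of 80
```

All 80 planted pairs are recovered; pairs planted at r = 0.2 in normal and
r = 0.4 in cancer give a mean differential co-expression of ~0.2 with an
overwhelmingly significant signed-rank test, and the data-derived median
thresholds land near the planted values. The 21 shifted calls are the pairs
whose sampled correlations straddle both medians.

### Command line

```bash
bidipair simulate --out sim --seed 7          # synthetic dataset + truth tables
bidipair pairs discover --gtf sim/genes.gtf --out pairs_out
bidipair run --config config.yaml             # full pipeline, YAML-configured
```

`bidipair run` writes per-stage TSV/JSON outputs plus a `manifest.json`
recording the seed, every threshold and input checksums; reruns with the
same config and seed are byte-identical, and completed stages are skipped.

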