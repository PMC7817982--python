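# Methods

This note documents the models and procedures implemented in `bidipair`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Pair discovery

Genes are taken from gene-level GTF rows (1-based inclusive coordinates,
kept 1-based internally; BED export converts to 0-based half-open). The
TSS is the gene feature's 5′ end — `start` on the `+` strand, `end` on the
`-` strand; no transcript-isoform resolution is attempted. The
mitochondrial genome is excluded, as are records without a usable strand.

An H2H candidate pair must satisfy, on one chromosome:

1. opposite strands;
2. 1 ≤ |ΔTSS| ≤ `max_distance` (default 1000 bp; ΔTSS = 0 is excluded so
   distance bins can start at 1);
3. neither gene body fully contained in the other;
4. divergent orientation: when the two bodies are disjoint, the minus-strand
   gene must lie upstream of the plus-strand gene. Overlapping bodies are
   retained (only full nesting is excluded), which deliberately admits
   pairs whose TSS order is inverted by 5′ overlap; the rejected disjoint
   arrangement with the minus gene downstream is tail-to-tail (convergent),
   not head-to-head.

Genes with several candidates within range are assigned 1-to-1 by greedy
smallest-TSS-distance matching, ties broken by the lower promoter
coordinate and then lexicographic gene ids, so discovery is deterministic.
The implementation enumerates candidates through a sorted-TSS window per
chromosome; tests hold it equal to an exhaustive all-pairs oracle.

Controls: *adjacent* pairs are consecutive same-strand genes in TSS order
with no intervening gene; *random* pairs are sampled without replacement
from pairs separated by at least one gene (or on different chromosomes),
reproducibly under a seed. Biotypes are normalized through a configurable
vocabulary (e.g. `lincRNA` → `lncRNA`, pseudogene subtypes pooled,
unmapped values → `other`) and pair labels order protein coding first.

## Activity, co-expression, shifted pairs

Activity: within each sample, expression values are ranked ascending with
average ties; a gene's score in a condition is the median of its ranks over
that condition's samples divided by the number of genes. Group comparisons
use the Wilcoxon rank-sum test (unpaired) or signed-rank test (paired),
reporting the median difference.

Co-expression: Pearson correlation of the two genes over a condition's
samples (minimum 3 samples; pairs with a constant gene are dropped with a
warning). Differential co-expression Δ = r_cancer − r_normal is tested
against zero with the Wilcoxon signed-rank test over pairs.

The LC/HC split and shifted-pair thresholds are data-derived medians of the
same pair universe they are applied to — the published cut-offs are treated
as dataset-specific realizations, not constants — with config overrides
(`t_normal`, `t_cancer`) to fix them externally. "Shifted" uses a strict
`<` on the normal side and `≥` on the cancer side. Pairs with an undefined
correlation in either condition leave the universe before medians are
computed. Housekeeping enrichment of the shifted subset is a goodness-of-fit
χ² of its (0, 1, 2)-HK counts against the full-universe proportions
(the background includes the shifted pairs themselves); expected-zero cells
raise an error suggesting pooling rather than silently testing. No
continuity correction by default (a flag enables Yates for the 2×2 test).

## Regulator inference

TF→gene and eRNA→gene calls share one rule: Spearman ρ ≥ 0.3 (signed —
positive regulation as defined; `absolute=True` switches to |ρ|) and
BH-adjusted FDR < 0.05, the BH family being all combinations tested in one
condition (and tumor-type stratum when stratified). Spearman is computed as
Pearson on rank-transformed vectors via one matrix product with the
t-approximation for p-values; a test pins it to `scipy.stats.spearmanr`.
Self-pairs (a regulator with itself) are never tested.

eRNA candidates are restricted to enhancers whose interval lies within
1 Mb of the pair's genomic *block* (the span of the two gene bodies;
distance 0 when overlapping). A pair is enhancer-regulated in a condition
when one eRNA is assigned to both genes; comparing conditions yields the
mutually exclusive categories both / loss (normal-only) / gain
(cancer-only) / none.

Differentially expressed eRNAs require expression (raw value > 0 in both
members) in ≥ 3 tumor–normal paired samples, |mean log2 fold change| >
log2(1.5) ≈ 0.585 (the fold-change bound is interpreted on the log2 scale
it constrains; override available) and BH-adjusted paired-t p < 0.05, with
pseudocount 1 in the log transform.

TF similarity of a pair is the Jaccard index of the two genes' regulator
sets, undefined (and excluded downstream) when the union is empty; its
association with pair correlation uses Spearman across pairs.

## Survival

The pair score is 1 per sample iff the first gene's expression strictly
exceeds the second's; ties score 0 (the literal "otherwise" branch). Each
pair is evaluated per endpoint with a univariate Cox proportional-hazards
fit (lifelines; the score is the only covariate — no adjustment) and a
log-rank test between score groups. The prognostic call uses the log-rank
p-value at α = 0.05; the Cox fit supplies the hazard ratio and direction
(protective < 1 < risk). No multiple-testing correction across pairs by
default (a BH option exists but is off, matching the raw-p convention of
the analysis this reproduces); pairs with a degenerate score distribution
(one group < 2 samples) or no events are skipped with an explicit reason,
and a pair significant for either OS or DFS enters the prognostic report.

## Synthetic data

The generator's defaults define the study conditions for all tests.

* **Annotation** (default 2 chromosomes; tested at 100–1000 genes):
  entities are laid out with inter-entity gaps above `max_distance` + 200,
  so exactly the planted pairs satisfy the discovery predicates; nested
  decoys (an antisense gene fully inside a host with in-range TSS distance)
  probe the nesting exclusion. TSS distances follow a mixture — 15 %
  uniform on [1, 100] plus 85 % uniform on [1, 1000] — putting ≈ 49 % of
  mass below 400 bp with the modal bin at [1, 100], mimicking the
  concentration of real bidirectional promoters near the core-promoter
  scale. Biotype mix defaults to 55 % protein coding, 20 % antisense, 12 %
  lincRNA, 8 % pseudogene, 5 % miRNA.
* **Expression**: exp(μ_g + σ_g·z) with latent standard normals — a
  Gaussian copula with log-normal marginals. Within a pair, the latent
  correlation is calibrated in closed form,
  ρ_latent = ln(1 + r·√((e^{σa²}−1)(e^{σb²}−1))) / (σaσb),
  so the *observable* Pearson correlation equals the planted target r
  exactly in expectation (tests confirm the estimator is unbiased to
  < 0.01 with sd ≈ 0.034 at n = 500). μ_g is a seeded permutation of a
  linear grid (default range 0.5–4 on the log scale), encoding the planted
  activity ordering; housekeeping genes get μ + 1 and σ × 0.6 (higher,
  more stable expression). σ defaults to 0.5. A configurable fraction of
  samples (default 50 %) carries tumor–normal case pairing.
* **Regulators/enhancers**: target genes receive a mixture of their TF's
  latent score with weight ρ_latent = 2·sin(πρ_s/6), the exact inverse of
  the bivariate-normal Spearman relation, so planted edges have Spearman
  ≈ the requested effect (default 0.6). Enhancer-driven pairs share a
  latent eRNA factor only in the designated condition, creating exact
  gain/loss/both ground truth; decoy eRNAs sit > 2 Mb from any block.
  Differential eRNAs are planted by multiplying cancer-sample values by a
  fold change (default 2).
* **Survival**: exponential event times with hazard λ0·∏HR^score
  (λ0 = ln2/1000 per day, i.e. a ~1000-day median), independent
  exponential censoring with rate tuned to the requested censored fraction
  (default 0.3).

What the generator does **not** emulate: batch effects, library-size or
GC biases, count discreteness and zero inflation, copy-number-driven
correlation, spatial correlation beyond planted pairs, non-proportional
hazards, and informative censoring. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean generative model,
not robustness to real-data artifacts — normalization and batch correction
are assumed upstream.

## Problem sizes and numerics

Validation runs use catalog sizes of 100–500 genes, 200–600 samples,
100–500 simulation replicates — sizes chosen so the full suite completes
in a few minutes on one CPU while keeping Monte-Carlo error well inside
the asserted tolerances (e.g. binomial sd < 0.01 at 500 replicates).
Deterministic seeding flows from a single integer through
`numpy.random.default_rng`; identical seeds regenerate every artifact
bit-for-bit, and the pipeline manifest deliberately contains no wall-clock
timestamps so whole runs are byte-reproducible. Ranks use average ties
throughout. The null prognostic-call rate measures ≈ 5–7 % at n = 200,
reflecting the known mild anti-conservatism of the asymptotic log-rank
test at moderate sample sizes rather than an implementation artifact.

## Known limitations

Gene-level TSSs ignore alternative promoters; discovery on annotations
with many overlapping isoform-driven gene models may under- or over-pair
relative to CAGE-refined TSS sets. The positive-only ρ ≥ 0.3 rule misses
repressive regulation by design. The enhancer block-distance gate is a
proximity heuristic, not a chromatin-contact model. Cox fits are
univariate; confounding by stage, age or subtype is not addressed.
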