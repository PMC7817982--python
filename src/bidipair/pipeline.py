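"""End-to-end orchestration: config, stage ordering, manifest, resumability.

Stages run in dependency order (pairs -> sets -> activity -> coexpr -> tf ->
enhancer -> survival); optional stages are skipped when their inputs are not
configured.  A JSON manifest records the package version, seed, every
parameter and the SHA-256 of every input, so a run is fully reproducible;
outputs contain no timestamps, making identical config+seed reruns
byte-identical.  Completed stages (all outputs present and marked done in
``status.json``) are skipped on re-run unless ``force`` is set.

Per-tumor-type analyses only include tumor types with strictly more than
``min_normal_samples`` (default 10) normal samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import annotation_pairs as ap
from . import gene_set_stats as gss
from . import activity as act
from . import coexpression as coex
from . import regulation_tf as rtf
from . import regulation_enhancer as renh
from . import survival as surv
from . import io as bio_io

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ["pairs", "sets", "activity", "coexpr", "tf", "enhancer", "survival"]


@dataclass
class RunConfig:
    """Validated pipeline configuration with every threshold surfaced."""

    gtf: str | None = None
    expr: str | None = None
    meta: str | None = None
    hk_genes: str | None = None
    mito_genes: str | None = None
    cancer_genes: str | None = None
    tf_list: str | None = None
    erna_bed: str | None = None
    erna_expr: str | None = None
    survival_table: str | None = None

    out_dir: str = "bidipair_run"
    seed: int = 0
    max_distance: int = 1000
    n_random_pairs: int | None = None
    rho_min: float = 0.3
    q_max: float = 0.05
    fc_log2: float = float(np.log2(1.5))
    alpha: float = 0.05
    min_normal_samples: int = 10
    max_enhancer_distance: int = 1_000_000
    t_normal: float | None = None
    t_cancer: float | None = None
    force: bool = False
    endpoints: list[str] = field(default_factory=lambda: ["OS", "DFS"])

    def validate(self) -> None:
        problems = []
        if self.gtf is None:
            problems.append("gtf: required")
        if self.max_distance < 1:
            problems.append("max_distance: must be >= 1")
        for key in ("rho_min",):
            if not -1 <= getattr(self, key) <= 1:
                problems.append(f"{key}: must be in [-1, 1]")
        for key in ("q_max", "alpha"):
            if not 0 < getattr(self, key) < 1:
                problems.append(f"{key}: must be in (0, 1)")
        if self.min_normal_samples < 0:
            problems.append("min_normal_samples: must be >= 0")
        for key in ("gtf", "expr", "meta", "hk_genes", "mito_genes", "cancer_genes",
                    "tf_list", "erna_bed", "erna_expr", "survival_table"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                problems.append(f"{key}: file not found: {path}")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    from importlib.metadata import version as pkg_version

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status_path = out / "status.json"
    status = json.loads(status_path.read_text()) if status_path.exists() else {}
    if config.force:
        status = {}

    def done(stage: str, outputs: list[Path]) -> bool:
        return (not config.force and status.get(stage) == "complete"
                and all(p.exists() for p in outputs))

    def mark(stage: str) -> None:
        status[stage] = "complete"
        _write_json(status, status_path)

    try:
        ver = pkg_version("bidipair")
    except Exception:
        ver = "unknown"
    inputs = {k: getattr(config, k) for k in
              ("gtf", "expr", "meta", "hk_genes", "mito_genes", "cancer_genes",
               "tf_list", "erna_bed", "erna_expr", "survival_table")
              if getattr(config, k) is not None}
    manifest = {
        "package": "bidipair",
        "version": ver,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in inputs and k not in ("out_dir", "force")},
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "stages": {},
    }

    failed_stage = None
    try:
        # ---- pairs ------------------------------------------------------
        pairs_out = [out / "pairs.tsv", out / "promoters.bed", out / "tss_histogram.tsv"]
        if not done("pairs", pairs_out):
            catalog = ap.parse_gene_annotation(config.gtf)
            h2h = ap.find_h2h_pairs(catalog, max_distance=config.max_distance)
            adjacent = ap.find_adjacent_pairs(catalog)
            n_random = config.n_random_pairs or max(1, len(h2h))
            random_pairs = ap.sample_random_pairs(catalog, n_random, seed=config.seed)
            bio_io.write_pairs_table(h2h + adjacent + random_pairs, pairs_out[0])
            ap.export_promoters(h2h, pairs_out[1])
            bio_io.write_histogram(ap.bin_tss_distances(
                h2h, max_distance=config.max_distance), pairs_out[2])
            mark("pairs")
        manifest["stages"]["pairs"] = {"outputs": [p.name for p in pairs_out]}

        all_pairs = bio_io.read_pairs_table(out / "pairs.tsv")
        h2h = [p for p in all_pairs if p.pair_class == "H2H"]
        random_pairs = [p for p in all_pairs if p.pair_class == "random"]
        catalog = ap.parse_gene_annotation(config.gtf)
        universe = [g.gene_id for g in catalog]
        h2h_genes = sorted({g for p in h2h for g in p.key})

        # ---- sets -------------------------------------------------------
        sets_out = [out / "set_enrichment.tsv"]
        gene_sets = {}
        for key, label in (("hk_genes", "housekeeping"), ("mito_genes", "mitochondrial"),
                           ("cancer_genes", "cancer")):
            if getattr(config, key):
                gene_sets[label] = gss.GeneSet.from_iterable(
                    label, bio_io.read_gene_list(getattr(config, key)))
        if gene_sets and not done("sets", sets_out):
            rows = []
            for label, gs in gene_sets.items():
                res = gss.overlap_enrichment(gs, h2h_genes, universe)
                rows.append({"set": label, "observed_proportion": res.observed_proportion,
                             "background_proportion": res.background_proportion,
                             "statistic": res.statistic, "p_value": res.p_value,
                             "counts": ",".join(map(str, res.counts))})
            import pandas as pd
            pd.DataFrame(rows).to_csv(sets_out[0], sep="\t", index=False)
            mark("sets")
        if gene_sets:
            manifest["stages"]["sets"] = {"outputs": [p.name for p in sets_out]}
        hk_set = gene_sets.get("housekeeping")
        if hk_set is not None:
            h2h = gss.annotate_hk_counts(h2h, hk_set)

        # ---- expression-dependent stages --------------------------------
        matrix = None
        if config.expr and config.meta:
            matrix = bio_io.read_expression(config.expr, config.meta)

        activity_out = [out / "activity.tsv", out / "activity_tests.tsv"]
        if matrix is not None and not done("activity", activity_out):
            import pandas as pd
            score_frames = {}
            for cond in ("normal", "cancer"):
                if matrix.samples_in(cond):
                    score_frames[cond] = act.condition_activity(matrix, cond)
            scores = pd.DataFrame(score_frames)
            scores.index.name = "gene"
            scores.to_csv(activity_out[0], sep="\t")
            tests = []
            h2h_in_matrix = [g for g in h2h_genes if g in matrix.genes]
            random_genes = sorted({g for p in random_pairs for g in p.key
                                   if g in matrix.genes})
            for cond, sc in score_frames.items():
                if h2h_in_matrix and random_genes:
                    cmp_res = act.compare_activity(sc.loc[h2h_in_matrix],
                                                   sc.loc[random_genes])
                    tests.append({"comparison": f"h2h_vs_random_{cond}",
                                  "statistic": cmp_res.statistic, "p_value": cmp_res.p_value,
                                  "median_difference": cmp_res.median_difference,
                                  "test": cmp_res.test})
            if {"normal", "cancer"} <= set(score_frames):
                common = score_frames["normal"].index
                cmp_res = act.compare_activity(score_frames["cancer"].loc[common],
                                               score_frames["normal"].loc[common],
                                               paired=True)
                tests.append({"comparison": "cancer_vs_normal_paired",
                              "statistic": cmp_res.statistic, "p_value": cmp_res.p_value,
                              "median_difference": cmp_res.median_difference,
                              "test": cmp_res.test})
            pd.DataFrame(tests).to_csv(activity_out[1], sep="\t", index=False)
            mark("activity")
        if matrix is not None:
            manifest["stages"]["activity"] = {"outputs": [p.name for p in activity_out]}

        coexpr_out = [out / "pair_correlations.tsv", out / "coexpr_summary.json"]
        pcc_n = pcc_c = None
        if matrix is not None and not done("coexpr", coexpr_out):
            import pandas as pd
            pcc_n = coex.pair_correlation(matrix, h2h, "normal")
            pcc_c = coex.pair_correlation(matrix, h2h, "cancer")
            common = pcc_n.index.intersection(pcc_c.index)
            diff = coex.differential_coexpression(pcc_n.loc[common], pcc_c.loc[common])
            labels, t_normal = coex.split_lc_hc(diff.table["pcc_normal"])
            shifted, thresholds = coex.find_shifted_pairs(
                diff.table["pcc_normal"], diff.table["pcc_cancer"],
                t_normal=config.t_normal, t_cancer=config.t_cancer)
            table = diff.table.copy()
            table["lc_hc"] = labels
            table["shifted"] = shifted
            hk_lookup = {p.key: p.hk_count for p in h2h}
            table["hk_count"] = [hk_lookup.get(k) for k in table.index]
            table.reset_index().to_csv(coexpr_out[0], sep="\t", index=False)
            summary = {
                "n_pairs": len(table), "mean_delta": diff.mean_delta,
                "median_delta": diff.median_delta, "signed_rank_p": diff.p_value,
                "t_normal": thresholds.t_normal, "t_cancer": thresholds.t_cancer,
                "n_shifted": int(shifted.sum()),
            }
            if hk_set is not None and shifted.any():
                shifted_pairs = [p for p in h2h if p.key in set(table.index[shifted])]
                try:
                    enr = coex.shifted_hk_enrichment(shifted_pairs, h2h, hk_set)
                    summary["shifted_hk_chi2"] = enr.statistic
                    summary["shifted_hk_p"] = enr.p_value
                except ValueError as exc:  # e.g. empty background subgroup
                    logger.warning("shifted HK enrichment not testable: %s", exc)
                    summary["shifted_hk_p"] = None
            eligible = matrix.tumor_types_with_min_normals(config.min_normal_samples)
            all_types = sorted(set(matrix.meta["tumor_type"]))
            for tt in all_types:
                if tt not in eligible:
                    logger.info("tumor type %s has <= %d normal samples; "
                                "excluded from per-type analysis", tt,
                                config.min_normal_samples)
            per_type_rows = []
            for tt in eligible:
                try:
                    ptn = coex.pair_correlation(matrix, h2h, "normal", tumor_type=tt)
                    ptc = coex.pair_correlation(matrix, h2h, "cancer", tumor_type=tt)
                except ValueError:
                    continue
                idx = ptn.index.intersection(ptc.index)
                if len(idx) == 0:
                    continue
                per_type_rows.append({
                    "tumor_type": tt, "n_pairs": len(idx),
                    "mean_delta": float((ptc.loc[idx] - ptn.loc[idx]).mean()),
                })
            summary["per_tumor_type"] = per_type_rows
            summary["excluded_tumor_types"] = [t for t in all_types if t not in eligible]
            _write_json(summary, coexpr_out[1])
            mark("coexpr")
        if matrix is not None:
            manifest["stages"]["coexpr"] = {"outputs": [p.name for p in coexpr_out]}

        # ---- tf ---------------------------------------------------------
        tf_out = [out / "tf_edges.tsv", out / "tf_similarity.tsv", out / "tf_association.json"]
        if matrix is not None and config.tf_list and not done("tf", tf_out):
            import pandas as pd
            tf_ids = bio_io.read_gene_list(config.tf_list)
            edge_frames, sims = [], {}
            for cond in ("normal", "cancer"):
                edges = rtf.infer_regulator_targets(matrix, tf_ids, cond,
                                                    rho_min=config.rho_min,
                                                    q_max=config.q_max)
                edge_frames.append(edges)
                sims[cond] = rtf.pair_tf_similarity(h2h, rtf.assignments_from_edges(edges))
            pd.concat(edge_frames).to_csv(tf_out[0], sep="\t", index=False)
            sim_table = pd.DataFrame({f"similarity_{c}": s for c, s in sims.items()})
            sim_table.reset_index().to_csv(tf_out[1], sep="\t", index=False)
            association = {}
            if pcc_n is None:
                pcc_n = coex.pair_correlation(matrix, h2h, "normal")
                pcc_c = coex.pair_correlation(matrix, h2h, "cancer")
            for cond, pcc in (("normal", pcc_n), ("cancer", pcc_c)):
                if len(sims[cond]) >= 3:
                    rho, p = rtf.similarity_correlation_association(sims[cond], pcc)
                    association[cond] = {"rho": rho, "p": p}
            _write_json(association, tf_out[2])
            mark("tf")
        if matrix is not None and config.tf_list:
            manifest["stages"]["tf"] = {"outputs": [p.name for p in tf_out]}

        # ---- enhancer ---------------------------------------------------
        enh_out = [out / "enhancer_assignments.tsv", out / "de_ernas.tsv",
                   out / "pair_regulation_categories.tsv"]
        if (matrix is not None and config.erna_bed and config.erna_expr
                and not done("enhancer", enh_out)):
            import pandas as pd
            ernas = bio_io.read_erna_bed(config.erna_bed)
            erna_expr = pd.read_csv(config.erna_expr, sep="\t", index_col=0)
            assign = {}
            for cond in ("normal", "cancer"):
                assign[cond] = renh.assign_enhancer_targets(
                    ernas, erna_expr, h2h, matrix, cond,
                    max_dist=config.max_enhancer_distance,
                    rho_min=config.rho_min, q_max=config.q_max)
            pd.concat(assign.values()).to_csv(enh_out[0], sep="\t", index=False)
            de = renh.differential_ernas(erna_expr, matrix, fc_log2=config.fc_log2,
                                         q_max=config.q_max)
            de.to_csv(enh_out[1], sep="\t", index=False)
            reg_n = renh.enhancer_regulated_pairs(assign["normal"], h2h)
            reg_c = renh.enhancer_regulated_pairs(assign["cancer"], h2h)
            cats = renh.categorize_pair_regulation(reg_n, reg_c, h2h)
            cats.rename("category").reset_index().to_csv(enh_out[2], sep="\t", index=False)
            mark("enhancer")
        if matrix is not None and config.erna_bed and config.erna_expr:
            manifest["stages"]["enhancer"] = {"outputs": [p.name for p in enh_out]}

        # ---- survival ---------------------------------------------------
        surv_out = [out / "prognosis.tsv"]
        if (matrix is not None and config.survival_table
                and not done("survival", surv_out)):
            import pandas as pd
            clin = pd.read_csv(config.survival_table, sep="\t")
            results: dict[tuple[str, str], dict[str, surv.PrognosisResult]] = {}
            for p in h2h:
                a, b = p.key
                if a not in matrix.genes or b not in matrix.genes:
                    continue
                cancer_samples = matrix.samples_in("cancer")
                scores = surv.pair_score(matrix.values[cancer_samples], a, b)
                per_ep = {}
                for endpoint in config.endpoints:
                    sub = clin[clin["endpoint"] == endpoint]
                    if len(sub) == 0:
                        continue
                    per_ep[endpoint] = surv.evaluate_pair_prognosis(
                        scores, sub, alpha=config.alpha)
                if per_ep:
                    results[p.key] = per_ep
            surv.prognostic_pair_report(results, alpha=config.alpha).to_csv(
                surv_out[0], sep="\t", index=False)
            mark("survival")
        if matrix is not None and config.survival_table:
            manifest["stages"]["survival"] = {"outputs": [p.name for p in surv_out]}
    except Exception:
        failed_stage = next((s for s in STAGES if status.get(s) != "complete"), None)
        manifest["failed_stage"] = failed_stage
        _write_json(manifest, out / "manifest.json")
        raise

    _write_json(manifest, out / "manifest.json")
    return out
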