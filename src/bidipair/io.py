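"""Plain-text readers/writers for the pipeline's tabular interchange formats.

Expression: TSV with gene ids in the first column, samples as columns.
Metadata: TSV with columns sample, condition[, tumor_type, paired_case].
Pairs: TSV with gene_a, gene_b, chrom, tss_a, tss_b, tss_distance,
pair_class, biotype_label[, hk_count].  Gene sets: one identifier per line.
eRNA annotation: BED (0-based half-open) alongside an expression TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation_pairs import GeneRecord, GenePair, compute_tss, classify_pair_biotype_from
from .matrix import ExpressionMatrix
from .regulation_enhancer import EnhancerRecord

__all__ = [
    "read_expression", "read_gene_list", "write_gene_list",
    "write_pairs_table", "read_pairs_table", "write_histogram",
    "read_erna_bed", "write_erna_bed",
]


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return ExpressionMatrix(values=values, meta=meta)


def write_expression(matrix: ExpressionMatrix, expr_path: str | Path,
                     meta_path: str | Path) -> None:
    matrix.values.to_csv(expr_path, sep="\t")
    matrix.meta.reset_index().to_csv(meta_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_pairs_table(pairs: Sequence[GenePair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append({
            "gene_a": p.gene_a.gene_id, "gene_b": p.gene_b.gene_id,
            "chrom_a": p.gene_a.chrom, "chrom_b": p.gene_b.chrom,
            "start_a": p.gene_a.start, "end_a": p.gene_a.end, "strand_a": p.gene_a.strand,
            "start_b": p.gene_b.start, "end_b": p.gene_b.end, "strand_b": p.gene_b.strand,
            "biotype_a": p.gene_a.biotype, "biotype_b": p.gene_b.biotype,
            "tss_a": compute_tss(p.gene_a), "tss_b": compute_tss(p.gene_b),
            "tss_distance": p.tss_distance if p.tss_distance is not None else "",
            "pair_class": p.pair_class,
            "biotype_label": p.biotype_label or "",
            "hk_count": p.hk_count if p.hk_count is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> list[GenePair]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = []
    for r in df.itertuples():
        a = GeneRecord(gene_id=r.gene_a, chrom=r.chrom_a, start=int(r.start_a),
                       end=int(r.end_a), strand=r.strand_a, biotype=r.biotype_a)
        b = GeneRecord(gene_id=r.gene_b, chrom=r.chrom_b, start=int(r.start_b),
                       end=int(r.end_b), strand=r.strand_b, biotype=r.biotype_b)
        d = int(r.tss_distance) if str(r.tss_distance) != "" else None
        promoter = None
        if r.pair_class == "H2H":
            promoter = (a.chrom, min(compute_tss(a), compute_tss(b)),
                        max(compute_tss(a), compute_tss(b)))
        label = r.biotype_label or classify_pair_biotype_from(a.biotype, b.biotype)
        hk = int(r.hk_count) if str(r.hk_count) != "" else None
        pairs.append(GenePair(gene_a=a, gene_b=b, pair_class=r.pair_class,
                              tss_distance=d, promoter=promoter,
                              biotype_label=label, hk_count=hk))
    return pairs


def write_histogram(hist, path: str | Path) -> None:
    pd.DataFrame({
        "bin_lo": [lo for lo, _ in hist.bin_edges],
        "bin_hi": [hi for _, hi in hist.bin_edges],
        "count": hist.counts,
    }).to_csv(path, sep="\t", index=False)


def read_erna_bed(path: str | Path) -> list[EnhancerRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        erna_id = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
        records.append(EnhancerRecord(erna_id=erna_id, chrom=chrom,
                                      start=start0 + 1, end=end0))
    return records


def write_erna_bed(records: Sequence[EnhancerRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.erna_id}\t0\t.\n")
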