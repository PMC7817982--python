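"""Gene x sample expression container with condition / tumor-type / pairing metadata.

Expression values live in a pandas DataFrame (rows = genes, columns =
samples).  Per-sample metadata carries the condition label (``normal`` or
``cancer``), an optional tumor-type code and an optional ``paired_case``
identifier linking a tumor sample to its matched normal from the same
patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ExpressionMatrix", "CONDITIONS"]

CONDITIONS = ("normal", "cancer")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            raise ValueError("sample metadata is required")
        meta = self.meta
        if meta.index.name != "sample":
            if "sample" in meta.columns:
                meta = meta.set_index("sample")
            else:
                meta = meta.rename_axis("sample")
        if "condition" not in meta.columns:
            raise ValueError("metadata must have a 'condition' column")
        bad = set(meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if "tumor_type" not in meta.columns:
            meta = meta.assign(tumor_type="NA")
        if "paired_case" not in meta.columns:
            meta = meta.assign(paired_case=pd.NA)
        missing = set(self.values.columns) - set(meta.index)
        if missing:
            raise ValueError(f"{len(missing)} samples lack metadata rows")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        # a paired case links at most one normal and one cancer sample
        linked = meta.loc[meta.index.intersection(self.values.columns)]
        with_case = linked.dropna(subset=["paired_case"])
        dup = with_case.groupby(["paired_case", "condition"]).size()
        if (dup > 1).any():
            raise ValueError("a paired_case links more than one sample per condition")
        self.meta = meta

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, condition: str, tumor_type: str | None = None) -> list[str]:
        meta = self.meta.loc[self.meta.index.intersection(self.values.columns)]
        mask = meta["condition"] == condition
        if tumor_type is not None:
            mask &= meta["tumor_type"] == tumor_type
        return [s for s in self.values.columns if s in set(meta.index[mask])]

    def condition_values(self, condition: str, tumor_type: str | None = None) -> pd.DataFrame:
        cols = self.samples_in(condition, tumor_type)
        if not cols:
            raise ValueError(f"no samples with condition={condition!r}"
                             + (f", tumor_type={tumor_type!r}" if tumor_type else ""))
        return self.values[cols]

    def paired_samples(self) -> list[tuple[str, str]]:
        """(normal_sample, cancer_sample) tuples for complete tumor-normal cases."""
        meta = self.meta.loc[self.meta.index.intersection(self.values.columns)]
        with_case = meta.dropna(subset=["paired_case"])
        out: list[tuple[str, str]] = []
        for _, grp in with_case.groupby("paired_case", sort=True):
            by_cond = grp.groupby("condition").groups
            if "normal" in by_cond and "cancer" in by_cond:
                out.append((str(list(by_cond["normal"])[0]), str(list(by_cond["cancer"])[0])))
        return out

    def tumor_types_with_min_normals(self, min_normal_samples: int = 10) -> list[str]:
        """Tumor types with strictly more than ``min_normal_samples`` normal samples."""
        meta = self.meta.loc[self.meta.index.intersection(self.values.columns)]
        counts = meta[meta["condition"] == "normal"].groupby("tumor_type").size()
        return sorted(counts.index[counts > min_normal_samples])
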