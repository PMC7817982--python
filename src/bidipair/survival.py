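"""Pair-level prognostic evaluation: binary pair score, Cox regression, log-rank.

Each gene pair is reduced to a per-sample binary score: 1 when the first
gene's expression strictly exceeds the second's, 0 otherwise (ties score 0).
The score is the sole covariate in a univariate Cox proportional-hazards fit,
and a log-rank test compares the two score groups.  A pair is called
prognostic for an endpoint (OS or DFS) when the log-rank p-value is below
alpha; a pair significant for either endpoint enters the prognostic report.
Direction is 'protective' when the hazard ratio for score 1 is below 1 and
'risk' when above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PrognosisResult", "pair_score", "evaluate_pair_prognosis", "prognostic_pair_report"]


@dataclass
class PrognosisResult:
    hazard_ratio: float | None
    cox_p: float | None
    logrank_p: float | None
    prognostic: bool
    direction: str | None  # protective | risk
    n: int
    n_events: int
    skipped: str | None = None


def pair_score(matrix: ExpressionMatrix | pd.DataFrame, gene_a: str, gene_b: str) -> pd.Series:
    """Per-sample binary score: 1 iff expr(gene_a) > expr(gene_b)."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if gene_a not in values.index or gene_b not in values.index:
        raise KeyError(f"pair genes {gene_a}/{gene_b} not both present in matrix")
    ea = values.loc[gene_a]
    eb = values.loc[gene_b]
    ok = ea.notna() & eb.notna()
    if (~ok).any():
        logger.warning("pair %s|%s: %d samples with missing values omitted",
                       gene_a, gene_b, int((~ok).sum()))
    return (ea[ok] > eb[ok]).astype(int)


def evaluate_pair_prognosis(scores: pd.Series, survival: pd.DataFrame,
                            alpha: float = 0.05) -> PrognosisResult:
    """Univariate Cox fit + log-rank test of the binary score.

    ``survival`` needs columns (time, event) indexed by (or keyed on a
    'sample' column matching) the score index.
    """
    surv = survival
    if "sample" in surv.columns:
        surv = surv.set_index("sample")
    common = scores.index.intersection(surv.index)
    df = pd.DataFrame({
        "score": scores.loc[common].astype(float),
        "time": surv.loc[common, "time"].astype(float),
        "event": surv.loc[common, "event"].astype(int),
    }).dropna()
    n = len(df)
    n_events = int(df["event"].sum())
    group_sizes = df["score"].value_counts()
    if len(group_sizes) < 2 or group_sizes.min() < 2:
        return PrognosisResult(None, None, None, False, None, n, n_events,
                               skipped="degenerate score")
    if n_events < 1:
        return PrognosisResult(None, None, None, False, None, n, n_events,
                               skipped="no events")
    g1 = df[df["score"] == 1]
    g0 = df[df["score"] == 0]
    lr = logrank_test(g1["time"], g0["time"],
                      event_observed_A=g1["event"], event_observed_B=g0["event"])
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["score"]))
        cox_p = float(cph.summary.loc["score", "p"])
    except Exception as exc:  # lifelines convergence failure
        logger.warning("Cox fit failed (%s); pair flagged", exc)
        return PrognosisResult(None, None, float(lr.p_value), False, None,
                               n, n_events, skipped="cox non-convergence")
    direction = "protective" if hr < 1 else "risk"
    prognostic = bool(lr.p_value < alpha)
    return PrognosisResult(hazard_ratio=hr, cox_p=cox_p, logrank_p=float(lr.p_value),
                           prognostic=prognostic, direction=direction,
                           n=n, n_events=n_events)


def prognostic_pair_report(results: dict[tuple[str, str], dict[str, PrognosisResult]],
                           alpha: float = 0.05) -> pd.DataFrame:
    """Ranked table over pairs x endpoints; a pair is prognostic when
    significant for either endpoint."""
    rows = []
    for (a, b), per_endpoint in results.items():
        any_sig = any(r.prognostic for r in per_endpoint.values())
        for endpoint, r in per_endpoint.items():
            rows.append({
                "gene_a": a, "gene_b": b, "endpoint": endpoint,
                "hazard_ratio": r.hazard_ratio, "cox_p": r.cox_p,
                "logrank_p": r.logrank_p, "direction": r.direction,
                "n": r.n, "n_events": r.n_events,
                "significant": r.prognostic, "prognostic_pair": any_sig,
                "skipped": r.skipped,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["prognostic_pair", "logrank_p"],
                                  ascending=[False, True], kind="mergesort")
        table = table.reset_index(drop=True)
    return table
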