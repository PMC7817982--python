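"""Shared statistical primitives: vectorized Spearman matrices and BH-FDR.

The regulator-inference modules test tens of thousands of regulator x gene
combinations; looping ``scipy.stats.spearmanr`` per combination is
prohibitively slow, so Spearman is computed as Pearson on rank-transformed
columns via one matrix product.  P-values use the standard t approximation
t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom, the same
approximation scipy applies for n above its exact-distribution cutoff.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman_matrix", "bh_adjust"]


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlation of every column of ``x`` against every column of ``y``.

    Parameters
    ----------
    x : (n_samples, n_x) array
    y : (n_samples, n_y) array

    Returns
    -------
    rho, p : (n_x, n_y) arrays.  Columns with zero variance produce NaN
        rho and p = 1 so callers can drop them explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be 2-D with a shared sample axis")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")

    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y, axis=0)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
    rho = np.clip(rho, -1.0, 1.0)
    rho[np.outer(sx == 0, np.ones_like(sy, dtype=bool))] = np.nan
    rho[np.outer(np.ones_like(sx, dtype=bool), sy == 0)] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, np.where(np.isinf(t), 0.0, p))
    return rho, p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    flat = pvalues.ravel()
    q = multipletests(flat, method="fdr_bh")[1]
    return q.reshape(pvalues.shape)
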