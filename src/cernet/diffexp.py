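"""Paired tumor vs non-tumor differential expression.

Each feature is tested with a paired two-sided t-test on the per-patient
tumor minus non-tumor log2 differences (an unpaired Welch test is available
for unmatched designs), p-values are Benjamini-Hochberg adjusted, and
features are gated on linear fold change and FDR:

    up   iff  FC >= fc_threshold      and q <= de_fdr
    down iff  FC <= 1 / fc_threshold  and q <= de_fdr

with FC = 2**(mean tumor - mean non-tumor log2 difference).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import ClinicalTable, ExpressionMatrix

log = logging.getLogger(__name__)


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test of matched vectors ``x`` (tumor), ``y`` (non-tumor).

    Pairs with a missing member are dropped.  Returns (t, p); t is on
    n-1 degrees of freedom.  If every difference is identical and nonzero
    (zero variance) the result is (inf with the sign of the mean, 0.0).
    Fewer than 3 complete pairs raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; NaNs dropped per group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p)


def bh_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up FDR adjustment (Benjamini-Hochberg, or Benjamini-Yekutieli).

    Returns q-values in the input order; monotone in the sorted order and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, n + 1))
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def differential_expression(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    fc_threshold: float = 1.5,
    de_fdr: float = 0.05,
    paired: bool = True,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-feature DE table: log2fc, fc, t, p, q, status.

    ``fc`` is the linear fold change 2**log2fc (values < 1 indicate lower
    tumor expression).  Features with fewer than 3 usable pairs are dropped
    with a log entry.  Degenerate zero-variance features are flagged.
    """
    tumor_ids, normal_ids = clinical.paired_samples()
    tum = matrix.values[tumor_ids].to_numpy(dtype=float)
    nor = matrix.values[normal_ids].to_numpy(dtype=float)

    records = []
    for i, fid in enumerate(matrix.feature_ids):
        degenerate = False
        try:
            if paired:
                t, p = paired_t_test(tum[i], nor[i])
            else:
                t, p = welch_t_test(tum[i], nor[i])
        except ValueError:
            log.info("differential_expression: skipping %s (too few complete pairs)", fid)
            continue
        if np.isinf(t):
            degenerate = True
        keep = ~(np.isnan(tum[i]) | np.isnan(nor[i]))
        log2fc = float(np.mean(tum[i][keep]) - np.mean(nor[i][keep]))
        records.append((fid, log2fc, t, p, degenerate))

    df = pd.DataFrame(records, columns=["feature_id", "log2fc", "t_stat", "p_value", "degenerate"])
    df["rna_class"] = matrix.rna_class
    df["fc"] = 2.0 ** df["log2fc"]
    df["q_value"] = bh_adjust(df["p_value"].to_numpy(), method=fdr_method) if len(df) else []
    up = (df["fc"] >= fc_threshold) & (df["q_value"] <= de_fdr)
    down = (df["fc"] <= 1.0 / fc_threshold) & (df["q_value"] <= de_fdr)
    df["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    df = df[["feature_id", "rna_class", "log2fc", "fc", "t_stat", "p_value",
             "q_value", "status", "degenerate"]]
    n_up, n_down = int((df["status"] == "up").sum()), int((df["status"] == "down").sum())
    log.info(
        "differential_expression: %s %d features -> %d up, %d down, %d ns",
        matrix.rna_class, len(df), n_up, n_down, len(df) - n_up - n_down,
    )
    return df


def cluster_samples(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples (Euclidean distance, average linkage).

    The matrix is typically restricted to DE features first.  Samples are
    pre-sorted by id, making the tree invariant to input column order; ties
    resolve deterministically.  Returns (scipy linkage matrix, leaf order).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    ordered = sorted(matrix.sample_ids)
    data = matrix.values[ordered].to_numpy(dtype=float).T
    z = linkage(pdist(data, metric="euclidean"), method="average")
    leaves = [ordered[i] for i in leaves_list(z)]
    return z, leaves
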