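"""Biomarker evaluation (ROC, logistic panels) and gene-set over-representation.

Candidate circRNAs are scored as single-marker classifiers via the
rank-based (Mann-Whitney) AUC with tie correction and a Youden-index
operating point, and as multi-marker panels via a ridge-stabilized
logistic regression whose fitted probabilities feed the same ROC
machinery.  Gene lists from the co-expression / ceRNA networks are tested
against named gene sets with an upper-tail hypergeometric test and BH
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .io import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    auc_p: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    youden_cut: float
    sensitivity: float
    specificity: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC analysis of continuous scores against binary labels.

    AUC is computed from the Mann-Whitney rank statistic with midranks for
    ties; its p-value is the two-sided normal approximation of U with tie
    correction.  The operating point maximizes Youden's J (sensitivity +
    specificity - 1); among tied maxima the smallest threshold is chosen.
    Positives are predicted at score >= threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(s)
    u = float(ranks[y].sum() - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n0)

    # normal approximation with tie correction
    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        auc_p = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
        auc_p = float(2.0 * stats.norm.sf(abs(z)))

    # curve over unique thresholds, descending
    thresholds = np.unique(s)[::-1]
    tpr = np.array([(s[y] >= t).mean() for t in thresholds])
    fpr = np.array([(s[~y] >= t).mean() for t in thresholds])
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    thresholds = np.concatenate([[np.inf], thresholds])

    j = tpr - fpr
    best_j = j.max()
    candidates = np.nonzero(j >= best_j - 1e-12)[0]
    best = candidates[np.argmin(thresholds[candidates])]
    return RocResult(
        auc=float(auc),
        auc_p=auc_p,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        youden_cut=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


def performance_label(auc: float) -> str:
    """Report adjective for an AUC band."""
    if auc > 0.9:
        return "excellent"
    if auc > 0.8:
        return "good"
    if auc > 0.7:
        return "fair"
    return "poor"


@dataclass
class LogisticFit:
    intercept: float
    weights: np.ndarray
    converged: bool
    separable: bool
    n_iter: int


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with a small L2 ridge.

    The ridge (not applied to the intercept) keeps the Newton system
    solvable for separable data; if the fit fails to converge the ridge is
    increased 1000-fold once and the fit retried, with the result flagged.
    Separability is flagged when fitted probabilities become numerically
    0/1 for every sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < 2 * (k + 1):
        raise ValueError(f"need n >= 2*(k+1) = {2*(k+1)}, have {n}")

    def _irls(lam: float) -> tuple[np.ndarray, bool, int]:
        Xd = np.column_stack([np.ones(n), X])
        beta = np.zeros(k + 1)
        penalty = lam * np.eye(k + 1)
        penalty[0, 0] = 0.0
        for it in range(1, max_iter + 1):
            eta = np.clip(Xd @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = Xd.T @ (y - mu) - penalty @ beta
            hess = (Xd * w[:, None]).T @ Xd + penalty
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                return beta, False, it
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                return beta, True, it
        return beta, False, max_iter

    beta, converged, n_iter = _irls(ridge)
    if not converged:
        beta, converged, n_iter = _irls(ridge * 1000.0)
    eta = np.clip(np.column_stack([np.ones(n), X]) @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    separable = bool(np.all((mu < 1e-4) | (mu > 1 - 1e-4)))
    return LogisticFit(
        intercept=float(beta[0]),
        weights=beta[1:].copy(),
        converged=converged,
        separable=separable,
        n_iter=n_iter,
    )


def logistic_panel(
    feature_matrix: pd.DataFrame,
    labels: np.ndarray,
    panel: list[str],
    ridge: float = 1e-6,
) -> tuple[LogisticFit, np.ndarray, RocResult]:
    """Fit a logistic panel and evaluate it by ROC on fitted probabilities.

    ``feature_matrix`` is samples x features; ``panel`` selects columns.
    Returns (fit, panel scores, RocResult).
    """
    X = feature_matrix[list(panel)].to_numpy(dtype=float)
    fit = fit_logistic(X, labels, ridge=ridge)
    eta = np.clip(fit.intercept + X @ fit.weights, -30, 30)
    scores = 1.0 / (1.0 + np.exp(-eta))
    roc = roc_auc(scores, labels)
    return fit, scores, roc


def ora(
    query: list[str],
    gene_sets: GeneSetCollection,
    background: list[str],
) -> pd.DataFrame:
    """Over-representation of a gene list against named sets.

    Upper-tail hypergeometric per set over ``background``, BH across sets.
    The query is deduplicated and clipped to the background; gene order is
    irrelevant.
    """
    bg = set(background)
    q = set(query) & bg
    if not set(query):
        raise ValueError("empty query")
    if not q:
        raise ValueError("query has no genes in the background")
    N = len(bg)
    n = len(q)
    records = []
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & bg
        K = len(members)
        m = len(members & q)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(m - 1, N, K, n)) if m > 0 else 1.0
        records.append(dict(set_name=name, overlap=m, set_size=K,
                            query_size=n, background=N, hyper_p=p))
    df = pd.DataFrame(
        records,
        columns=["set_name", "overlap", "set_size", "query_size", "background", "hyper_p"],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["hyper_p"].to_numpy())
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# the three tissue/grade classification contrasts


def grade_contrasts(clinical) -> dict[str, tuple[list[str], np.ndarray]]:
    """Sample sets and labels for the three standard contrasts.

    Returns {name: (sample_ids, labels)} for non-tumor vs grade 1-2,
    grade 1-2 vs grade 3-4, and non-tumor vs grade 3-4 (label 1 = the
    later/worse group).
    """
    d = clinical.data
    grade = d.set_index("sample_id")["grade"]
    tissue = d.set_index("sample_id")["tissue"]
    non_tumor = [s for s in d["sample_id"] if tissue[s] == "non_tumor"]
    low = [s for s in d["sample_id"] if tissue[s] == "tumor" and grade[s] in (1, 2)]
    high = [s for s in d["sample_id"] if tissue[s] == "tumor" and grade[s] in (3, 4)]
    out = {}
    for name, neg, pos in (
        ("non_tumor_vs_grade12", non_tumor, low),
        ("grade12_vs_grade34", low, high),
        ("non_tumor_vs_grade34", non_tumor, high),
    ):
        ids = neg + pos
        labels = np.array([0] * len(neg) + [1] * len(pos))
        out[name] = (ids, labels)
    return out
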