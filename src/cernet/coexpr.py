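"""Clinically relevant circRNA-mRNA co-expression networks.

All-pairs Pearson correlation between a set of clinically associated DE
circRNAs and the DE mRNAs, t-based two-sided p-values (df = n - 2), BH
correction across every tested pair, and retention at |r| >= ``r_min`` and
q <= ``fdr``.  Retained edges form an undirected bipartite network whose
connected components are reported largest-first; within a component a
small set of "nodal" circRNAs is chosen by greedy maximum coverage of the
component's genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .io import CircAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered/scaled to unit norm; returns (matrix, zero-variance mask)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0.0
    norms[zero] = 1.0
    return centered / norms[:, None], zero


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of a (Pearson or rank) correlation via t with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_edges(
    circ: ExpressionMatrix,
    mrna: ExpressionMatrix,
    r_min: float = 0.7,
    fdr: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """All-pairs correlation edges between two matrices over shared samples.

    Returns the retained edges (|r| >= r_min, BH q <= fdr across all tested
    pairs) as a DataFrame (a_id, b_id, r, p_value, q_value, method).
    Zero-variance features are skipped with a log entry.
    """
    samples = [s for s in circ.sample_ids if s in set(mrna.sample_ids)]
    n = len(samples)
    if n < 4:
        raise ValueError("need >= 4 shared samples for edge testing")
    a_vals = circ.values[samples].to_numpy(dtype=float)
    b_vals = mrna.values[samples].to_numpy(dtype=float)
    if method == "spearman":
        a_vals = np.apply_along_axis(stats.rankdata, 1, a_vals)
        b_vals = np.apply_along_axis(stats.rankdata, 1, b_vals)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    a_std, a_zero = _standardize_rows(a_vals)
    b_std, b_zero = _standardize_rows(b_vals)
    if a_zero.any() or b_zero.any():
        log.info(
            "pearson_edges: skipping %d zero-variance features",
            int(a_zero.sum() + b_zero.sum()),
        )
    r = a_std @ b_std.T
    p = correlation_p(r, n)

    a_ids = np.asarray(circ.feature_ids)
    b_ids = np.asarray(mrna.feature_ids)
    valid = ~a_zero[:, None] & ~b_zero[None, :]
    ai, bi = np.nonzero(valid)
    df = pd.DataFrame(
        {
            "a_id": a_ids[ai],
            "b_id": b_ids[bi],
            "r": r[ai, bi],
            "p_value": p[ai, bi],
        }
    )
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df["method"] = method
    kept = df[(df["r"].abs() >= r_min) & (df["q_value"] <= fdr)].copy()
    kept = kept.sort_values(["a_id", "b_id"], kind="mergesort").reset_index(drop=True)
    log.info("pearson_edges: %d/%d pairs retained", len(kept), len(df))
    return kept


def build_network(
    edges: pd.DataFrame,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Undirected graph from an edge table; node attributes optional."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.a_id, row.b_id, r=float(row.r), q=float(row.q_value))
    if node_attrs:
        for nid, attrs in node_attrs.items():
            if nid in g:
                g.nodes[nid].update(attrs)
    return g


def components(network: nx.Graph) -> list[list[str]]:
    """Connected components, largest first; ties broken by smallest node id.

    Node lists are sorted, so the output is deterministic.
    """
    comps = [sorted(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def nodal_cover(
    network: nx.Graph,
    circ_ids: Iterable[str],
    coverage_target: float = 0.93,
) -> tuple[list[str], list[float], float]:
    """Greedy maximum-coverage selection of nodal circRNAs.

    Genes are the non-circRNA nodes of the (bipartite) network.  Repeatedly
    pick the circRNA covering the most uncovered genes — ties broken by
    higher total degree, then lexicographically smaller id — until the
    covered fraction reaches ``coverage_target`` or no selection helps.
    Returns (selection order, per-step cumulative coverage, achieved
    fraction); if the target is unreachable the full useful selection is
    returned with a warning.
    """
    circ_set = {c for c in circ_ids if c in network}
    genes = {n for n in network.nodes if n not in circ_set}
    if not genes:
        return [], [], 0.0
    neighborhoods = {c: set(network.neighbors(c)) & genes for c in circ_set}

    selected: list[str] = []
    coverage_path: list[float] = []
    covered: set[str] = set()
    remaining = set(circ_set)
    while remaining:
        frac = len(covered) / len(genes)
        if frac >= coverage_target:
            break
        best = min(
            remaining,
            key=lambda c: (-len(neighborhoods[c] - covered), -network.degree(c), c),
        )
        gain = len(neighborhoods[best] - covered)
        if gain == 0:
            break
        covered |= neighborhoods[best]
        selected.append(best)
        coverage_path.append(len(covered) / len(genes))
        remaining.discard(best)
    achieved = len(covered) / len(genes)
    if achieved < coverage_target:
        log.warning(
            "nodal_cover: coverage target %.3f unreachable, achieved %.3f",
            coverage_target, achieved,
        )
    return selected, coverage_path, achieved


def host_concordance(
    circ_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    annotation: CircAnnotation,
) -> tuple[float, pd.DataFrame]:
    """Concordance of circRNA and host-gene tumor/non-tumor log2 fold changes.

    Pairs each annotated circRNA with its host gene's DE record and returns
    (Pearson r over the paired log2fc values, per-pair table with quadrant
    labels).  Quadrants: ii = both up, iii = both down (concordant);
    i = circ down / host up, iv = circ up / host down (discordant).
    """
    circ_fc = circ_de.set_index("feature_id")["log2fc"]
    mrna_fc = mrna_de.set_index("feature_id")["log2fc"]
    records = []
    for row in annotation.data.itertuples(index=False):
        if row.circ_id in circ_fc.index and row.host_gene in mrna_fc.index:
            cf = float(circ_fc[row.circ_id])
            hf = float(mrna_fc[row.host_gene])
            if cf >= 0 and hf >= 0:
                quad = "ii"
            elif cf < 0 and hf < 0:
                quad = "iii"
            elif cf < 0 <= hf:
                quad = "i"
            else:
                quad = "iv"
            records.append(
                dict(circ_id=row.circ_id, host_gene=row.host_gene,
                     circ_log2fc=cf, host_log2fc=hf, quadrant=quad,
                     concordant=quad in ("ii", "iii"))
            )
    pairs = pd.DataFrame(
        records,
        columns=["circ_id", "host_gene", "circ_log2fc", "host_log2fc",
                 "quadrant", "concordant"],
    )
    if len(pairs) < 2:
        return float("nan"), pairs
    r = float(np.corrcoef(pairs["circ_log2fc"], pairs["host_log2fc"])[0, 1])
    return r, pairs
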