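"""End-to-end orchestration of the network-inference workflow.

Stages run in a fixed order — differential expression, clinical
association, prognosis calls, co-expression edges, network components and
nodal cover, ceRNA interaction filtering / pair scoring / tiering,
triplets, clinical intersection, biomarker ROC, optional enrichment — and
every stage reads its predecessor's files from the run directory, so the
stage-by-stage CLI composes identically to :func:`run_all`.  Given a seed
the whole run is deterministic, byte for byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import grade_contrasts, logistic_panel, performance_label, roc_auc
from .cerna import (
    CeRNAThresholds,
    build_triplets,
    filter_interactions,
    intersect_clinical,
    score_pairs,
)
from .clinical import associate_features, call_prognosis
from .coexpr import build_network, components, nodal_cover, pearson_edges
from .config import RunConfig
from .diffexp import cluster_samples, differential_expression
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    RNA_CLASSES,
    check_samples_resolve,
    read_clinical_table,
    read_expression_matrix,
    read_gmt,
    read_table,
    read_target_table,
    write_clinical_table,
    write_expression_matrix,
    write_network,
    write_table,
    write_target_table,
)
from .simulate import CohortTruth, SimulationConfig, simulate_cohort
from .biomarker import ora

log = logging.getLogger(__name__)

MATRIX_FILES = {cls: f"expr_{cls}.tsv" for cls in RNA_CLASSES}


# ---------------------------------------------------------------------------
# stages (each reads its inputs from disk and writes its outputs to disk)


def stage_simulate(sim_config: SimulationConfig, outdir: str | Path) -> CohortTruth:
    """Generate a synthetic cohort and write all input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, clinical, targets, truth = simulate_cohort(sim_config)
    for cls, mat in matrices.items():
        write_expression_matrix(mat, outdir / MATRIX_FILES[cls])
    write_clinical_table(clinical, outdir / "clinical.tsv")
    write_target_table(targets, outdir / "targets.tsv")
    truth.to_yaml(outdir / "truth.yaml")
    sim_config.to_yaml(outdir / "sim_config.yaml")
    return truth


def _load_inputs(outdir: Path) -> tuple[dict[str, ExpressionMatrix], ClinicalTable]:
    clinical = read_clinical_table(outdir / "clinical.tsv")
    matrices = {
        cls: read_expression_matrix(outdir / MATRIX_FILES[cls], cls)
        for cls in RNA_CLASSES
    }
    for mat in matrices.values():
        check_samples_resolve(mat, clinical)
    return matrices, clinical


def stage_de(config: RunConfig, outdir: str | Path) -> None:
    """Differential expression per RNA class + DE-restricted sample dendrogram."""
    outdir = Path(outdir)
    matrices, clinical = _load_inputs(outdir)
    for cls, mat in matrices.items():
        de = differential_expression(
            mat, clinical,
            fc_threshold=config.fc_threshold, de_fdr=config.de_fdr,
            paired=config.paired, fdr_method=config.fdr_method,
        )
        write_table(de, outdir / f"de_{cls}.tsv")
        de_ids = de.loc[de["status"] != "ns", "feature_id"].tolist()
        if len(de_ids) >= 1 and mat.shape[1] >= 2:
            _, leaves = cluster_samples(mat.subset_features(de_ids))
            write_table(
                pd.DataFrame({"order": range(len(leaves)), "sample_id": leaves}),
                outdir / f"dendrogram_{cls}.tsv",
            )


def stage_clinical(config: RunConfig, outdir: str | Path) -> None:
    """Clinical associations and prognosis calls for DE features, per class."""
    outdir = Path(outdir)
    matrices, clinical = _load_inputs(outdir)
    for cls, mat in matrices.items():
        de = read_table(outdir / f"de_{cls}.tsv")
        assoc = associate_features(
            mat, clinical, de,
            clin_fc=config.clin_fc, clin_p=config.clin_p, adjust=config.clin_adjust,
        )
        write_table(assoc, outdir / f"clinical_assoc_{cls}.tsv")
        prog = call_prognosis(de, assoc)
        write_table(prog, outdir / f"prognosis_{cls}.tsv")


def stage_coexpr(config: RunConfig, outdir: str | Path) -> None:
    """Clinically relevant circRNA-mRNA edges, components, nodal cover, export."""
    outdir = Path(outdir)
    matrices, clinical = _load_inputs(outdir)
    de_circ = read_table(outdir / "de_circRNA.tsv")
    de_mrna = read_table(outdir / "de_mRNA.tsv")
    prog_circ = read_table(outdir / "prognosis_circRNA.tsv")

    clin_circ = sorted(set(prog_circ["feature_id"]))
    de_mrna_ids = sorted(de_mrna.loc[de_mrna["status"] != "ns", "feature_id"])
    samples = clinical.samples("tumor") if config.tumor_only else clinical.samples()

    if clin_circ and de_mrna_ids:
        edges = pearson_edges(
            matrices["circRNA"].subset_features(clin_circ).subset_samples(samples),
            matrices["mRNA"].subset_features(de_mrna_ids).subset_samples(samples),
            r_min=config.coexpr_r, fdr=config.coexpr_fdr,
        )
    else:
        edges = pd.DataFrame(columns=["a_id", "b_id", "r", "p_value", "q_value", "method"])
    write_table(edges, outdir / "coexpr_edges.tsv")

    prog_call = dict(zip(prog_circ["feature_id"], prog_circ["call"]))
    node_attrs = {}
    for nid in set(edges["a_id"]) | set(edges["b_id"]):
        is_circ = nid in set(clin_circ)
        node_attrs[nid] = dict(
            node_type="circRNA" if is_circ else "mRNA",
            prognosis=prog_call.get(nid, "none") if is_circ else "none",
        )
    net = build_network(edges, node_attrs)
    comps = components(net)
    comp_rows = [
        dict(component=i, size=len(c), members=",".join(c))
        for i, c in enumerate(comps, start=1)
    ]
    write_table(
        pd.DataFrame(comp_rows, columns=["component", "size", "members"]),
        outdir / "components.tsv",
    )

    # greedy nodal cover on the largest bipartite component
    nodal_rows = []
    if comps:
        sub = net.subgraph(comps[0])
        selected, path, achieved = nodal_cover(
            sub, clin_circ, coverage_target=config.coverage_target
        )
        nodal_rows = [
            dict(rank=i + 1, circ_id=c, cumulative_coverage=path[i], achieved=achieved)
            for i, c in enumerate(selected)
        ]
    write_table(
        pd.DataFrame(nodal_rows, columns=["rank", "circ_id", "cumulative_coverage", "achieved"]),
        outdir / "nodal.tsv",
    )

    edge_triples = [(r.a_id, "coexpr", r.b_id, {"r": float(r.r)})
                    for r in edges.itertuples(index=False)]
    write_network(node_attrs, edge_triples, outdir / "coexpr_network.sif", fmt="sif")
    write_network(node_attrs, edge_triples, outdir / "coexpr_network.graphml", fmt="graphml")


def stage_cerna(config: RunConfig, outdir: str | Path) -> None:
    """miRNA interaction filtering, ceRNA pair scoring, triplets, clinical flag."""
    outdir = Path(outdir)
    matrices, clinical = _load_inputs(outdir)
    targets = read_target_table(outdir / "targets.tsv")
    samples = clinical.samples("tumor") if config.tumor_only else clinical.samples()

    de_ids = {}
    for cls in RNA_CLASSES:
        de = read_table(outdir / f"de_{cls}.tsv")
        de_ids[cls] = sorted(de.loc[de["status"] != "ns", "feature_id"])
    sub = {
        cls: matrices[cls].subset_features(de_ids[cls]).subset_samples(samples)
        for cls in RNA_CLASSES
    }

    interactions = filter_interactions(
        targets, sub["miRNA"], {"circRNA": sub["circRNA"], "mRNA": sub["mRNA"]},
        min_predictors=config.min_predictors, alpha=config.spearman_alpha,
    )
    write_table(interactions, outdir / "interactions.tsv")

    th = CeRNAThresholds(
        hyper_alpha=config.hyper_alpha, pc_alpha=config.pc_alpha,
        ppc_alpha=config.ppc_alpha, sppc_min=config.sppc_min,
        cmi_alpha=config.cmi_alpha,
    )
    exprs = {"miRNA": sub["miRNA"], "circRNA": sub["circRNA"], "mRNA": sub["mRNA"]}
    pairs = score_pairs(
        interactions, exprs, thresholds=th,
        cmi_perms=config.cmi_perms, seed=config.seed,
        ppc_aggregate=config.ppc_aggregate,
    )
    write_table(pairs, outdir / "cerna_pairs.tsv")

    triplets = build_triplets(pairs, min_tier="moderate")
    edges = read_table(outdir / "coexpr_edges.tsv")
    triplets = intersect_clinical(triplets, edges)
    write_table(triplets, outdir / "triplets.tsv")

    tri_nodes: dict[str, dict[str, object]] = {}
    tri_edges = []
    for r in triplets[triplets["clinical_flag"]].itertuples(index=False):
        tri_nodes.setdefault(r.ceRNA1, {"node_type": r.class1})
        tri_nodes.setdefault(r.ceRNA2, {"node_type": r.class2})
        tri_nodes.setdefault(r.mirna, {"node_type": "miRNA"})
        tri_edges.append((r.ceRNA1, "ceRNA", r.ceRNA2))
        tri_edges.append((r.mirna, "targets", r.ceRNA1))
        tri_edges.append((r.mirna, "targets", r.ceRNA2))
    write_network(tri_nodes, sorted(set(tri_edges)), outdir / "cerna_network.sif", fmt="sif")


def stage_biomarker(config: RunConfig, outdir: str | Path) -> None:
    """ROC of each nodal circRNA and of the combined logistic panel."""
    outdir = Path(outdir)
    matrices, clinical = _load_inputs(outdir)
    nodal = read_table(outdir / "nodal.tsv")
    markers = [c for c in nodal["circ_id"]] if len(nodal) else []
    contrasts = grade_contrasts(clinical)
    expr = matrices["circRNA"].values

    rows = []
    panel_rows = []
    for cname, (sample_ids, labels) in contrasts.items():
        if labels.sum() == 0 or labels.sum() == len(labels):
            continue
        for marker in markers:
            scores = expr.loc[marker, sample_ids].to_numpy(dtype=float)
            roc = roc_auc(scores, labels)
            rows.append(dict(
                marker=marker, contrast=cname, auc=roc.auc, auc_p=roc.auc_p,
                youden_cut=roc.youden_cut, sensitivity=roc.sensitivity,
                specificity=roc.specificity, label=performance_label(roc.auc),
            ))
        if len(markers) >= 1 and len(labels) >= 2 * (len(markers) + 1):
            fm = expr.loc[markers, sample_ids].T.astype(float)
            fit, _, roc = logistic_panel(fm, labels, markers, ridge=config.logistic_ridge)
            panel_rows.append(dict(
                contrast=cname, panel=",".join(markers), auc=roc.auc, auc_p=roc.auc_p,
                sensitivity=roc.sensitivity, specificity=roc.specificity,
                converged=fit.converged, separable=fit.separable,
                label=performance_label(roc.auc),
            ))
    write_table(
        pd.DataFrame(rows, columns=["marker", "contrast", "auc", "auc_p", "youden_cut",
                                    "sensitivity", "specificity", "label"]),
        outdir / "roc_markers.tsv",
    )
    write_table(
        pd.DataFrame(panel_rows, columns=["contrast", "panel", "auc", "auc_p",
                                          "sensitivity", "specificity", "converged",
                                          "separable", "label"]),
        outdir / "roc_panels.tsv",
    )


def stage_enrich(config: RunConfig, outdir: str | Path, gmt_path: str | Path) -> None:
    """Over-representation of the co-expression network genes against a GMT."""
    outdir = Path(outdir)
    gene_sets = read_gmt(gmt_path)
    edges = read_table(outdir / "coexpr_edges.tsv")
    de_mrna = read_table(outdir / "de_mRNA.tsv")
    query = sorted(set(edges["b_id"])) if len(edges) else []
    background = sorted(de_mrna["feature_id"])
    if query:
        result = ora(query, gene_sets, background)
    else:
        result = pd.DataFrame(columns=["set_name", "overlap", "set_size", "query_size",
                                       "background", "hyper_p", "q_value"])
    write_table(result, outdir / "enrichment.tsv")


# ---------------------------------------------------------------------------
# Venn tallies of clinical-category membership


def venn_counts(sets_by_category: dict[str, set[str]]) -> dict[str, int]:
    """All 2^k - 1 overlap-region counts for k <= 3 named sets.

    Region keys join member category names with "&"; each feature is
    counted in exactly one region (its full membership pattern).
    """
    names = sorted(sets_by_category)
    k = len(names)
    if k > 3:
        raise ValueError("venn_counts supports at most 3 categories")
    universe = set().union(*sets_by_category.values()) if sets_by_category else set()
    regions: dict[str, int] = {}
    for r in range(1, k + 1):
        for combo in itertools.combinations(names, r):
            regions["&".join(combo)] = 0
    for f in universe:
        member = tuple(n for n in names if f in sets_by_category[n])
        regions["&".join(member)] += 1
    return regions


# ---------------------------------------------------------------------------
# run report and run_all


def _stage_counts(outdir: Path) -> dict:
    """Collect the per-stage tallies from the stage output files."""
    counts: dict = {"de": {}, "clinical": {}, "venn": {}, "coexpr": {}, "cerna": {}}
    for cls in RNA_CLASSES:
        de = read_table(outdir / f"de_{cls}.tsv")
        counts["de"][cls] = dict(
            n_tested=len(de),
            up=int((de["status"] == "up").sum()),
            down=int((de["status"] == "down").sum()),
        )
        assoc = read_table(outdir / f"clinical_assoc_{cls}.tsv")
        prog = read_table(outdir / f"prognosis_{cls}.tsv")
        sig = assoc[assoc["significant"]] if len(assoc) else assoc
        counts["clinical"][cls] = dict(
            n_associated=int(sig["feature_id"].nunique()) if len(sig) else 0,
            worse_prognostic=int((prog["call"] == "worse_prognostic").sum()) if len(prog) else 0,
            better_prognostic=int((prog["call"] == "better_prognostic").sum()) if len(prog) else 0,
            unclear=int((prog["call"] == "unclear").sum()) if len(prog) else 0,
        )
        if len(sig):
            by_cat = {
                cat: set(sig.loc[sig["category"] == cat, "feature_id"])
                for cat in sorted(sig["category"].unique())
            }
            venn = venn_counts(by_cat)
            multi = sum(v for k_, v in venn.items() if "&" in k_)
        else:
            venn, multi = {}, 0
        counts["venn"][cls] = dict(regions=venn, n_multi_category=multi)

    edges = read_table(outdir / "coexpr_edges.tsv")
    comps = read_table(outdir / "components.tsv")
    nodal = read_table(outdir / "nodal.tsv")
    counts["coexpr"] = dict(
        n_edges=len(edges),
        n_components=len(comps),
        component_sizes=[int(s) for s in comps["size"]] if len(comps) else [],
        nodal_circRNAs=list(nodal["circ_id"]) if len(nodal) else [],
        nodal_coverage=float(nodal["achieved"].iloc[0]) if len(nodal) else 0.0,
    )

    interactions = read_table(outdir / "interactions.tsv")
    pairs = read_table(outdir / "cerna_pairs.tsv")
    triplets = read_table(outdir / "triplets.tsv")
    counts["cerna"] = dict(
        n_links_tested=len(interactions),
        n_links_retained=int(interactions["retained"].sum()) if len(interactions) else 0,
        n_pairs=len(pairs),
        n_highly_confident=int((pairs["tier"] == "highly_confident").sum()) if len(pairs) else 0,
        n_moderate=int((pairs["tier"] == "moderate").sum()) if len(pairs) else 0,
        n_triplets=len(triplets),
        n_clinical_triplets=int(triplets["clinical_flag"].sum()) if len(triplets) else 0,
    )

    panels = read_table(outdir / "roc_panels.tsv")
    counts["biomarker"] = {
        row.contrast: dict(panel_auc=float(row.auc), label=row.label)
        for row in panels.itertuples(index=False)
    } if len(panels) else {}
    return counts


def run_all(
    config: RunConfig,
    outdir: str | Path,
    simulate: SimulationConfig | None = None,
    gmt_path: str | Path | None = None,
) -> dict:
    """Run every stage in order and write the run report.

    With ``simulate`` set, the cohort is generated first; otherwise the
    input files (expr_*.tsv, clinical.tsv, targets.tsv) must already be in
    ``outdir``.  Returns the report dict (also written as report.json and
    report.txt).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if simulate is not None:
        stage_simulate(simulate, outdir)
    stage_de(config, outdir)
    stage_clinical(config, outdir)
    stage_coexpr(config, outdir)
    stage_cerna(config, outdir)
    stage_biomarker(config, outdir)
    if gmt_path is not None:
        stage_enrich(config, outdir, gmt_path)

    report = dict(
        version=__version__,
        seed=config.seed,
        config=dataclasses.asdict(config),
        counts=_stage_counts(outdir),
    )
    _validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(report))
    return report


def _validate_report(report: dict) -> None:
    c = report["counts"]
    if c["cerna"]["n_clinical_triplets"] > c["cerna"]["n_triplets"]:
        raise AssertionError("clinically flagged triplets exceed total triplets")
    for cls, d in c["de"].items():
        if min(d.values()) < 0 or d["up"] + d["down"] > d["n_tested"]:
            raise AssertionError(f"inconsistent DE counts for {cls}")


def render_report(report: dict) -> str:
    c = report["counts"]
    lines = [
        f"cernet run report (version {report['version']}, seed {report['seed']})",
        "",
        "Differential expression:",
    ]
    for cls in RNA_CLASSES:
        d = c["de"][cls]
        lines.append(
            f"  {cls}: {d['up']} up / {d['down']} down of {d['n_tested']} tested"
        )
    lines.append("Clinical association / prognosis calls:")
    for cls in RNA_CLASSES:
        d = c["clinical"][cls]
        lines.append(
            f"  {cls}: {d['n_associated']} associated "
            f"({d['worse_prognostic']} worse / {d['better_prognostic']} better / "
            f"{d['unclear']} unclear); "
            f">=2 categories: {c['venn'][cls]['n_multi_category']}"
        )
    cx = c["coexpr"]
    lines += [
        "Co-expression network:",
        f"  {cx['n_edges']} edges, {cx['n_components']} components "
        f"(sizes {cx['component_sizes'][:5]})",
        f"  nodal circRNAs: {', '.join(cx['nodal_circRNAs']) or 'none'} "
        f"(coverage {cx['nodal_coverage']:.3f})",
    ]
    ce = c["cerna"]
    lines += [
        "ceRNA analysis:",
        f"  {ce['n_links_retained']}/{ce['n_links_tested']} miRNA-target links retained",
        f"  {ce['n_pairs']} candidate pairs: {ce['n_highly_confident']} highly confident, "
        f"{ce['n_moderate']} moderate",
        f"  {ce['n_triplets']} triplets, {ce['n_clinical_triplets']} clinically relevant",
    ]
    if c.get("biomarker"):
        lines.append("Biomarker panels:")
        for contrast, d in sorted(c["biomarker"].items()):
            lines.append(f"  {contrast}: panel AUC {d['panel_auc']:.3f} ({d['label']})")
    return "\n".join(lines) + "\n"
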