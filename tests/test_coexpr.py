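import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.coexpr import (
    build_network,
    components,
    host_concordance,
    nodal_cover,
    pearson_edges,
)
from cernet.io import CircAnnotation, ExpressionMatrix


def _matrix(data, features, samples, cls="circRNA"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(data, float), index=features, columns=samples), cls
    )


def naive_edges(a_vals, b_vals):
    """Double-loop correlation oracle."""
    out = {}
    n = a_vals.shape[1]
    for i in range(a_vals.shape[0]):
        for j in range(b_vals.shape[0]):
            r, p = stats.pearsonr(a_vals[i], b_vals[j])
            out[(i, j)] = (r, p)
    return out


class TestPearsonEdges:
    def test_identical_vectors_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        a = _matrix([x], ["c1"], [f"s{i}" for i in range(12)])
        b = _matrix([x], ["g1"], [f"s{i}" for i in range(12)], "mRNA")
        edges = pearson_edges(a, b, r_min=0.7, fdr=0.05)
        assert len(edges) == 1
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_formula_example(self):
        # x=(1,2,3,4), y=(1,2,3,5): direct formula gives
        # r = 6.5 / sqrt(5 * 8.75) = 0.98271...
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        expect = 6.5 / np.sqrt(5 * 8.75)
        a = _matrix([x], ["c1"], list("wxyz"))
        b = _matrix([y], ["g1"], list("wxyz"), "mRNA")
        edges = pearson_edges(a, b, r_min=0.7, fdr=1.0)
        assert edges["r"].iloc[0] == pytest.approx(expect, rel=1e-12)
        assert edges["r"].iloc[0] == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        a_vals = rng.normal(size=(20, 10))
        b_vals = rng.normal(size=(15, 10))
        samples = [f"s{i}" for i in range(10)]
        a = _matrix(a_vals, [f"c{i}" for i in range(20)], samples)
        b = _matrix(b_vals, [f"g{i}" for i in range(15)], samples, "mRNA")
        edges = pearson_edges(a, b, r_min=0.0, fdr=1.0)
        oracle = naive_edges(a_vals, b_vals)
        assert len(edges) == 300
        for row in edges.itertuples(index=False):
            i = int(row.a_id[1:])
            j = int(row.b_id[1:])
            r_ref, p_ref = oracle[(i, j)]
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_spearman_matches_scipy(self):
        rng = np.random.default_rng(2)
        a_vals = rng.normal(size=(5, 15))
        b_vals = rng.normal(size=(4, 15))
        samples = [f"s{i}" for i in range(15)]
        a = _matrix(a_vals, [f"c{i}" for i in range(5)], samples)
        b = _matrix(b_vals, [f"g{i}" for i in range(4)], samples, "mRNA")
        edges = pearson_edges(a, b, r_min=0.0, fdr=1.0, method="spearman")
        for row in edges.itertuples(index=False):
            ref = stats.spearmanr(a_vals[int(row.a_id[1:])], b_vals[int(row.b_id[1:])])
            assert row.r == pytest.approx(ref.statistic, abs=1e-12)
            assert row.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_feature_skipped(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(3)
        a = _matrix([np.ones(8), rng.normal(size=8)], ["flat", "ok"], samples)
        b = _matrix([rng.normal(size=8)], ["g1"], samples, "mRNA")
        edges = pearson_edges(a, b, r_min=0.0, fdr=1.0)
        assert set(edges["a_id"]) == {"ok"}

    def test_null_retention_is_rare(self):
        """Independent features at n=98 essentially never reach |r| >= 0.7."""
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(98)]
        a = _matrix(rng.normal(size=(30, 98)), [f"c{i}" for i in range(30)], samples)
        b = _matrix(rng.normal(size=(40, 98)), [f"g{i}" for i in range(40)], samples, "mRNA")
        edges = pearson_edges(a, b, r_min=0.7, fdr=0.05)
        assert len(edges) == 0


class TestComponents:
    def test_two_detached_pairs(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        comps = components(g)
        assert [len(c) for c in comps] == [2, 2]
        assert comps[0] == ["a", "b"]  # tie-break by smallest id

    def test_empty_edges_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        assert components(g) == [["x"], ["y"]]

    def test_star_plus_pair(self):
        g = nx.Graph([("c1", f"g{i}") for i in range(5)] + [("c2", "g9")])
        sizes = [len(c) for c in components(g)]
        assert sizes == [6, 2]


def exhaustive_best_coverage(neigh, genes, k):
    """Best achievable gene coverage with exactly k sets (oracle)."""
    best = 0
    for combo in itertools.combinations(neigh, k):
        covered = set().union(*(neigh[c] for c in combo))
        best = max(best, len(covered))
    return best / len(genes)


class TestNodalCover:
    def _net(self, mapping):
        g = nx.Graph()
        for c, gs in mapping.items():
            for gene in gs:
                g.add_edge(c, gene)
        return g

    def test_worked_example_selects_minimal_cover(self):
        mapping = {
            "circA": {"g1", "g2", "g3", "g4", "g5"},
            "circB": {"g4", "g5", "g6"},
            "circC": {"g6", "g7"},
        }
        g = self._net(mapping)
        selected, path, achieved = nodal_cover(g, mapping, coverage_target=1.0)
        assert selected == ["circA", "circC"]
        assert achieved == pytest.approx(1.0)
        assert path == [pytest.approx(5 / 7), pytest.approx(1.0)]

    def test_single_cover(self):
        mapping = {"circA": {"g1", "g2"}}
        g = self._net(mapping)
        selected, _, achieved = nodal_cover(g, mapping, coverage_target=1.0)
        assert selected == ["circA"] and achieved == 1.0

    def test_tie_break_lexicographic(self):
        mapping = {"circB": {"g1", "g2"}, "circA": {"g1", "g2"}}
        g = self._net(mapping)
        selected, _, _ = nodal_cover(g, mapping, coverage_target=1.0)
        assert selected == ["circA"]

    def test_greedy_guarantee_vs_exhaustive(self):
        """Greedy coverage >= (1 - 1/e) of exhaustive optimum at equal size."""
        rng = np.random.default_rng(5)
        for trial in range(15):
            n_circ = int(rng.integers(3, 13))
            genes = [f"g{i}" for i in range(int(rng.integers(5, 15)))]
            neigh = {
                f"c{i:02d}": set(rng.choice(genes,
                                            size=rng.integers(1, len(genes) + 1),
                                            replace=False))
                for i in range(n_circ)
            }
            g = self._net(neigh)
            covered_genes = {x for s in neigh.values() for x in s}
            selected, path, achieved = nodal_cover(g, neigh, coverage_target=1.0)
            for k, frac in enumerate(path, start=1):
                opt = exhaustive_best_coverage(neigh, covered_genes, k)
                assert frac >= (1 - 1 / np.e) * opt - 1e-12


class TestHostConcordance:
    def _annotation(self, pairs):
        rows = [(c, "chr1", 1, 100, "+", h, "exonic") for c, h in pairs]
        return CircAnnotation(pd.DataFrame(
            rows, columns=["circ_id", "chrom", "start", "end", "strand",
                           "host_gene", "circ_type"]))

    def _de(self, ids, fcs, cls):
        return pd.DataFrame({"feature_id": ids, "log2fc": fcs, "status": "up",
                             "rna_class": cls})

    def test_equal_fold_changes_fully_concordant(self):
        circ = self._de(["c1", "c2", "c3"], [1.0, -1.0, 0.5], "circRNA")
        mrna = self._de(["h1", "h2", "h3"], [1.0, -1.0, 0.5], "mRNA")
        ann = self._annotation([("c1", "h1"), ("c2", "h2"), ("c3", "h3")])
        r, pairs = host_concordance(circ, mrna, ann)
        assert r == pytest.approx(1.0)
        assert pairs["concordant"].all()

    def test_discordant_pair_flagged(self):
        circ = self._de(["c1", "c2"], [1.0, 2.0], "circRNA")
        mrna = self._de(["h1", "h2"], [-1.0, 2.0], "mRNA")
        ann = self._annotation([("c1", "h1"), ("c2", "h2")])
        _, pairs = host_concordance(circ, mrna, ann)
        assert list(pairs["quadrant"]) == ["iv", "ii"]

    def test_hand_formula_r(self):
        pts = [(1.0, 2.0), (2.0, 1.0), (-1.0, -2.0), (2.0, -1.0)]
        circ = self._de([f"c{i}" for i in range(4)], [p[0] for p in pts], "circRNA")
        mrna = self._de([f"h{i}" for i in range(4)], [p[1] for p in pts], "mRNA")
        ann = self._annotation([(f"c{i}", f"h{i}") for i in range(4)])
        r, pairs = host_concordance(circ, mrna, ann)
        ref = np.corrcoef([p[0] for p in pts], [p[1] for p in pts])[0, 1]
        assert r == pytest.approx(ref, rel=1e-12)
        assert int((~pairs["concordant"]).sum()) == 1

    def test_no_annotated_pairs(self):
        circ = self._de(["c1"], [1.0], "circRNA")
        mrna = self._de(["h1"], [1.0], "mRNA")
        ann = self._annotation([("cX", "hX")])
        r, pairs = host_concordance(circ, mrna, ann)
        assert np.isnan(r) and len(pairs) == 0


def test_planted_pairs_recovered_in_edges(default_run):
    from cernet.io import read_table
    from cernet.simulate import score_recovery
    outdir, _, truth = default_run
    edges = read_table(outdir / "coexpr_edges.tsv")
    true_pairs = sorted({(c, m) for c, _, m in truth.triplets})
    r = score_recovery(list(zip(edges["a_id"], edges["b_id"])), true_pairs)
    assert r.sensitivity > r.fdp
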