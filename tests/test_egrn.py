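"""eGRN link inference, filtering, refinement, export and validation."""

import numpy as np
import pandas as pd
import pytest

from ernanet.egrn import (
    EgrnEdge,
    assemble,
    filter_by_gwas,
    link_erna_to_genes,
    link_tf_to_erna,
    refine_by_starr,
    spearman_fdr,
    validate_network,
    write_exports,
)
from ernanet.intervals import GenomicInterval
from ernanet.motifs import MotifHit


def frame(rows, n=20, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(n)]
    return pd.DataFrame({c: rng.random(len(rows)) for c in cols}, index=rows), cols


class TestSpearman:
    def test_monotone_pairs(self):
        cols = [f"s{i}" for i in range(20)]
        a = pd.DataFrame([np.arange(20.0)], index=["x"], columns=cols)
        b = pd.DataFrame([np.arange(20.0) ** 2], index=["y"], columns=cols)
        [res] = spearman_fdr(a, b, [("x", "y")])
        assert res.rho == pytest.approx(1.0)
        b.loc["y"] = -b.loc["y"]
        [res] = spearman_fdr(a, b, [("x", "y")])
        assert res.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        cols = [f"s{i}" for i in range(20)]
        a = pd.DataFrame(rng.random((30, 20)), index=[f"a{i}" for i in range(30)], columns=cols)
        b = pd.DataFrame(rng.random((30, 20)), index=[f"b{i}" for i in range(30)], columns=cols)
        pairs = [(f"a{i}", f"b{i}") for i in range(30)]
        results = spearman_fdr(a, b, pairs)

        def rank_avg(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        for res in results:
            ra = rank_avg(a.loc[res.feature_a].to_numpy())
            rb = rank_avg(b.loc[res.feature_b].to_numpy())
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_dropped(self, caplog):
        cols = [f"s{i}" for i in range(20)]
        a = pd.DataFrame([np.ones(20)], index=["x"], columns=cols)
        b = pd.DataFrame([np.arange(20.0)], index=["y"], columns=cols)
        with caplog.at_level("WARNING"):
            assert spearman_fdr(a, b, [("x", "y")]) == []

    def test_column_mismatch_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]], index=["x"], columns=["s0", "s1"])
        b = pd.DataFrame([[1.0, 2.0]], index=["y"], columns=["s1", "s0"])
        with pytest.raises(ValueError):
            spearman_fdr(a, b, [])


def _correlated_frames(rho_pairs, n=20, seed=1):
    """Rows engineered so pair i has high/low correlation per rho_pairs."""
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(n)]
    a_rows, b_rows = {}, {}
    for i, strong in enumerate(rho_pairs):
        z = rng.standard_normal(n)
        if strong:
            a_rows[f"tf{i}"] = z + 0.05 * rng.standard_normal(n)
            b_rows[f"e{i}"] = z + 0.05 * rng.standard_normal(n)
        else:
            a_rows[f"tf{i}"] = rng.standard_normal(n)
            b_rows[f"e{i}"] = rng.standard_normal(n)
    return (
        pd.DataFrame(a_rows, index=cols).T,
        pd.DataFrame(b_rows, index=cols).T,
        cols,
    )


class TestTfLinks:
    def test_threshold_conjunction(self):
        tf_expr, erna_expr, _ = _correlated_frames([True, True, False])
        hits = [
            MotifHit("m0", "e0", 0, "+", 5.0),
            MotifHit("m2", "e2", 0, "+", 5.0),  # correlated=False -> no edge
            # tf1 correlated but no motif hit -> no edge
        ]
        edges = link_tf_to_erna(
            ["tf0", "tf1", "tf2"], ["e0", "e1", "e2"], hits,
            tf_expr, erna_expr,
            {"tf0": True, "tf1": True, "tf2": True},
            {"tf0": "m0", "tf1": "m1", "tf2": "m2"},
        )
        assert [(e.source, e.target) for e in edges] == [("tf0", "e0")]
        assert edges[0].motif_hit

    def test_unexpressed_tf_blocked(self):
        tf_expr, erna_expr, _ = _correlated_frames([True])
        hits = [MotifHit("m0", "e0", 0, "+", 5.0)]
        edges = link_tf_to_erna(
            ["tf0"], ["e0"], hits, tf_expr, erna_expr, {"tf0": False}, {"tf0": "m0"}
        )
        assert edges == []

    def test_rho_exactly_at_threshold_excluded(self):
        cols = [f"s{i}" for i in range(5)]
        # hand-built vectors with sample Spearman exactly 0.5
        a = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["tf0"], columns=cols)
        b = pd.DataFrame([[1.0, 4, 2, 5, 3]], index=["e0"], columns=cols)
        [res] = spearman_fdr(a, b, [("tf0", "e0")])
        assert res.rho == pytest.approx(0.5)
        edges = link_tf_to_erna(
            ["tf0"], ["e0"], [MotifHit("m0", "e0", 0, "+", 5.0)],
            a, b, {"tf0": True}, {"tf0": "m0"},
        )
        assert edges == []


class TestGeneLinks:
    tads = [
        GenomicInterval("chr1", 0, 2_000_000, ".", "tadA"),
        GenomicInterval("chr1", 2_000_000, 4_000_000, ".", "tadB"),
    ]

    def _expr(self):
        erna_expr, gene_expr, _ = _correlated_frames([True])
        return erna_expr.rename(index={"tf0": "e0"}), gene_expr.rename(index={"e0": "g0"})

    def test_edge_with_all_conditions(self):
        erna_expr, gene_expr = self._expr()
        regions = {"e0": GenomicInterval("chr1", 100_000, 106_000, ".", "e0")}
        edges = link_erna_to_genes(
            regions, {"g0": ("chr1", 600_000)}, erna_expr, gene_expr, self.tads
        )
        assert len(edges) == 1
        assert edges[0].distance == 600_000 - 103_000
        assert edges[0].tad_id == "tadA"

    def test_distance_beyond_1mb_blocked(self):
        erna_expr, gene_expr = self._expr()
        regions = {"e0": GenomicInterval("chr1", 100_000, 106_000, ".", "e0")}
        edges = link_erna_to_genes(
            regions, {"g0": ("chr1", 1_603_001)}, erna_expr, gene_expr, self.tads
        )
        assert edges == []

    def test_different_tads_blocked(self):
        erna_expr, gene_expr = self._expr()
        regions = {"e0": GenomicInterval("chr1", 1_900_000, 1_906_000, ".", "e0")}
        edges = link_erna_to_genes(
            regions, {"g0": ("chr1", 2_100_000)}, erna_expr, gene_expr, self.tads
        )
        assert edges == []

    def test_anchor_outside_all_tads_dropped(self):
        erna_expr, gene_expr = self._expr()
        regions = {"e0": GenomicInterval("chr2", 100_000, 106_000, ".", "e0")}
        edges = link_erna_to_genes(
            regions, {"g0": ("chr2", 200_000)}, erna_expr, gene_expr, self.tads
        )
        assert edges == []


class TestGwasFilter:
    regions = {"e1": GenomicInterval("chr1", 100_000, 106_000)}

    def test_hit_within_20kb_keeps(self):
        assert filter_by_gwas(self.regions, [("chr1", 110_000)]) == {"e1"}

    def test_hit_beyond_window_drops(self):
        assert filter_by_gwas(self.regions, [("chr1", 130_000)]) == set()

    def test_no_hits_empty(self):
        assert filter_by_gwas(self.regions, []) == set()


def _tiny_network():
    edges = [
        EgrnEdge("TF->eRNA", "tf0", "e0", 0.9, 0.001, motif_hit=True),
        EgrnEdge("TF->eRNA", "tf1", "e0", 0.8, 0.002, motif_hit=True),
        EgrnEdge("eRNA->gene", "e0", "g0", 0.7, 0.001, distance=1000, tad_id="t"),
        EgrnEdge("eRNA->gene", "e0", "g1", 0.6, 0.002, distance=2000, tad_id="t"),
        EgrnEdge("eRNA->gene", "e0", "g2", 0.5, 0.003, distance=3000, tad_id="t"),
        EgrnEdge("eRNA->gene", "e1", "g3", 0.5, 0.003, distance=3000, tad_id="t"),
    ]
    return assemble(edges)


class TestAssembleAndRefine:
    def test_node_and_edge_counts(self):
        net = _tiny_network()
        assert (len(net.tfs), len(net.ernas), len(net.genes), len(net.edges)) == (2, 2, 4, 6)

    def test_duplicate_edge_stored_once(self):
        e = EgrnEdge("TF->eRNA", "tf0", "e0", 0.9, 0.001, motif_hit=True)
        net = assemble([e, e])
        assert len(net.edges) == 1

    def test_empty_edge_list_valid(self, tmp_path):
        net = assemble([])
        paths = write_exports(net, tmp_path)
        for p in paths.values():
            assert (tmp_path / p).exists() or p  # files written even when empty

    def test_tf_edge_without_motif_rejected(self):
        with pytest.raises(ValueError):
            assemble([EgrnEdge("TF->eRNA", "tf0", "e0", 0.9, 0.001, motif_hit=False)])

    def test_refine_keeps_erna_with_regulatory_snp(self):
        net = _tiny_network()
        regions = {
            "e0": GenomicInterval("chr1", 0, 6000),
            "e1": GenomicInterval("chr1", 100_000, 106_000),
        }
        refined = refine_by_starr(net, regions, [("chr1", 3000)])
        assert refined.ernas == {"e0"}
        assert len(refined.edges) == 5  # e1's edge pruned, g3 orphan removed
        assert "g3" not in refined.genes

    def test_refine_empty_regulatory_set_empties_network(self):
        net = _tiny_network()
        regions = {"e0": GenomicInterval("chr1", 0, 6000), "e1": GenomicInterval("chr1", 10, 20)}
        refined = refine_by_starr(net, regions, [])
        assert refined.edges == [] and not refined.ernas

    def test_refine_monotone(self):
        net = _tiny_network()
        regions = {"e0": GenomicInterval("chr1", 0, 6000), "e1": GenomicInterval("chr1", 10, 20)}
        refined = refine_by_starr(net, regions, [("chr1", 3000), ("chr1", 15)])
        assert len(refined.edges) <= len(net.edges)
        assert refined.ernas <= net.ernas


class TestValidator:
    def test_fabricated_edge_caught(self):
        cols = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        tf_expr = pd.DataFrame(rng.random((1, 20)), index=["tf0"], columns=cols)
        erna_expr = pd.DataFrame(rng.random((1, 20)), index=["e0"], columns=cols)
        gene_expr = pd.DataFrame(rng.random((1, 20)), index=["g0"], columns=cols)
        net = assemble([EgrnEdge("TF->eRNA", "tf0", "e0", 0.9, 0.001, motif_hit=True)])
        violations = validate_network(
            net, tf_expr, erna_expr, gene_expr,
            {"e0": GenomicInterval("chr1", 0, 6000)}, {"g0": ("chr1", 1000)},
            [GenomicInterval("chr1", 0, 10_000, ".", "t")],
            [], {"tf0": "m0"},
        )
        assert violations  # no motif hit and rho mismatch both flagged
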