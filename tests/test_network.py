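import numpy as np
import pandas as pd
import pytest

from cartx.enrichment import GeneSetCollection
from cartx.matrix import CartxError
from cartx.network import (
    RegulatoryNetwork,
    assemble_mirna_tf_gene,
    assemble_tf_gene_lncrna,
    export_network,
    find_crosstalk_nodes,
    select_consistent_dems,
)


def dem_table(entries):
    return pd.DataFrame(
        [{"patient": "x", "feature_id": m, "log2fc": 1.0 if d == "up" else -1.0,
          "direction": d, "pre": 1.0, "post": 2.0} for m, d in entries]
    )


class TestSelectConsistentDems:
    def test_shared_direction_selected(self):
        tables = {
            "A": dem_table([("mir-1", "up"), ("mir-2", "up")]),
            "B": dem_table([("mir-1", "up"), ("mir-2", "down")]),
            "C": dem_table([("mir-1", "up")]),
        }
        out = select_consistent_dems(tables, ["A", "B", "C"])
        assert out["mirna"].tolist() == ["mir-1"]
        assert out["direction"].tolist() == ["up"]

    def test_partial_presence_or_conflict_excluded(self):
        tables = {
            "A": dem_table([("mir-1", "up"), ("mir-2", "up"), ("mir-3", "up")]),
            "B": dem_table([("mir-1", "down"), ("mir-2", "up")]),
        }
        out = select_consistent_dems(tables, ["A", "B"])
        assert out["mirna"].tolist() == ["mir-2"]

    def test_preconditions(self):
        tables = {"A": dem_table([("mir-1", "up")])}
        with pytest.raises(CartxError, match="at least 2"):
            select_consistent_dems(tables, ["A"])
        with pytest.raises(CartxError, match="no DEM table"):
            select_consistent_dems(tables, ["A", "Z"])


class TestRegulatoryNetworkContainer:
    def test_typed_endpoint_constraints(self):
        net = RegulatoryNetwork()
        net.add_node("g1", "gene")
        net.add_node("mir-1", "miRNA")
        net.add_node("tf1", "TF")
        net.add_node("pw1", "pathway")
        net.add_edge("mir-1", "g1", "mirna_target")
        net.add_edge("tf1", "g1", "tf_target")
        net.add_edge("g1", "pw1", "gene_pathway")
        net.validate()
        with pytest.raises(CartxError, match="miRNA"):
            net.add_edge("g1", "tf1", "mirna_target")
        with pytest.raises(CartxError, match="TF"):
            net.add_edge("g1", "tf1", "tf_target")
        with pytest.raises(CartxError, match="pathway"):
            net.add_edge("tf1", "g1", "gene_pathway")
        with pytest.raises(CartxError, match="duplicate"):
            net.add_edge("mir-1", "g1", "mirna_target")
        with pytest.raises(CartxError, match="not a node"):
            net.add_edge("mir-1", "missing", "mirna_target")


class TestAssembleMirnaTfGene:
    def _toy_inputs(self, toy_matrix, toy_annotation):
        mirnas = pd.DataFrame({"mirna": ["mir-1", "mir-2"], "direction": ["up", "down"]})
        mirna_targets = pd.DataFrame(
            {"regulator": ["mir-1", "mir-1", "mir-2", "mir-2", "mir-2", "mir-1"],
             "target": ["t1", "t2", "t3", "t4", "tf1", "tf1"]}
        )
        tf_targets = pd.DataFrame({"regulator": ["tf1"], "target": ["t1"]})
        deg_union = {"t1", "t2", "t3", "t4", "tf1"}
        modules = pd.Series(
            {"t1": "blue", "t2": "blue", "t3": "brown", "t4": "brown", "tf1": "blue"}
        )
        ann = toy_annotation(["t1", "t2", "t3", "t4", "tf1"],
                             flags=["", "", "", "", "TF"])
        rng = np.random.default_rng(0)
        expr = toy_matrix(rng.normal(size=(5, 8)) ,
                          feature_ids=["t1", "t2", "t3", "t4", "tf1"], unit="log2")
        pathways = GeneSetCollection({"pw1": ("KEGG", ["t1", "t3", "zz"]),
                                      "pw_none": ("KEGG", ["zz"])})
        return mirnas, mirna_targets, tf_targets, deg_union, modules, pathways, expr, ann

    def test_hand_counted_nodes_and_edges(self, toy_matrix, toy_annotation):
        (mirnas, mirna_targets, tf_targets, deg_union, modules,
         pathways, expr, ann) = self._toy_inputs(toy_matrix, toy_annotation)
        net = assemble_mirna_tf_gene(
            mirnas, mirna_targets, tf_targets, deg_union, modules, pathways,
            expr, ann, coexpr_r_min=1.01,  # suppress chance co-expression edges
        )
        nodes = net.nodes()
        # 2 miRNAs + 5 targets (tf1 counted once) = 7 feature nodes + 1 pathway
        assert (nodes["kind"] != "pathway").sum() == 7
        edges = net.edges()
        assert (edges["kind"] == "mirna_target").sum() == 6
        assert (edges["kind"] == "tf_target").sum() == 1
        assert (edges["kind"] == "gene_pathway").sum() == 2
        assert "pw_none" not in set(nodes["node"])  # isolated pathway dropped
        assert net.node_attr("tf1", "kind") == "TF"

    def test_empty_deg_union_leaves_only_mirna_nodes(self, toy_matrix, toy_annotation):
        (mirnas, mirna_targets, tf_targets, _, modules,
         pathways, expr, ann) = self._toy_inputs(toy_matrix, toy_annotation)
        net = assemble_mirna_tf_gene(
            mirnas, mirna_targets, tf_targets, set(), modules, pathways, expr, ann
        )
        assert set(net.nodes()["kind"]) == {"miRNA"}
        assert net.n_edges == 0

    def test_absent_mirna_kept_isolated_with_warning(self, toy_matrix, toy_annotation):
        (mirnas, mirna_targets, tf_targets, deg_union, modules,
         pathways, expr, ann) = self._toy_inputs(toy_matrix, toy_annotation)
        mirnas = pd.concat(
            [mirnas, pd.DataFrame({"mirna": ["mir-9"], "direction": ["up"]})],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="mir-9"):
            net = assemble_mirna_tf_gene(
                mirnas, mirna_targets, tf_targets, deg_union, modules, pathways,
                expr, ann,
            )
        assert "mir-9" in set(net.nodes()["node"])

    def test_coexpression_edges_cross_modules_only(self, toy_matrix, toy_annotation):
        (mirnas, mirna_targets, tf_targets, deg_union, modules,
         pathways, _, ann) = self._toy_inputs(toy_matrix, toy_annotation)
        profile = np.arange(8.0)
        rows = np.vstack([profile, profile * 2, profile * 3, np.random.default_rng(1).normal(size=8),
                          -profile])
        expr = toy_matrix(rows, feature_ids=["t1", "t2", "t3", "t4", "tf1"], unit="log2")
        net = assemble_mirna_tf_gene(
            mirnas, mirna_targets, tf_targets, deg_union, modules, pathways,
            expr, ann, coexpr_r_min=0.9,
        )
        coex = net.edges().query("kind == 'coexpression'")
        pairs = set(zip(coex["source"], coex["target"]))
        # t1~t2~t3~tf1 all perfectly correlated, but t1,t2,tf1 share module blue:
        # only cross-module pairs survive
        assert ("t1", "t3") in pairs and ("t2", "t3") in pairs and ("t3", "tf1") in pairs
        assert ("t1", "t2") not in pairs

    def test_deterministic_edge_lists(self, toy_matrix, toy_annotation):
        args = self._toy_inputs(toy_matrix, toy_annotation)
        n1 = assemble_mirna_tf_gene(*args[:4], args[4], args[5], args[6], args[7])
        n2 = assemble_mirna_tf_gene(*args[:4], args[4], args[5], args[6], args[7])
        pd.testing.assert_frame_equal(n1.edges(), n2.edges())
        assert n1 == n2


class TestAssembleTfGeneLncrna:
    def _inputs(self, toy_annotation):
        modules = pd.Series(
            {"g1": "turquoise", "g2": "turquoise", "g3": "turquoise",
             "tfA": "turquoise", "l1": "turquoise", "l2": "turquoise",
             "g9": "blue"}
        )
        ann = toy_annotation(
            ["g1", "g2", "g3", "tfA", "l1", "l2", "g9"],
            biotypes=["coding"] * 4 + ["lncRNA", "lncRNA", "coding"],
            flags=["", "", "", "TF", "", "", ""],
        )
        top_pairs = pd.DataFrame(
            {"feature_a": ["g1", "g2", "g9"], "feature_b": ["l1", "l2", "l1"],
             "r": [0.99, 0.98, 0.97], "p": [1e-9, 1e-8, 1e-8]}
        )
        tf_targets = pd.DataFrame({"regulator": ["tfA", "tfA"], "target": ["g1", "g9"]})
        pathways = GeneSetCollection({"pwT": ("KEGG", ["g1", "g2"]),
                                      "pwX": ("KEGG", ["g3"])})
        enr = pd.DataFrame(
            {"set": ["pwT", "pwX"], "category": ["KEGG", "KEGG"],
             "p": [1e-5, 0.5], "fdr": [2e-5, 0.5]}
        )
        return modules, ann, top_pairs, tf_targets, pathways, enr

    def test_hand_counted_module_network(self, toy_annotation):
        modules, ann, top_pairs, tf_targets, pathways, enr = self._inputs(toy_annotation)
        net = assemble_tf_gene_lncrna(
            "turquoise", modules, top_pairs, tf_targets, pathways, enr, ann
        )
        nodes = net.nodes()
        assert (nodes["kind"] != "pathway").sum() == 6
        assert (nodes["kind"] == "lncRNA").sum() == 2
        edges = net.edges()
        # within-module pairs only: (g1,l1), (g2,l2); tf edge tfA->g1 only
        assert (edges["kind"] == "coexpression").sum() == 2
        assert (edges["kind"] == "tf_target").sum() == 1
        # only the significantly enriched pathway is attached
        assert set(edges.query("kind == 'gene_pathway'")["target"]) == {"pwT"}

    def test_unknown_module_rejected(self, toy_annotation):
        modules, ann, top_pairs, tf_targets, pathways, enr = self._inputs(toy_annotation)
        with pytest.raises(CartxError, match="unknown or empty"):
            assemble_tf_gene_lncrna("salmon", modules, top_pairs, tf_targets,
                                    pathways, enr, ann)

    def test_module_without_enrichment_has_no_pathways(self, toy_annotation):
        modules, ann, top_pairs, tf_targets, pathways, _ = self._inputs(toy_annotation)
        net = assemble_tf_gene_lncrna(
            "turquoise", modules, top_pairs, tf_targets, pathways,
            pd.DataFrame(columns=["set", "fdr"]), ann,
        )
        assert (net.nodes()["kind"] == "pathway").sum() == 0


class TestCrosstalk:
    def _net(self, degrees):
        net = RegulatoryNetwork()
        for i in range(4):
            net.add_node(f"pw{i}", "pathway")
        for gene, d in degrees.items():
            net.add_node(gene, "gene")
            for i in range(d):
                net.add_edge(gene, f"pw{i}", "gene_pathway")
        return net

    def test_degree_ordering_and_threshold(self):
        net = self._net({"gA": 3, "gB": 2, "gC": 2, "gD": 1})
        assert find_crosstalk_nodes(net, 2) == ["gA", "gB", "gC"]
        net2 = self._net({"gA": 1, "gB": 1})
        assert find_crosstalk_nodes(net2, 2) == []
        with pytest.raises(CartxError):
            find_crosstalk_nodes(net, 1)


class TestExport:
    def _toy_net(self):
        net = RegulatoryNetwork()
        net.add_node("mir-1", "miRNA", direction="up")
        net.add_node("g1", "gene", direction="down", module="blue")
        net.add_node("pw", "pathway")
        net.add_edge("mir-1", "g1", "mirna_target", weight=-0.8)
        net.add_edge("g1", "pw", "gene_pathway")
        return net

    def test_graphml_round_trip_is_byte_stable(self, tmp_path):
        net = self._toy_net()
        p1 = tmp_path / "net.graphml"
        net.to_graphml(p1)
        back = RegulatoryNetwork.from_graphml(p1)
        p2 = tmp_path / "net2.graphml"
        back.to_graphml(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back == net

    def test_tsv_round_trip_and_counts(self, tmp_path):
        net = self._toy_net()
        paths = export_network(net, tmp_path / "net", fmt="tsv")
        back = RegulatoryNetwork.from_tsvs(*paths)
        assert back == net
        nodes = pd.read_csv(paths[0], sep="\t")
        edges = pd.read_csv(paths[1], sep="\t")
        assert len(nodes) == net.n_nodes
        assert len(edges) == net.n_edges

    def test_empty_network_exports_valid_graphml(self, tmp_path):
        net = RegulatoryNetwork()
        paths = export_network(net, tmp_path / "empty", fmt="graphml")
        back = RegulatoryNetwork.from_graphml(paths[0])
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(CartxError, match="format"):
            export_network(self._toy_net(), tmp_path / "x", fmt="gexf")
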