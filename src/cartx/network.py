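"""Heterogeneous miRNA-TF-gene(-lncRNA-pathway) regulatory networks.

Two assembly modes mirror the two network views the analysis produces:

* ``assemble_mirna_tf_gene`` — consistent differential miRNAs plus their
  targets restricted to the DEG union, TF->target edges among included
  genes, co-expression edges between included genes of *different* modules,
  and gene->pathway membership edges.
* ``assemble_tf_gene_lncrna`` — a single co-expression module's members,
  with within-module top correlated pairs as co-expression edges,
  TF->target edges among members, and edges to the module's significantly
  enriched pathways.

Node kinds are {miRNA, TF, gene, lncRNA, pathway}; edge kinds are
{mirna_target, tf_target, coexpression, gene_pathway}. Networks are
validated containers (typed endpoints, no duplicate edges) and export to
GraphML or paired node/edge TSVs with lossless round-tripping.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import _rowwise_standardize
from .matrix import CartxError, ExpressionMatrix, FeatureAnnotation

NODE_KINDS = ("miRNA", "TF", "gene", "lncRNA", "pathway")
EDGE_KINDS = ("mirna_target", "tf_target", "coexpression", "gene_pathway")
DIRECTIONS = ("up", "down", "mixed", "NA")


class RegulatoryNetwork:
    """Typed multigraph of regulatory relations.

    Nodes carry ``kind``, ``direction`` (up/down/mixed/NA) and ``module``;
    edges carry ``kind`` and an optional correlation ``weight``. At most
    one edge per (source, target, kind) triple.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction ---------------------------------------------------
    def add_node(
        self, node_id: str, kind: str, direction: str = "NA", module: str = "grey"
    ) -> None:
        if kind not in NODE_KINDS:
            raise CartxError(f"unknown node kind {kind!r}")
        if direction not in DIRECTIONS:
            raise CartxError(f"unknown direction {direction!r}")
        if node_id in self._g:
            existing = self._g.nodes[node_id]["kind"]
            if existing != kind:
                raise CartxError(
                    f"node {node_id!r} already present with kind {existing!r}"
                )
            return
        self._g.add_node(node_id, kind=kind, direction=direction, module=module)

    def add_edge(
        self, source: str, target: str, kind: str, weight: float | None = None
    ) -> None:
        if kind not in EDGE_KINDS:
            raise CartxError(f"unknown edge kind {kind!r}")
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise CartxError(f"edge endpoint {endpoint!r} is not a node")
        if self._g.has_edge(source, target, key=kind):
            raise CartxError(f"duplicate edge ({source!r}, {target!r}, {kind!r})")
        src_kind = self._g.nodes[source]["kind"]
        tgt_kind = self._g.nodes[target]["kind"]
        if kind == "mirna_target" and src_kind != "miRNA":
            raise CartxError("mirna_target edges must start at a miRNA node")
        if kind == "tf_target" and src_kind != "TF":
            raise CartxError("tf_target edges must start at a TF node")
        if kind == "gene_pathway" and tgt_kind != "pathway":
            raise CartxError("gene_pathway edges must end at a pathway node")
        attrs = {"kind": kind}
        if weight is not None:
            attrs["weight"] = float(weight)
        self._g.add_edge(source, target, key=kind, **attrs)

    # -- inspection -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> pd.DataFrame:
        rows = [
            {"node": n, "kind": d["kind"], "direction": d["direction"], "module": d["module"]}
            for n, d in self._g.nodes(data=True)
        ]
        df = pd.DataFrame(rows, columns=["node", "kind", "direction", "module"])
        return df.sort_values("node").reset_index(drop=True)

    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "kind": d["kind"],
                "weight": d.get("weight", float("nan")),
            }
            for u, v, d in self._g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "kind", "weight"])
        return df.sort_values(["source", "target", "kind"]).reset_index(drop=True)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self._g.nodes(data=True) if d["kind"] == kind)

    def node_attr(self, node_id: str, attr: str):
        return self._g.nodes[node_id][attr]

    def validate(self) -> None:
        """Re-check every type constraint; raises on violation."""
        seen = set()
        for u, v, key, d in self._g.edges(keys=True, data=True):
            if (u, v, d["kind"]) in seen:
                raise CartxError(f"duplicate edge ({u}, {v}, {d['kind']})")
            seen.add((u, v, d["kind"]))
            if d["kind"] not in EDGE_KINDS:
                raise CartxError(f"unknown edge kind {d['kind']!r}")
            if d["kind"] == "mirna_target" and self._g.nodes[u]["kind"] != "miRNA":
                raise CartxError(f"mirna_target edge from non-miRNA node {u!r}")
            if d["kind"] == "tf_target" and self._g.nodes[u]["kind"] != "TF":
                raise CartxError(f"tf_target edge from non-TF node {u!r}")
            if d["kind"] == "gene_pathway" and self._g.nodes[v]["kind"] != "pathway":
                raise CartxError(f"gene_pathway edge to non-pathway node {v!r}")
        for n, d in self._g.nodes(data=True):
            if d["kind"] not in NODE_KINDS:
                raise CartxError(f"unknown node kind {d['kind']!r} on {n!r}")
            if d["direction"] not in DIRECTIONS:
                raise CartxError(f"unknown direction {d['direction']!r} on {n!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.nodes().equals(other.nodes()) and self.edges().equals(other.edges())

    # -- serialisation --------------------------------------------------
    def _sorted_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for _, row in self.nodes().iterrows():
            g.add_node(
                row["node"], kind=row["kind"], direction=row["direction"], module=row["module"]
            )
        for _, row in self.edges().iterrows():
            attrs = {"kind": row["kind"]}
            if not pd.isna(row["weight"]):
                attrs["weight"] = float(row["weight"])
            g.add_edge(row["source"], row["target"], key=row["kind"], **attrs)
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self._sorted_graph(), str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "RegulatoryNetwork":
        g = nx.read_graphml(str(path), force_multigraph=True)
        net = cls()
        for n, d in g.nodes(data=True):
            net.add_node(n, d["kind"], d.get("direction", "NA"), d.get("module", "grey"))
        for u, v, d in g.edges(data=True):
            net.add_edge(u, v, d["kind"], d.get("weight"))
        return net

    def to_tsvs(self, node_path: str | Path, edge_path: str | Path) -> None:
        self.nodes().to_csv(node_path, sep="\t", index=False)
        self.edges().to_csv(edge_path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsvs(cls, node_path: str | Path, edge_path: str | Path) -> "RegulatoryNetwork":
        net = cls()
        nodes = pd.read_csv(node_path, sep="\t", keep_default_na=False)
        for _, row in nodes.iterrows():
            net.add_node(row["node"], row["kind"], row["direction"], row["module"])
        edges = pd.read_csv(edge_path, sep="\t")
        for _, row in edges.iterrows():
            w = None if pd.isna(row["weight"]) else float(row["weight"])
            net.add_edge(row["source"], row["target"], row["kind"], w)
        return net


def export_network(
    net: RegulatoryNetwork, out_prefix: str | Path, fmt: str = "graphml"
) -> list[Path]:
    """Write a network as GraphML or as paired node/edge TSVs."""
    out_prefix = Path(out_prefix)
    if fmt == "graphml":
        path = out_prefix.with_suffix(".graphml")
        net.to_graphml(path)
        return [path]
    if fmt == "tsv":
        node_path = out_prefix.parent / (out_prefix.name + "_nodes.tsv")
        edge_path = out_prefix.parent / (out_prefix.name + "_edges.tsv")
        net.to_tsvs(node_path, edge_path)
        return [node_path, edge_path]
    raise CartxError(f"unknown export format {fmt!r}")


def select_consistent_dems(
    dem_tables: Mapping[str, pd.DataFrame], remissive_patients: Sequence[str]
) -> pd.DataFrame:
    """miRNAs called DE with an identical direction in every remissive patient.

    Returns a table with columns ``mirna, direction`` sorted by miRNA id.
    """
    patients = list(remissive_patients)
    if len(patients) < 2:
        raise CartxError("need at least 2 remissive patients")
    unknown = [p for p in patients if p not in dem_tables]
    if unknown:
        raise CartxError(f"no DEM table for patient(s): {unknown}")

    direction_maps = [
        dict(zip(dem_tables[p]["feature_id"], dem_tables[p]["direction"])) for p in patients
    ]
    common = set(direction_maps[0])
    for d in direction_maps[1:]:
        common &= set(d)
    rows = [
        {"mirna": m, "direction": direction_maps[0][m]}
        for m in sorted(common)
        if len({d[m] for d in direction_maps}) == 1
    ]
    return pd.DataFrame(rows, columns=["mirna", "direction"])


def _feature_kind(feature: str, annotation: FeatureAnnotation) -> str:
    if feature in annotation.table.index:
        if annotation.has_flag("TF").get(feature, False):
            return "TF"
        if annotation.table.loc[feature, "biotype"] == "lncRNA":
            return "lncRNA"
    return "gene"


def _coexpression_edges(
    features: list[str], expr: ExpressionMatrix, r_min: float
) -> list[tuple[str, str, float]]:
    present = [f for f in features if f in expr.data.index]
    if len(present) < 2:
        return []
    X = expr.data.loc[present].values
    Z = _rowwise_standardize(X)
    R = np.clip(Z @ Z.T / (expr.n_samples - 1), -1.0, 1.0)
    out = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            r = float(R[i, j])
            if abs(r) >= r_min:
                out.append((present[i], present[j], r))
    return sorted(out)


def assemble_mirna_tf_gene(
    important_mirnas: pd.DataFrame,
    mirna_targets: pd.DataFrame,
    tf_targets: pd.DataFrame,
    deg_union: set[str] | Iterable[str],
    modules: pd.Series,
    pathways,
    expr: ExpressionMatrix,
    annotation: FeatureAnnotation,
    coexpr_r_min: float = 0.9,
    directions: Mapping[str, str] | None = None,
    mirna_expr: ExpressionMatrix | None = None,
) -> RegulatoryNetwork:
    """Assemble the miRNA-TF-gene network around consistent DEMs.

    Nodes are the important miRNAs plus their targets restricted to the DEG
    union; TF->target edges run among included genes, co-expression edges
    (|r| >= ``coexpr_r_min``) connect included genes of *different*
    modules, and gene->pathway edges attach the gene-set collection
    (isolated pathway nodes are dropped). When ``mirna_expr`` is given,
    each miRNA->target edge carries the miRNA-target expression correlation
    as its weight (anti-correlation is informational, never a filter).
    """
    deg_union = set(deg_union)
    directions = dict(directions or {})
    net = RegulatoryNetwork()

    mirna_list = list(important_mirnas["mirna"])
    mirna_dir = dict(zip(important_mirnas["mirna"], important_mirnas["direction"]))
    targeted = mirna_targets.groupby("regulator")["target"].apply(list).to_dict()

    for m in sorted(mirna_list):
        net.add_node(m, "miRNA", direction=mirna_dir.get(m, "NA"))
        if m not in targeted:
            warnings.warn(f"miRNA {m!r} absent from the target table; kept isolated")

    included_genes: set[str] = set()
    for m in sorted(mirna_list):
        for t in sorted(targeted.get(m, [])):
            if t not in deg_union:
                continue
            kind = _feature_kind(t, annotation)
            net.add_node(
                t, kind, direction=directions.get(t, "NA"),
                module=str(modules.get(t, "grey")),
            )
            included_genes.add(t)
            weight = None
            if mirna_expr is not None and m in mirna_expr.data.index and t in expr.data.index:
                from .coexpression import pearson_with_p

                x = mirna_expr.data.loc[m].values
                y = expr.data.loc[t].values
                if np.ptp(x) > 0 and np.ptp(y) > 0:
                    weight = pearson_with_p(x, y).r
            net.add_edge(m, t, "mirna_target", weight=weight)

    for _, row in tf_targets.sort_values(["regulator", "target"]).iterrows():
        tf, t = row["regulator"], row["target"]
        if tf in included_genes and t in included_genes and tf != t:
            if net.node_attr(tf, "kind") == "TF":
                net.add_edge(tf, t, "tf_target")

    module_of = {g: str(modules.get(g, "grey")) for g in included_genes}
    for a, b, r in _coexpression_edges(sorted(included_genes), expr, coexpr_r_min):
        if module_of[a] != module_of[b]:
            net.add_edge(a, b, "coexpression", weight=r)

    for pw in sorted(pathways.names):
        members = set(pathways.members(pw)) & included_genes
        if not members:
            continue
        net.add_node(pw, "pathway")
        for g in sorted(members):
            net.add_edge(g, pw, "gene_pathway")

    net.validate()
    return net


def assemble_tf_gene_lncrna(
    module_label: str,
    modules: pd.Series,
    top_pairs: pd.DataFrame,
    tf_targets: pd.DataFrame,
    pathways,
    enrichment_table: pd.DataFrame,
    annotation: FeatureAnnotation,
    significant_fdr: float = 0.05,
    directions: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Within-module TF-gene-lncRNA co-expression network.

    Nodes are the members of ``module_label``; co-expression edges come
    from ``top_pairs`` restricted to the module, TF->target edges run among
    members, and gene->pathway edges attach only the module's significantly
    enriched pathways (BH FDR < ``significant_fdr``).
    """
    directions = dict(directions or {})
    members = sorted(modules.index[modules == module_label])
    if not members:
        raise CartxError(f"unknown or empty module {module_label!r}")
    member_set = set(members)

    net = RegulatoryNetwork()
    for g in members:
        net.add_node(
            g, _feature_kind(g, annotation),
            direction=directions.get(g, "NA"), module=module_label,
        )

    if len(top_pairs):
        sub = top_pairs[
            top_pairs["feature_a"].isin(member_set) & top_pairs["feature_b"].isin(member_set)
        ]
        for _, row in sub.sort_values(["feature_a", "feature_b"]).iterrows():
            net.add_edge(row["feature_a"], row["feature_b"], "coexpression", weight=row["r"])

    for _, row in tf_targets.sort_values(["regulator", "target"]).iterrows():
        tf, t = row["regulator"], row["target"]
        if tf in member_set and t in member_set and tf != t:
            if net.node_attr(tf, "kind") == "TF":
                net.add_edge(tf, t, "tf_target")

    if len(enrichment_table):
        significant = enrichment_table[enrichment_table["fdr"] < significant_fdr]
        for pw in sorted(significant["set"]):
            if pw not in pathways:
                continue
            pw_members = set(pathways.members(pw)) & member_set
            if not pw_members:
                continue
            net.add_node(pw, "pathway")
            for g in sorted(pw_members):
                net.add_edge(g, pw, "gene_pathway")

    net.validate()
    return net


def find_crosstalk_nodes(net: RegulatoryNetwork, min_pathways: int = 2) -> list[str]:
    """Gene/TF nodes linked to at least ``min_pathways`` distinct pathways.

    Sorted by pathway-degree descending, then node id ascending.
    """
    if min_pathways < 2:
        raise CartxError("min_pathways must be >= 2")
    edges = net.edges()
    pw_edges = edges[edges["kind"] == "gene_pathway"]
    nodes_df = net.nodes().set_index("node")
    degree = pw_edges.groupby("source")["target"].nunique()
    hits = [
        (int(d), n)
        for n, d in degree.items()
        if d >= min_pathways and nodes_df.loc[n, "kind"] in ("gene", "TF")
    ]
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [n for _, n in hits]
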