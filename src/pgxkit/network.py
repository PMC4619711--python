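"""Tri-partite gene-drug-category interaction network.

Nodes are typed ``gene``, ``drug``, or ``category``; edges run gene→drug
(a variant of the gene affects the drug's response) and drug→category (the
drug's curated functional classification).  A drug's gene in-degree is the
number of distinct genes carrying annotations for it, so a drug affected by
many variants shows many incoming arrows.  Node colors follow the
green/blue/yellow convention for gene/drug/category and are emitted as
attributes only — rendering is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx

from .annotation import MatchedAnnotation
from .knowledgebase import KnowledgeBase

__all__ = ["build_network", "export_network", "import_graphml", "node_color"]

NODE_COLORS = {"gene": "green", "drug": "blue", "category": "yellow"}


def node_color(node_type: str) -> str:
    return NODE_COLORS[node_type]


def build_network(
    kb: KnowledgeBase,
    matches: Iterable[MatchedAnnotation] | None = None,
    effect_attrs: bool = True,
) -> nx.DiGraph:
    """Build the typed gene→drug→category graph from a knowledge base.

    With ``matches`` given, the network is restricted to matched rows (a
    personal network); otherwise the whole KB is used.  Isolated nodes are
    omitted: genes and drugs appear only when a witnessing annotation exists,
    categories only via a drug edge.  Each gene→drug edge optionally carries
    the set of effect directions of its witnessing rows.
    """
    if matches is None:
        rows = kb.annotations
    else:
        rows = [m.annotation for m in matches]

    g = nx.DiGraph()
    for ann in rows:
        gene, drug = ann.gene_symbol, ann.drug_name
        if gene == drug:
            continue  # self-loops are excluded by construction
        g.add_node(gene, node_type="gene", color=NODE_COLORS["gene"])
        g.add_node(drug, node_type="drug", color=NODE_COLORS["drug"])
        if g.has_edge(gene, drug):
            if effect_attrs:
                dirs = set(g.edges[gene, drug].get("directions", "").split(";")) - {""}
                dirs.add(ann.direction)
                g.edges[gene, drug]["directions"] = ";".join(sorted(dirs))
        else:
            attrs = {"edge_type": "gene-drug"}
            if effect_attrs:
                attrs["directions"] = ann.direction
            g.add_edge(gene, drug, **attrs)

        record = kb.drugs.get(drug)
        if record is not None:
            for cat in record.categories:
                if cat == drug:
                    continue
                g.add_node(cat, node_type="category", color=NODE_COLORS["category"])
                g.add_edge(drug, cat, edge_type="drug-category")
    return g


def export_network(
    net: nx.DiGraph,
    fmt: str,
    out: str | Path,
    undirected: bool = False,
) -> None:
    """Write the network as GraphML, node-link JSON, or Graphviz DOT.

    GraphML carries the ``node_type`` and ``color`` attributes, so a
    re-import reconstructs the typed graph exactly.
    """
    out = Path(out)
    graph = net.to_undirected(as_view=False) if undirected else net
    if fmt == "graphml":
        nx.write_graphml(graph, out)
    elif fmt == "json":
        data = nx.node_link_data(graph, edges="edges")
        out.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    elif fmt == "dot":
        out.write_text(_to_dot(graph), encoding="utf-8")
    else:
        raise ValueError(f"unknown network format {fmt!r}; use graphml, json, or dot")


def _to_dot(g: nx.Graph) -> str:
    # hand-rolled DOT writer; pydot/pygraphviz are deliberately not required
    directed = g.is_directed()
    lines = ["digraph pgx {" if directed else "graph pgx {"]
    arrow = " -> " if directed else " -- "
    for node, data in sorted(g.nodes(data=True)):
        color = data.get("color", "gray")
        lines.append(f'  "{node}" [fillcolor={color}, style=filled];')
    for u, v in sorted(g.edges()):
        lines.append(f'  "{u}"{arrow}"{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def import_graphml(path: str | Path) -> nx.DiGraph:
    """Re-import a GraphML export as a typed directed graph."""
    g = nx.read_graphml(path)
    return nx.DiGraph(g)
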