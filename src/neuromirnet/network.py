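"""Bipartite miRNA-mRNA network construction and summaries.

Nodes are miRNAs and genes; every edge is a retained, tiered target
prediction of a candidate miRNA against a down-regulated gene. Gene node
``size`` encodes target confidence as max |CWCS| over incident edges, and
genes with at least one high-confidence edge carry ``label_flag`` so a plot
can print their names. Layout is deliberately not part of the contract.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .types import NetworkEdge

__all__ = ["build_network", "network_summary"]


def build_network(edges: Iterable[NetworkEdge]) -> nx.Graph:
    """Build the bipartite graph with display attributes.

    Node attributes: ``kind`` in {mirna, gene}; ``bipartite`` 0/1 (networkx
    convention); gene nodes get ``size`` = max |CWCS| over incident edges
    and ``label_flag`` = True iff any incident edge is high confidence.
    Edge attributes: ``cwcs``, ``tier``. Duplicate (miRNA, gene) pairs are
    an error.
    """
    graph = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for edge in edges:
        key = (edge.mirna_id, edge.gene_id)
        if key in seen:
            raise ValueError(f"duplicate edge {edge.mirna_id} -> {edge.gene_id}")
        seen.add(key)
        mnode, gnode = f"mirna::{edge.mirna_id}", f"gene::{edge.gene_id}"
        graph.add_node(mnode, kind="mirna", name=edge.mirna_id, bipartite=0)
        if gnode not in graph:
            graph.add_node(
                gnode, kind="gene", name=edge.gene_id, bipartite=1,
                size=0.0, label_flag=False,
            )
        graph.add_edge(mnode, gnode, cwcs=edge.cwcs, tier=edge.tier)
        graph.nodes[gnode]["size"] = max(graph.nodes[gnode]["size"], abs(edge.cwcs))
        if edge.tier == "high":
            graph.nodes[gnode]["label_flag"] = True
    return graph


def network_summary(graph: nx.Graph) -> dict:
    """Deterministic count summary of a built network."""
    mirnas = [n for n, d in graph.nodes(data=True) if d["kind"] == "mirna"]
    genes = [n for n, d in graph.nodes(data=True) if d["kind"] == "gene"]
    tiers = pd.Series([d["tier"] for _, _, d in graph.edges(data=True)])
    per_tier = tiers.value_counts().to_dict() if len(tiers) else {}
    return {
        "n_edges": graph.number_of_edges(),
        "n_mirna": len(mirnas),
        "n_gene": len(genes),
        "edges_per_tier": {t: int(per_tier.get(t, 0)) for t in ("high", "moderate")},
        "mirna_degrees": {graph.nodes[n]["name"]: graph.degree(n) for n in sorted(mirnas)},
        "gene_degrees": {graph.nodes[n]["name"]: graph.degree(n) for n in sorted(genes)},
    }
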