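"""Shared-guQTL gene networks: Jaccard edges, maximal cliques, components.

Genes with at least one significant guQTL become nodes; two genes are
connected when their significant variant sets intersect, with the edge
weighted by the shared-variant count and the Jaccard index of the two sets.
Maximal cliques (complete subgraphs not extendable by any node) mark groups
of genes all pairwise sharing guQTLs — candidates for coordinated
regulation through extended haplotypes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def jaccard(set_a: set[str], set_b: set[str]) -> float:
    """|A ∩ B| / |A ∪ B| for two non-empty variant-id sets."""
    if not set_a or not set_b:
        raise ValueError("Jaccard undefined for empty sets")
    return len(set_a & set_b) / len(set_a | set_b)


def build_graph(significant_sets: dict[str, set[str]]) -> nx.Graph:
    """Gene graph with an edge per pair sharing >= 1 guQTL variant.

    Genes with empty sets become isolated nodes. Edge attributes:
    ``shared_count`` and ``jaccard``.
    """
    g = nx.Graph()
    genes = sorted(significant_sets)
    g.add_nodes_from(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            sa, sb = significant_sets[a], significant_sets[b]
            if not sa or not sb:
                continue
            shared = sa & sb
            if shared:
                g.add_edge(a, b, shared_count=len(shared), jaccard=jaccard(sa, sb))
    return g


def degree_table(g: nx.Graph) -> pd.DataFrame:
    """Per gene, the number of genes it shares at least one guQTL with."""
    return pd.DataFrame(
        {"gene": list(g.nodes), "n_sharing_genes": [g.degree(n) for n in g.nodes]}
    ).sort_values("gene", ignore_index=True)


def maximal_cliques(g: nx.Graph, min_size: int = 2) -> list[set[str]]:
    """All maximal cliques of at least ``min_size`` genes (Bron-Kerbosch
    with pivoting; exact and duplicate-free)."""
    cliques = [set(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    return sorted(cliques, key=lambda c: (-len(c), sorted(c)))


def connected_components(g: nx.Graph, min_size: int = 2) -> list[set[str]]:
    """Connected components of >= ``min_size`` genes (the 'super clique'
    style groupings in which subcliques are embedded)."""
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= min_size]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def edges_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_a": a, "gene_b": b, "shared_count": d["shared_count"], "jaccard": d["jaccard"]}
        for a, b, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "shared_count", "jaccard"])
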