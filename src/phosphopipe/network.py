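"""Interaction subnetworks on reversal-screen hits.

Confidence-filtered edges (STRING-style combined score, threshold ≥ 0.7
inclusive) are induced on the reversed-protein set; connected components,
degrees and hub proteins summarize the result.  Isolated query proteins are
retained and flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .tables import EdgeList

__all__ = ["Subnetwork", "filter_edges", "induced_subgraph"]


def filter_edges(edges: EdgeList, min_confidence: float = 0.7) -> EdgeList:
    """Edges with confidence ≥ threshold (inclusive)."""
    return edges.filter(min_confidence)


@dataclass
class Subnetwork:
    graph: nx.Graph
    node_classes: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def isolates(self) -> list[str]:
        return sorted(nx.isolates(self.graph))

    @property
    def components(self) -> list[list[str]]:
        """Connected components, largest first, ties by first node name."""
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), c[0]))

    def degree_table(self) -> pd.DataFrame:
        rows = [{"protein": n, "degree": d,
                 "reversal_class": self.node_classes.get(n, "")}
                for n, d in self.graph.degree]
        df = pd.DataFrame(rows, columns=["protein", "degree", "reversal_class"])
        return df.sort_values(["degree", "protein"], ascending=[False, True],
                              ignore_index=True)

    def hubs(self, k: int = 10) -> pd.DataFrame:
        return self.degree_table().head(k)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"protein_a": a, "protein_b": b, "confidence": d["confidence"]}
                for a, b, d in self.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])
        return df.sort_values(["protein_a", "protein_b"], ignore_index=True)

    def summary(self) -> dict:
        comps = self.components
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_components": len(comps),
            "largest_component": len(comps[0]) if comps else 0,
            "n_isolates": len(self.isolates),
        }


def induced_subgraph(nodes, edges: EdgeList,
                     node_classes: dict[str, str] | None = None) -> Subnetwork:
    """Subgraph on exactly the given proteins, keeping isolates.

    ``edges`` should already be confidence-filtered; ``node_classes`` maps
    protein → reversal class for node attributes.
    """
    node_set = {str(n).upper() for n in nodes}
    g = nx.Graph()
    g.add_nodes_from(sorted(node_set))
    df = edges.edges
    keep = df["protein_a"].isin(node_set) & df["protein_b"].isin(node_set)
    for a, b, c in df[keep].itertuples(index=False):
        g.add_edge(a, b, confidence=float(c))
    classes = {str(k).upper(): v for k, v in (node_classes or {}).items()}
    nx.set_node_attributes(g, {n: classes.get(n, "") for n in g.nodes},
                           "reversal_class")
    return Subnetwork(g, classes)
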