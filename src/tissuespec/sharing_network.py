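"""Tissue-sharing network of group-enriched genes.

Group-enriched genes define combinations of tissues that share elevated
expression. The network has one node per distinct tissue combination
(sized by the square root of its gene count, the convention used for
bubble plots of such networks) connected to the member tissues.
Tissue-enriched genes can be included as the singleton combination of the
target tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class SharingNetwork:
    """Node/edge tables of the tissue-sharing network.

    ``nodes`` columns: id, type ("combo" or "tissue"), gene_count, size
    (sqrt of gene count for combos, 0 for tissue nodes).
    ``edges`` columns: combo_id, tissue.
    ``tissue_tally`` maps each non-target tissue to the number of
    group-enriched genes whose group contains it.
    """

    target: str
    nodes: pd.DataFrame
    edges: pd.DataFrame
    tissue_tally: dict[str, int]

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        for row in self.nodes.itertuples():
            graph.add_node(row.id, type=row.type, gene_count=row.gene_count,
                           size=row.size)
        for row in self.edges.itertuples():
            graph.add_edge(row.combo_id, row.tissue)
        return graph


def build_sharing_network(
    classes: pd.DataFrame,
    target: str,
    include_enriched: bool = True,
) -> SharingNetwork:
    """Build the sharing network from a classification table.

    Groups are keyed by their exact tissue set; combos are ordered by size
    then lexicographically so output is deterministic. With
    ``include_enriched`` the tissue-enriched genes appear as the singleton
    combination ``{target}``.
    """
    combos: dict[tuple[str, ...], int] = {}
    grouped = classes[classes["category"] == "group_enriched"]
    for gene, group in grouped["group"].items():
        if not group:
            raise ValueError(
                f"group_enriched gene {gene!r} has an empty group")
        key = tuple(sorted(group))
        combos[key] = combos.get(key, 0) + 1
    if include_enriched:
        n_enriched = int((classes["category"] == "tissue_enriched").sum())
        if n_enriched:
            key = (target,)
            combos[key] = combos.get(key, 0) + n_enriched

    ordered = sorted(combos, key=lambda c: (len(c), c))
    node_rows, edge_rows = [], []
    tissues_seen: list[str] = []
    for combo in ordered:
        combo_id = ";".join(combo)
        count = combos[combo]
        node_rows.append({"id": combo_id, "type": "combo",
                          "gene_count": count, "size": count ** 0.5})
        for tissue in combo:
            edge_rows.append({"combo_id": combo_id, "tissue": tissue})
            if tissue not in tissues_seen:
                tissues_seen.append(tissue)
    for tissue in sorted(tissues_seen):
        node_rows.append({"id": tissue, "type": "tissue",
                          "gene_count": 0, "size": 0.0})

    tally: dict[str, int] = {}
    for gene, group in grouped["group"].items():
        for tissue in group:
            if tissue != target:
                tally[tissue] = tally.get(tissue, 0) + 1

    nodes = pd.DataFrame(node_rows,
                         columns=["id", "type", "gene_count", "size"])
    edges = pd.DataFrame(edge_rows, columns=["combo_id", "tissue"])
    return SharingNetwork(target=target, nodes=nodes, edges=edges,
                          tissue_tally=tally)
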