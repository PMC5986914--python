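"""Cooperation-network export.

Significant motif pairs form an undirected graph: nodes are motifs,
edges are predicted cooperations carrying the score trail (z, corrected
score, specific/common label).  Nodes that appear only in common pairs
are flagged so downstream plots can grey them out.
"""

from __future__ import annotations

import networkx as nx

from .core import LABEL_COMMON, LABEL_SPECIFIC, PairCollection

FORMATS = ("graphml", "edge-tsv")


def build_network(collection: PairCollection, provenance: str = "") -> nx.Graph:
    """Graph of all significant (classified) pairs.

    Nodes are the motifs appearing in at least one significant pair;
    each edge carries ``z``, ``pmi_pc_apc``, ``pmi_specific``,
    ``avg_background`` and ``label``.  A node involved in common pairs
    only gets ``common_only = True``.
    """
    g = nx.Graph(provenance=provenance)
    for r in collection.significant():
        label = r.label if r.label in (LABEL_SPECIFIC, LABEL_COMMON) else ""
        g.add_edge(
            r.motif_a,
            r.motif_b,
            z=float(r.z),
            pmi_pc_apc=float(r.pmi_pc_apc),
            pmi_specific=float(r.pmi_specific),
            avg_background=float(r.avg_background),
            label=label,
        )
    for node in g.nodes:
        labels = {g.edges[e]["label"] for e in g.edges(node)}
        g.nodes[node]["common_only"] = labels == {LABEL_COMMON}
    return g


def export_network(
    collection: PairCollection, path, fmt: str = "graphml", provenance: str = ""
) -> nx.Graph:
    """Write the cooperation network to ``path`` as GraphML or an edge TSV."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; choose from {FORMATS}")
    g = build_network(collection, provenance=provenance)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("motif_a\tmotif_b\tz\tpmi_pc_apc\tpmi_specific\tavg_background\tlabel\n")
            for u, v, attrs in sorted(g.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{attrs['z']:.10g}\t{attrs['pmi_pc_apc']:.10g}\t"
                    f"{attrs['pmi_specific']:.10g}\t{attrs['avg_background']:.10g}\t"
                    f"{attrs['label']}\n"
                )
    return g
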