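"""One-edge-difference graph over topological configurations.

Nodes are the admissible configurations; two nodes are adjacent when their
optional-edge masks differ in exactly one bit, i.e. the configurations are
separated by the gain or loss of a single reaction — a minimal evolutionary
event.  Adjacency requires both endpoints to be admissible; a single-bit
flip landing outside the admissible set is simply an absent edge.
Connectivity of a robust subset is read as evolutionary accessibility.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .scaffold import OPTIONAL_EDGES, TopologyConfiguration


def _hamming(a: TopologyConfiguration, b: TopologyConfiguration) -> int:
    return sum(x != y for x, y in zip(a.present_edges, b.present_edges))


def build_topology_graph(configs: Sequence[TopologyConfiguration]) -> nx.Graph:
    """Hamming-distance-1 adjacency over the configurations' edge masks."""
    masks = [c.present_edges for c in configs]
    if len(set(masks)) != len(masks):
        raise ValueError("duplicate configurations")
    g = nx.Graph()
    for c in configs:
        g.add_node(
            c.label,
            mask="".join(map(str, c.present_edges)),
            n_edges=c.n_edges,
        )
    for i, a in enumerate(configs):
        for b in configs[i + 1:]:
            if _hamming(a, b) == 1:
                g.add_edge(a.label, b.label)
    return g


def is_connected(
    graph: nx.Graph, node_subset: Iterable[str] | None = None
) -> tuple[bool, list[set[str]]]:
    """Connectivity and component decomposition of an induced subgraph."""
    nodes = set(graph.nodes) if node_subset is None else set(node_subset)
    unknown = nodes - set(graph.nodes)
    if unknown:
        raise KeyError(f"unknown nodes: {sorted(unknown)}")
    sub = graph.subgraph(nodes)
    components = [set(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), sorted(c)))
    return len(components) <= 1, components


def write_edge_list_tsv(graph: nx.Graph, path: str | Path) -> None:
    lines = ["source\ttarget"]
    for a, b in sorted(graph.edges):
        lines.append(f"{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
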