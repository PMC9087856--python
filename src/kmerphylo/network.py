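"""Thresholded genome-relatedness networks.

Each genome is a node; every pair carries the similarity S = 10 − d. A
threshold t in [0, 10] displays only edges with S >= t: at t = 0 the network
is a clique, and at t = 10 (with strictly positive distances) every node is
isolated. Views are nested as t grows, so the component count is
non-decreasing in t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from kmerphylo.d2s_distance import MAX_DISTANCE, DistanceMatrix
from kmerphylo.io_formats import ValidationError


@dataclass
class RelatednessNetwork:
    graph: nx.Graph
    region_kind: str | None = None
    k: int | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["S"]) for u, v, d in self.graph.edges(data=True)]

    def to_json_obj(self, t: float | None = None) -> dict:
        """D3-style nodes/links object; links carry the S value.

        By default all edges are exported so a rendering layer can
        re-threshold dynamically; pass ``t`` to keep only edges with S >= t.
        """
        nodes = []
        for nid, data in self.graph.nodes(data=True):
            nodes.append({
                "id": nid,
                "species": data.get("species", ""),
                "lifestyle": data.get("lifestyle", "unknown"),
                "group": data.get("group", data.get("species", "")),
            })
        links = [{"source": u, "target": v, "value": s}
                 for u, v, s in sorted(self.edges())
                 if t is None or s >= t]
        return {"nodes": sorted(nodes, key=lambda n: n["id"]), "links": links}


def build_network(matrix: DistanceMatrix,
                  metadata: Mapping[str, Mapping[str, str]] | None = None
                  ) -> RelatednessNetwork:
    """Complete weighted graph with S = 10 − d on every pair (no self-edges)."""
    values = matrix.values
    if (values < 0).any() or (values > MAX_DISTANCE).any():
        raise ValidationError("distances outside [0, 10] violate the S = 10 - d transform")
    g = nx.Graph()
    for label in matrix.labels:
        attrs = dict(metadata.get(label, {})) if metadata else {}
        g.add_node(label, **attrs)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(matrix.labels[i], matrix.labels[j],
                       S=MAX_DISTANCE - float(values[i, j]))
    return RelatednessNetwork(g, matrix.region_kind, matrix.k)


def threshold_view(network: RelatednessNetwork, t: float) -> nx.Graph:
    """Subgraph keeping all nodes and only the edges with S >= t."""
    if not (0.0 <= t <= MAX_DISTANCE):
        raise ValidationError(f"threshold t={t} outside [0, 10]")
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes(data=True))
    for u, v, data in network.graph.edges(data=True):
        if data["S"] >= t:
            g.add_edge(u, v, **data)
    return g


def connected_components(network: RelatednessNetwork, t: float = 0.0
                         ) -> list[set[str]]:
    """Maximal connected node groups of the thresholded view.

    Deterministic order: components sorted by their smallest member.
    """
    view = threshold_view(network, t)
    comps = [set(c) for c in nx.connected_components(view)]
    return sorted(comps, key=lambda c: min(c))


def component_breakpoints(network: RelatednessNetwork) -> list[tuple[float, int]]:
    """Thresholds where the component structure changes, swept from t = 0.

    Returns (t, n_components) pairs: t = 0 first, then every distinct edge
    similarity at which raising t past it alters the partition. Just above the
    largest S every node is isolated.
    """
    out = [(0.0, len(connected_components(network, 0.0)))]
    prev = {frozenset(c) for c in connected_components(network, 0.0)}
    for s in sorted({s for _, _, s in network.edges()}):
        t = min(MAX_DISTANCE, float(s))
        # structure just above this similarity: use nextafter to step past ties
        import math
        t_above = min(MAX_DISTANCE, math.nextafter(t, MAX_DISTANCE + 1))
        parts = {frozenset(c) for c in connected_components(network, t_above)}
        if parts != prev:
            out.append((float(s), len(parts)))
            prev = parts
    return out
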