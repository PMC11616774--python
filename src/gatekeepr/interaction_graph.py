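"""Interaction graph derivation and structural node scores.

The interaction graph of a Boolean network has a directed edge g → h exactly
when g appears in the input list of h's update rule.  It is exponentially
smaller than the 2^n-state dynamic state graph, which is what makes
structure-based screening feasible for large models.

Two structural measures live here:

* **vertex betweenness** (VB) — fractional shortest-path betweenness on the
  directed, unweighted graph (Freeman/Brandes definition, endpoints excluded,
  unnormalized).  High-VB nodes are bottlenecks of information flow.
* **z-transformed connectivity** C_i = (δ_i − δ̄)/σ, where δ_i is the total
  (in + out) degree and δ̄, σ are the population mean and standard deviation
  of the degree distribution.  Nodes with C_i ≥ 2.5 are conventionally called
  hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model_io import BooleanNetwork

__all__ = [
    "build_interaction_graph",
    "vertex_betweenness",
    "DegreeStats",
    "connectivity_zscores",
    "detect_hubs",
]

DEFAULT_HUB_THRESHOLD = 2.5


def build_interaction_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Directed regulator→target graph of the network's rule dependencies.

    Node order follows the network; self-loops are kept; inputs are distinct
    per rule, so there are no parallel edges.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(net.nodes)
    for target in net.nodes:
        for regulator in net.rules[target].inputs:
            graph.add_edge(regulator, target)
    return graph


def vertex_betweenness(graph: nx.DiGraph) -> dict[str, float]:
    """Unnormalized fractional betweenness of every node.

    VB(v) = Σ_{s≠t≠v} σ_st(v)/σ_st over ordered pairs, where σ_st counts
    shortest s→t paths; unreachable pairs contribute 0.  Self-loops never lie
    on a shortest path and are ignored.
    """
    return nx.betweenness_centrality(graph, normalized=False)


@dataclass(frozen=True)
class DegreeStats:
    """Total degrees and their z-transformation for one graph."""

    degrees: dict[str, int]
    mean: float
    std: float
    zscores: dict[str, float]


def connectivity_zscores(graph: nx.DiGraph) -> DegreeStats:
    """Compute δ_i, δ̄, σ (population) and C_i = (δ_i − δ̄)/σ per node.

    A self-loop adds 1 to the in-degree and 1 to the out-degree.  On a
    degree-regular graph σ = 0 and every C_i is defined as 0 (no hubs).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("connectivity z-scores are undefined for an empty graph")
    nodes = list(graph.nodes)
    degrees = {v: graph.in_degree(v) + graph.out_degree(v) for v in nodes}
    values = np.array([degrees[v] for v in nodes], dtype=float)
    mean = float(values.mean())
    std = float(values.std())  # population (divide-by-n)
    if std > 0:
        z = {v: (degrees[v] - mean) / std for v in nodes}
    else:
        z = {v: 0.0 for v in nodes}
    return DegreeStats(degrees=degrees, mean=mean, std=std, zscores=z)


def detect_hubs(
    stats: DegreeStats, hub_threshold: float = DEFAULT_HUB_THRESHOLD
) -> set[str]:
    """Nodes with C_i ≥ *hub_threshold* (the boundary value is included)."""
    return {v for v, c in stats.zscores.items() if c >= hub_threshold}
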