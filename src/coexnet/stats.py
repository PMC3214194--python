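"""Network statistics panel: degree and weight distributions, diameter,
local clustering coefficients, cluster sizes.

Conventions chosen for filtered (possibly disconnected) views:

* the diameter is the maximum eccentricity within each connected component,
  maximized over components — disconnected pairs never contribute, so the
  statistic stays finite and informative on heavily filtered networks;
* the local clustering coefficient of a node of degree < 2 is 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError, InvalidDataError
from .explore import connected_components

__all__ = [
    "NetworkStats",
    "degree_distribution",
    "diameter",
    "local_clustering_coefficient",
    "weight_and_cluster_distributions",
    "network_stats",
]


@dataclass
class NetworkStats:
    degree_histogram: dict[int, int]
    diameter: int
    weight_histogram: list[int]
    weight_bin_edges: list[float]
    local_cc: dict[str, float]
    cluster_sizes: list[int]

    def to_dict(self) -> dict:
        return {
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "diameter": self.diameter,
            "weight_histogram": self.weight_histogram,
            "weight_bin_edges": self.weight_bin_edges,
            "mean_local_clustering_coefficient": (
                float(np.mean(list(self.local_cc.values()))) if self.local_cc else 0.0
            ),
            "local_clustering_coefficient": {k: self.local_cc[k] for k in sorted(self.local_cc)},
            "cluster_sizes": self.cluster_sizes,
        }


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Map degree value -> number of nodes with that degree."""
    return dict(Counter(d for _, d in g.degree()))


def diameter(g: nx.Graph) -> int:
    """Maximum within-component eccentricity; 0 for a single-node network."""
    if g.number_of_nodes() == 0:
        raise InvalidDataError("diameter of an empty network is undefined")
    best = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        best = max(best, nx.diameter(sub))
    return int(best)


def local_clustering_coefficient(g: nx.Graph) -> dict[str, float]:
    """Watts–Strogatz local clustering coefficient per node:
    2 T(v) / (k (k-1)) for degree k >= 2, else 0."""
    return {str(n): float(c) for n, c in nx.clustering(g).items()}


def weight_and_cluster_distributions(
    g: nx.Graph, bins: int = 20
) -> tuple[list[int], list[float], list[int]]:
    """Equal-width edge-weight histogram over [min, max] plus the multiset
    of connected-component sizes (decreasing).

    A degenerate weight range (all edges equal, or a single edge) yields a
    single bin holding every edge.  Returns (counts, bin_edges, sizes).
    """
    if bins < 1:
        raise InvalidArgumentError("bins must be >= 1")
    weights = np.array([d.get("weight", 1.0) for _, _, d in g.edges(data=True)])
    if weights.size == 0:
        counts, edges = [], []
    elif weights.min() == weights.max():
        counts = [int(weights.size)]
        edges = [float(weights.min()), float(weights.max())]
    else:
        c, e = np.histogram(weights, bins=bins, range=(weights.min(), weights.max()))
        counts, edges = [int(x) for x in c], [float(x) for x in e]
    sizes = sorted(
        (len(c) for c in nx.connected_components(g)), reverse=True
    )
    return counts, edges, sizes


def network_stats(g: nx.Graph, bins: int = 20) -> NetworkStats:
    """Compute the full statistics panel in one call."""
    counts, edges, sizes = weight_and_cluster_distributions(g, bins=bins)
    return NetworkStats(
        degree_histogram=degree_distribution(g),
        diameter=diameter(g),
        weight_histogram=counts,
        weight_bin_edges=edges,
        local_cc=local_clustering_coefficient(g),
        cluster_sizes=sizes,
    )
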