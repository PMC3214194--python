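"""Interactive-exploration semantics, headless.

Everything a user of the original GUI could do to a loaded co-expression
network is reproduced here as pure functions on :class:`networkx.Graph`:

* :class:`FilterState` — edge-weight threshold, minimum-degree cutoff and
  cluster selection; every other operation can be made filter-aware by
  applying it first;
* "deepness" neighborhoods — the BFS ball of radius d around a selected
  node set, or the full reachable component at ``deepness="max"``;
* unweighted shortest paths with a lexicographic tie rule;
* Girvan–Newman clustering by removing a chosen number of
  highest-betweenness edges.

All tie-breaks are lexicographic on node ids so results are reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .errors import InvalidArgumentError, UnknownNodeError

MAX_DEEPNESS = "max"

__all__ = [
    "FilterState",
    "NeighborhoodQuery",
    "ClusterAssignment",
    "apply_filter",
    "connected_components",
    "neighborhood_subnetwork",
    "induce_subnetwork",
    "shortest_path",
    "edge_betweenness",
    "girvan_newman_clusters",
    "search_nodes",
    "MAX_DEEPNESS",
]


@dataclass(frozen=True)
class FilterState:
    """Active view filter.

    ``min_edge_weight`` keeps edges with weight >= the threshold ("under"
    the threshold is excluded).  ``min_degree`` removes nodes whose degree
    in the edge-filtered graph falls below the cutoff — by default in a
    single pass (degrees measured once, not recomputed after removals);
    ``iterate_degree=True`` switches to iterated k-core-style pruning.
    ``selected_clusters`` restricts the view to the chosen connected
    components of the edge-filtered graph, labeled per
    :class:`ClusterAssignment`.
    """

    min_edge_weight: float = 0.0
    min_degree: int = 0
    selected_clusters: frozenset[int] | None = None
    iterate_degree: bool = False

    def __post_init__(self) -> None:
        if self.min_edge_weight < 0:
            raise InvalidArgumentError("min_edge_weight must be >= 0")
        if self.min_degree < 0:
            raise InvalidArgumentError("min_degree must be >= 0")
        if self.selected_clusters is not None:
            object.__setattr__(
                self, "selected_clusters", frozenset(self.selected_clusters)
            )


@dataclass(frozen=True)
class NeighborhoodQuery:
    """n selected node ids plus a deepness d (BFS radius), or ``"max"``."""

    selected_ids: frozenset[str]
    deepness: int | str = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected_ids", frozenset(self.selected_ids))
        if not self.selected_ids:
            raise InvalidArgumentError("selected_ids must be nonempty")
        d = self.deepness
        if isinstance(d, str):
            if d.lower() != MAX_DEEPNESS:
                raise InvalidArgumentError(f"deepness must be an integer or 'max', got {d!r}")
            object.__setattr__(self, "deepness", MAX_DEEPNESS)
        elif d < 0:
            raise InvalidArgumentError("deepness must be >= 0")


@dataclass
class ClusterAssignment:
    """node id -> cluster label; labels are consecutive integers ordered by
    decreasing cluster size, ties broken by the smallest member id."""

    labels: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_components(cls, components) -> "ClusterAssignment":
        comps = [sorted(map(str, c)) for c in components]
        comps.sort(key=lambda c: (-len(c), c[0]))
        labels = {n: i for i, c in enumerate(comps) for n in c}
        return cls(labels=labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return sorted(n for n, l in self.labels.items() if l == label)

    def sizes(self) -> list[int]:
        from collections import Counter

        counts = Counter(self.labels.values())
        return [counts[i] for i in range(self.n_clusters)]


def apply_filter(g: nx.Graph, f: FilterState) -> nx.Graph:
    """Apply a view filter: drop weak edges, then low-degree nodes (one
    pass), then restrict to selected clusters of the edge-filtered graph."""
    edge_filtered = nx.Graph()
    edge_filtered.add_nodes_from(g.nodes(data=True))
    for u, v, data in g.edges(data=True):
        if data.get("weight", 1.0) >= f.min_edge_weight:
            edge_filtered.add_edge(u, v, **data)

    if f.iterate_degree and f.min_degree > 0:
        pruned = edge_filtered.copy()
        while True:
            doomed = [n for n in pruned if pruned.degree(n) < f.min_degree]
            if not doomed:
                break
            pruned.remove_nodes_from(doomed)
        keep = set(pruned.nodes)
    else:
        keep = {n for n in edge_filtered if edge_filtered.degree(n) >= f.min_degree}

    if f.selected_clusters is not None:
        assignment = connected_components(edge_filtered)
        keep &= {
            n for n, lab in assignment.labels.items() if lab in f.selected_clusters
        }
    return edge_filtered.subgraph(keep).copy()


def connected_components(g: nx.Graph) -> ClusterAssignment:
    """Clusters = maximal sub-networks without a connection between them.

    Callers exploring a filtered view pass the filtered network: clusters
    never take excluded edges into account.
    """
    return ClusterAssignment.from_components(nx.connected_components(g))


def _require_nodes(g: nx.Graph, ids, detail: str = "") -> None:
    for nid in sorted(ids):
        if nid not in g:
            raise UnknownNodeError(nid, detail)


def neighborhood_subnetwork(g: nx.Graph, q: NeighborhoodQuery) -> nx.Graph:
    """BFS ball of radius ``deepness`` around the selected set, induced.

    ``deepness="max"`` returns the union of the selected nodes' connected
    components, i.e. everything reachable regardless of distance.
    """
    _require_nodes(g, q.selected_ids)
    if q.deepness == MAX_DEEPNESS:
        included: set[str] = set()
        for nid in q.selected_ids:
            included |= nx.node_connected_component(g, nid)
    else:
        included = set(q.selected_ids)
        frontier = set(q.selected_ids)
        for _ in range(int(q.deepness)):
            frontier = {
                nbr for n in frontier for nbr in g.neighbors(n)
            } - included
            if not frontier:
                break
            included |= frontier
    return g.subgraph(included).copy()


def induce_subnetwork(g: nx.Graph, keep) -> nx.Graph:
    """Induced subgraph on ``keep`` (the 'remove non-selected nodes' action)."""
    keep = set(keep)
    _require_nodes(g, keep)
    return g.subgraph(keep).copy()


def shortest_path(
    g: nx.Graph, f: FilterState | None, a: str, b: str
) -> list[str] | None:
    """Unweighted (hop-count) shortest path on the filtered network.

    Among equal-length paths the lexicographically smallest node-id
    sequence is returned; ``a == b`` yields ``[a]``; unreachable pairs
    yield ``None`` (an explicit no-path result, not an exception).  A
    terminal that exists in the network but was removed by the filter
    raises :class:`UnknownNodeError` citing the filter.
    """
    h = apply_filter(g, f) if f is not None else g
    for nid in (a, b):
        if nid not in h:
            if f is not None and nid in g:
                raise UnknownNodeError(nid, "node removed by the active filter")
            raise UnknownNodeError(nid)
    if a == b:
        return [a]
    dist = {a: 0}
    queue = deque([a])
    while queue:
        n = queue.popleft()
        for nbr in h.neighbors(n):
            if nbr not in dist:
                dist[nbr] = dist[n] + 1
                queue.append(nbr)
    if b not in dist:
        return None
    # reconstruct forward, greedily taking the smallest id that still lies
    # on some shortest a->b path (dist from b certifies reachability)
    dist_b = {b: 0}
    queue = deque([b])
    while queue:
        n = queue.popleft()
        for nbr in h.neighbors(n):
            if nbr not in dist_b:
                dist_b[nbr] = dist_b[n] + 1
                queue.append(nbr)
    total = dist[b]
    path = [a]
    current = a
    while current != b:
        step = len(path)  # next node must sit at this distance from a
        candidates = [
            nbr
            for nbr in h.neighbors(current)
            if dist.get(nbr) == step and dist_b.get(nbr) == total - step
        ]
        current = min(candidates)
        path.append(current)
    return path


def edge_betweenness(g: nx.Graph) -> dict[tuple[str, str], float]:
    """Unweighted shortest-path edge betweenness.

    For each unordered node pair (a, b), every edge receives
    (number of shortest a-b paths through it) / (total shortest a-b paths);
    credits are summed over all pairs.  Keys are sorted (u, v) tuples.
    """
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    return {tuple(sorted((str(u), str(v)))): val for (u, v), val in raw.items()}


def girvan_newman_clusters(
    g: nx.Graph, m: int
) -> tuple[ClusterAssignment, list[tuple[str, str]]]:
    """Girvan–Newman clustering: remove the m highest-betweenness edges.

    Each of the m iterations recomputes edge betweenness on the current
    residual graph and removes the single highest-betweenness edge (ties:
    lexicographically smallest (source, target) pair).  Returns the
    connected components of the residual graph and the removal sequence.
    """
    if m < 0 or m > g.number_of_edges():
        raise InvalidArgumentError(
            f"m must be between 0 and the edge count ({g.number_of_edges()}), got {m}"
        )
    h = g.copy()
    removed: list[tuple[str, str]] = []
    for _ in range(m):
        bet = edge_betweenness(h)
        target = min(bet, key=lambda e: (-bet[e], e))
        h.remove_edge(*target)
        removed.append(target)
    return connected_components(h), removed


def search_nodes(g: nx.Graph, query: str) -> list[str]:
    """Case-insensitive substring search over node ids and all node
    attribute values; returns matching ids sorted."""
    q = query.lower()
    hits = []
    for n, attrs in g.nodes(data=True):
        if q in str(n).lower() or any(q in str(v).lower() for v in attrs.values()):
            hits.append(str(n))
    return sorted(hits)
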