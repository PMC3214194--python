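"""Independent brute-force oracles used only by the tests.

Everything here is written with explicit loops and elementary data
structures, deliberately avoiding the code paths (and the libraries) that
the implementation under test uses, so that agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter


def mi_plugin(a, b) -> float:
    """Plug-in mutual information by direct dictionary counting, in nats."""
    n = len(a)
    assert n == len(b)
    if n <= 1:
        return 0.0
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((pa[x] / n) * (pb[y] / n)))
    return total


def entropy_plugin(a) -> float:
    """Plug-in entropy by direct counting, in nats."""
    n = len(a)
    return -sum((c / n) * math.log(c / n) for c in Counter(a).values())


def mrmr_exhaustive(mim):
    """Directed MRMR scores from a symmetric MI matrix, explicit loops.

    scores[i][j] = the MRMR forward-selection score of predictor i for
    target j, selection run to exhaustion, arg-max ties to lowest index.
    """
    p = len(mim)
    scores = [[0.0] * p for _ in range(p)]
    for target in range(p):
        candidates = [i for i in range(p) if i != target]
        selected = []
        while candidates:
            best_i, best_u = None, None
            for i in candidates:
                relevance = mim[i][target]
                if selected:
                    redundancy = sum(mim[i][k] for k in selected) / len(selected)
                else:
                    redundancy = 0.0
                u = relevance - redundancy
                if best_u is None or u > best_u:  # strict: first max wins ties
                    best_i, best_u = i, u
            scores[best_i][target] = best_u
            selected.append(best_i)
            candidates.remove(best_i)
    return scores


def mrnet_weights_exhaustive(mim):
    """Undirected MRNET weights from the exhaustive directed scores."""
    scores = mrmr_exhaustive(mim)
    p = len(mim)
    w = [[0.0] * p for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i != j:
                w[i][j] = max(0.0, scores[i][j], scores[j][i])
    return w


def _adjacency(edges, nodes):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def enumerate_shortest_paths(edges, nodes, a, b):
    """All shortest a-b paths by breadth-first layer expansion of whole paths."""
    adj = _adjacency(edges, nodes)
    if a == b:
        return [[a]]
    frontier = [[a]]
    found = []
    seen_depth = {a: 0}
    depth = 0
    while frontier and not found:
        depth += 1
        nxt = []
        for path in frontier:
            for nbr in adj[path[-1]]:
                if nbr in path:
                    continue
                if seen_depth.get(nbr, depth) < depth:
                    continue
                seen_depth[nbr] = depth
                new = path + [nbr]
                if nbr == b:
                    found.append(new)
                else:
                    nxt.append(new)
        frontier = nxt
    return found


def betweenness_by_path_counting(edges, nodes):
    """Edge betweenness by enumerating every shortest path of every pair."""
    credit = {tuple(sorted(e)): 0.0 for e in edges}
    node_list = sorted(nodes)
    for i, a in enumerate(node_list):
        for b in node_list[i + 1:]:
            paths = enumerate_shortest_paths(edges, nodes, a, b)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for u, v in zip(path, path[1:]):
                    credit[tuple(sorted((u, v)))] += share
    return credit


def shortest_length_bruteforce(edges, nodes, a, b):
    """Minimum a-b path length via exhaustive simple-path enumeration."""
    adj = _adjacency(edges, nodes)
    best = [None]

    def walk(node, visited, length):
        if best[0] is not None and length >= best[0]:
            return
        if node == b:
            best[0] = length
            return
        for nbr in sorted(adj[node]):
            if nbr not in visited:
                walk(nbr, visited | {nbr}, length + 1)

    walk(a, {a}, 0)
    return best[0]
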