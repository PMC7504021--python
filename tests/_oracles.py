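"""Independent brute-force oracles for graph metrics.

Everything here is written from first principles — hand-rolled BFS,
exhaustive shortest-path enumeration, explicit neighbor-pair counting —
deliberately sharing no code path with the package implementation, so the
two routes check each other.
"""

from __future__ import annotations

from collections import deque


def neighbors_out(graph, node):
    return list(graph.successors(node)) if graph.is_directed() else list(graph.neighbors(node))


def bfs_distances(graph, source) -> dict:
    """Plain hand-rolled BFS hop distances from source."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in neighbors_out(graph, u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(graph, s, t) -> list[list]:
    """Every shortest s→t path, by DFS over the BFS distance levels."""
    dist = bfs_distances(graph, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in neighbors_out(graph, u):
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def weak_components(graph) -> list[set]:
    """Reachability closure on the undirected view, from scratch."""
    undirected_adj = {v: set() for v in graph.nodes}
    for u, v in graph.edges:
        undirected_adj[u].add(v)
        undirected_adj[v].add(u)
    seen, comps = set(), []
    for start in graph.nodes:
        if start in seen:
            continue
        comp, queue = {start}, deque([start])
        while queue:
            u = queue.popleft()
            for v in undirected_adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    return comps


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by exhaustive shortest-path enumeration.

    Raw score of n sums sigma_st(n)/sigma_st over all pairs s != n != t
    (ordered for directed graphs, unordered for undirected); normalization
    divides by the transit-pair count of n's weak component.
    """
    nodes = list(graph.nodes)
    raw = {v: 0.0 for v in nodes}
    pairs = [
        (s, t)
        for s in nodes
        for t in nodes
        if s != t and (graph.is_directed() or str(s) < str(t))
    ]
    for s, t in pairs:
        paths = all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            on = sum(1 for p in paths if n in p)
            raw[n] += on / len(paths)
    result = {}
    for comp in weak_components(graph):
        size = len(comp)
        if graph.is_directed():
            denom = (size - 1) * (size - 2)
        else:
            denom = (size - 1) * (size - 2) / 2
        for n in comp:
            result[n] = raw[n] / denom if denom > 0 else 0.0
    return result


def brute_closeness(graph) -> dict:
    """1 / mean hop distance to reachable nodes; 0 if nothing is reachable."""
    result = {}
    for n in graph.nodes:
        dist = bfs_distances(graph, n)
        reach = [d for v, d in dist.items() if v != n]
        result[n] = len(reach) / sum(reach) if reach and sum(reach) > 0 else 0.0
    return result


def brute_clustering(graph, node) -> float:
    """2 n_I / (k_I (k_I − 1)) by explicit neighbor-pair counting."""
    adj = {v: set() for v in graph.nodes}
    for u, v in graph.edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    nbrs = sorted(adj[node], key=str)
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for i in range(k) for j in range(i + 1, k) if nbrs[j] in adj[nbrs[i]]
    )
    return 2.0 * links / (k * (k - 1))


def brute_path_panel(graph) -> tuple:
    """(diameter, mean distance) over connected ordered pairs, own BFS."""
    dists = []
    for s in graph.nodes:
        for v, d in bfs_distances(graph, s).items():
            if d > 0:
                dists.append(d)
    if not dists:
        return None, None
    return max(dists), sum(dists) / len(dists)


def brute_bottleneck(graph) -> dict:
    """Bottleneck scores by explicit rooted-tree path enumeration.

    Builds the same deterministic tree (BFS levels, lexicographically
    smallest predecessor) from independently computed distances, then lists
    each root-to-node path explicitly and counts memberships by scanning.
    """
    bn = {v: 0 for v in graph.nodes}
    for root in graph.nodes:
        dist = bfs_distances(graph, root)
        tree_nodes = sorted(dist, key=str)
        if len(tree_nodes) - 1 < 2:
            continue
        parent = {root: None}
        for v in tree_nodes:
            if v == root:
                continue
            preds = [
                u
                for u in graph.nodes
                if v in neighbors_out(graph, u) and dist.get(u) == dist[v] - 1
            ]
            parent[v] = min(preds, key=str)
        paths = []
        for v in tree_nodes:
            if v == root:
                continue
            path, u = [], v
            while u is not None:
                path.append(u)
                u = parent[u]
            paths.append(path)  # v ... root
        quota = len(tree_nodes) / 4
        for v in tree_nodes:
            if v == root:
                continue
            meets = sum(1 for p in paths if v in p)
            if meets > quota:
                bn[v] += 1
    return bn


def brute_r2(x, y) -> float:
    """Coefficient of determination of the least-squares line, from sums."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    if syy == 0:
        return 0.0
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((yi - (slope * xi + intercept)) ** 2 for xi, yi in zip(x, y))
    return 1.0 - ss_res / syy
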