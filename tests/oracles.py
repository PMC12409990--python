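"""Independent brute-force oracles used to cross-check the implementation."""

import itertools

import networkx as nx


def enumerate_betweenness(g: nx.Graph, length_attr: str = "length") -> dict:
    """Unnormalized node betweenness by exhaustive simple-path enumeration.

    For every unordered node pair, enumerates all simple paths, keeps those
    of minimal total length (ties within 1e-12), and credits each interior
    node with 1/#shortest-paths.  Exponential — only for tiny graphs.
    """
    nodes = sorted(g.nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best = None
        shortest = []
        for path in nx.all_simple_paths(g, s, t):
            length = sum(g[a][b][length_attr] for a, b in zip(path, path[1:]))
            if best is None or length < best - 1e-12:
                best = length
                shortest = [path]
            elif abs(length - best) <= 1e-12:
                shortest.append(path)
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def random_weighted_graph(n: int, p: float, rng) -> nx.Graph:
    """Erdos-Renyi graph with uniform(0.5, 3) contact weights and length 1/w."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            w = float(rng.uniform(0.5, 3.0))
            g.add_edge(i, j, weight=w, length=1.0 / w)
    return g


def nearest_projection_index(points, target) -> int:
    """Exhaustive nearest-point scan (lowest index wins ties)."""
    best, best_d = 0, float("inf")
    for i, p in enumerate(points):
        d = sum((a - b) ** 2 for a, b in zip(p, target))
        if d < best_d:
            best, best_d = i, d
    return best
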