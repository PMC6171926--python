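"""Independent brute-force oracles used only in tests.

These recompute the graph metrics from their definitions (exhaustive
path enumeration, subset enumeration, dense eigendecomposition) or via
networkx, never through the package's own algorithms.
"""

import itertools

import networkx as nx
import numpy as np


def to_nx(adj: np.ndarray, directed: bool = False):
    cls = nx.DiGraph if directed else nx.Graph
    return nx.from_numpy_array(np.asarray(adj), create_using=cls)


def brute_betweenness(adj: np.ndarray, directed: bool = False) -> np.ndarray:
    """Betweenness by explicit enumeration of every shortest path."""
    g = to_nx(adj, directed)
    n = adj.shape[0]
    scores = np.zeros(n)
    pairs = (
        itertools.permutations(range(n), 2)
        if directed
        else itertools.combinations(range(n), 2)
    )
    for s, t in pairs:
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                scores[v] += 1.0 / len(paths)
    return scores


def brute_clique_number(adj: np.ndarray) -> int:
    """Maximum clique size by enumerating all vertex subsets (n <= ~12)."""
    adj = np.asarray(adj)
    adj = ((adj + adj.T) != 0).astype(int)
    n = adj.shape[0]
    best = 1 if n else 0
    for size in range(2, n + 1):
        found = False
        for subset in itertools.combinations(range(n), size):
            if all(adj[i, j] for i, j in itertools.combinations(subset, 2)):
                best, found = size, True
                break
        if not found:
            break
    return best


def dense_eigenvector(adj: np.ndarray) -> np.ndarray:
    """Eigenvector scores from a dense symmetric eigendecomposition.

    Restricted to the largest connected component (isolates and smaller
    components get 0), rescaled to max 1 — the same convention as the
    implementation, reached by a different algorithm.
    """
    adj = np.asarray(adj, dtype=float)
    adj = ((adj + adj.T) != 0).astype(float)
    g = to_nx(adj)
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    if not comps:
        return np.zeros(adj.shape[0])
    comp = sorted(max(comps, key=lambda c: (len(c), -min(c))))
    sub = adj[np.ix_(comp, comp)]
    evals, evecs = np.linalg.eigh(sub)
    vec = np.abs(evecs[:, -1])
    out = np.zeros(adj.shape[0])
    out[comp] = vec / vec.max()
    return out


def nx_closeness(adj: np.ndarray, directed: bool = False) -> np.ndarray:
    """Wasserman-Faust closeness via networkx (distance *from* the node)."""
    g = to_nx(adj, directed)
    if directed:
        g = g.reverse()  # networkx closeness uses incoming distance
    scores = nx.closeness_centrality(g, wf_improved=True)
    return np.array([scores[i] for i in range(adj.shape[0])])


def nx_clique_number(adj: np.ndarray) -> int:
    g = to_nx(((np.asarray(adj) + np.asarray(adj).T) != 0).astype(int))
    return max(len(c) for c in nx.find_cliques(g))
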