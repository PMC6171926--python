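"""Pen-level network properties: centralities, Freeman centralisation, cliques.

The pen-level summary of an agonistic network is Freeman centralisation:
the sum of differences between the most central animal's centrality and
every other animal's, divided by the theoretical largest such sum in any
network of the same size.  A star network scores 1 (maximally
centralised), a ring scores 0.  Four individual centralities feed this
summary — degree (partner count), betweenness (shortest-path brokerage),
eigenvector (neighbour-quality weighted connectivity) and closeness
(inverse mean geodesic distance) — plus the size of the largest clique,
the biggest fully connected subgroup in which every pig interacted with
every other.

All metrics operate on the binary (0/1) adjacency: repeated interactions
between the same pair do not increase centrality, only the number of
distinct partners and the path structure matter.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import BEHAVIOURS, PenNetwork, binary_adjacency, build_pen_network

__all__ = [
    "CentralityScoreSet",
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "closeness_centrality",
    "freeman_centralisation",
    "largest_clique_size",
    "network_traits",
    "pen_trait_table",
]

EIGEN_TOL = 1e-10
EIGEN_MAX_ITER = 10_000


class DegenerateNetworkWarning(UserWarning):
    """Raised when a pen's network is edgeless and metrics default to 0."""


@dataclass
class CentralityScoreSet:
    """Individual centrality scores for every member of one pen."""

    metric: str
    values: np.ndarray  # aligned with node order
    directed: bool
    nodes: list[str] | None = None
    pen_id: str | None = None

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def scores(self) -> dict[str, float]:
        if self.nodes is None:
            return {str(i): float(v) for i, v in enumerate(self.values)}
        return {node: float(v) for node, v in zip(self.nodes, self.values)}


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    return (adj != 0).astype(np.int8)


def _neighbour_lists(adj: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(adj[i]) for i in range(adj.shape[0])]


def degree_centrality(
    adj: np.ndarray,
    mode: str = "total",
    *,
    nodes: list[str] | None = None,
    pen_id: str | None = None,
) -> CentralityScoreSet:
    """Number of direct connections, as raw partner counts.

    ``in`` counts attackers of the focal animal (column sums), ``out``
    counts its victims (row sums); both require a directed network.
    ``total`` counts distinct partners in either direction.
    """
    adj = _check_adjacency(adj)
    symmetric = bool(np.array_equal(adj, adj.T))
    if mode == "in":
        if symmetric:
            raise ValueError("in-degree is only defined for directed networks")
        values = adj.sum(axis=0).astype(float)
    elif mode == "out":
        if symmetric:
            raise ValueError("out-degree is only defined for directed networks")
        values = adj.sum(axis=1).astype(float)
    elif mode == "total":
        sym = ((adj + adj.T) != 0).astype(np.int8)
        values = sym.sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    metric = {"in": "degree_in", "out": "degree_out", "total": "degree_total"}[mode]
    return CentralityScoreSet(metric, values, directed=not symmetric, nodes=nodes, pen_id=pen_id)


def betweenness_centrality(
    adj: np.ndarray,
    directed: bool = False,
    *,
    nodes: list[str] | None = None,
    pen_id: str | None = None,
) -> CentralityScoreSet:
    """Shortest-path betweenness by Brandes' accumulation.

    For each node v the score sums, over pairs (s, t) with s != t != v,
    the fraction of shortest s-t paths passing through v.  Pairs are
    unordered for undirected networks and ordered for directed ones;
    unreachable pairs contribute nothing.
    """
    adj = _check_adjacency(adj)
    if not directed:
        adj = ((adj + adj.T) != 0).astype(np.int8)
    n = adj.shape[0]
    nbrs = _neighbour_lists(adj)
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest paths (unweighted BFS)
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    if not directed:
        bc /= 2.0  # each unordered pair was accumulated from both endpoints
    return CentralityScoreSet("betweenness", bc, directed=directed, nodes=nodes, pen_id=pen_id)


def _components(adj: np.ndarray) -> list[np.ndarray]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = [start]
        while queue:
            v = queue.popleft()
            for w in np.flatnonzero(adj[v]):
                if not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    queue.append(w)
        comps.append(np.array(sorted(comp)))
    return comps


def eigenvector_centrality(
    adj: np.ndarray,
    *,
    nodes: list[str] | None = None,
    pen_id: str | None = None,
) -> CentralityScoreSet:
    """Dominant-eigenvector centrality, rescaled so the maximum score is 1.

    Scores are computed on the largest connected component by a shifted
    power iteration ((A + I) has the same dominant eigenvector as A but
    cannot oscillate on bipartite components); all other nodes, including
    isolates, score 0.  An edgeless network returns all zeros with a
    degenerate-network warning.
    """
    adj = _check_adjacency(adj)
    adj = ((adj + adj.T) != 0).astype(float)  # eigenvector defined on symmetric view
    n = adj.shape[0]
    if adj.sum() == 0:
        warnings.warn(
            "edgeless network: eigenvector centrality degenerate, all scores 0",
            DegenerateNetworkWarning,
            stacklevel=2,
        )
        return CentralityScoreSet("eigenvector", np.zeros(n), False, nodes=nodes, pen_id=pen_id)
    comps = [c for c in _components(adj) if len(c) > 1]
    largest = max(comps, key=len)
    sub = adj[np.ix_(largest, largest)]
    m = len(largest)
    x = np.full(m, 1.0 / np.sqrt(m))
    shifted = sub + np.eye(m)
    for _ in range(EIGEN_MAX_ITER):
        y = shifted @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < EIGEN_TOL:
            x = y
            break
        x = y
    values = np.zeros(n)
    values[largest] = x / x.max()
    return CentralityScoreSet("eigenvector", values, False, nodes=nodes, pen_id=pen_id)


def _geodesics_from(nbrs: list[np.ndarray], source: int, n: int) -> np.ndarray:
    dist = np.full(n, -1)
    dist[source] = 0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in nbrs[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness_centrality(
    adj: np.ndarray,
    directed: bool = False,
    mode: str = "out",
    *,
    nodes: list[str] | None = None,
    pen_id: str | None = None,
) -> CentralityScoreSet:
    """Closeness with the Wasserman-Faust disconnected-graph adjustment.

    Score = (r / (n-1)) * (r / sum of geodesic distances), where r is the
    number of other nodes the focal animal can reach.  On a connected
    network this is the usual normalised closeness (n-1)/sum(d); on
    disconnected ones the range factor r/(n-1) keeps small components
    from dominating, so network centralisation stays within [0, 1].
    Isolates and nodes reaching nobody score 0.  For directed networks
    ``mode='out'`` uses distances from the focal animal (whom it can
    reach), ``mode='in'`` distances to it.
    """
    adj = _check_adjacency(adj)
    if not directed:
        adj = ((adj + adj.T) != 0).astype(np.int8)
    elif mode == "in":
        adj = adj.T
    elif mode != "out":
        raise ValueError(f"unknown closeness mode {mode!r}")
    n = adj.shape[0]
    nbrs = _neighbour_lists(adj)
    values = np.zeros(n)
    for v in range(n):
        dist = _geodesics_from(nbrs, v, n)
        reach = dist > 0
        if reach.any():
            r = reach.sum()
            values[v] = (r / (n - 1)) * (r / dist[reach].sum())
    return CentralityScoreSet("closeness", values, directed=directed, nodes=nodes, pen_id=pen_id)


def freeman_centralisation(
    scoreset: CentralityScoreSet | np.ndarray,
    metric: str | None = None,
    directed: bool | None = None,
) -> float:
    """Freeman's network centralisation, in [0, 1].

    Sum of differences between the most central animal's score and every
    other animal's, divided by the theoretical maximum of that sum over
    all networks of the same size n:

    ===========  ==========  =============================
    metric       network     theoretical maximum
    ===========  ==========  =============================
    degree       undirected  (n-1)(n-2)
    degree       directed    (n-1)^2       (in or out)
    betweenness  undirected  (n-1)^2 (n-2)/2
    betweenness  directed    (n-1)^2 (n-2)
    closeness    undirected  (n-1)(n-2)/(2n-3)
    closeness    directed    n-1           (out-star attains it)
    eigenvector  any         n-2  (attained by a single dyad
                             plus isolates, where the pair
                             scores 1 and everyone else 0)
    ===========  ==========  =============================

    The eigenvector maximum is the convention of igraph's
    ``centr_eigen``; a star network does not attain 1 on this metric
    (its leaves retain positive scores), only degree, betweenness and
    closeness centralisation reach exactly 1 on a star.
    """
    if isinstance(scoreset, CentralityScoreSet):
        values = scoreset.values
        metric = metric or scoreset.metric
        if directed is None:
            directed = scoreset.directed
    else:
        values = np.asarray(scoreset, dtype=float)
        if metric is None:
            raise ValueError("metric required when passing a raw score array")
        directed = bool(directed)
    n = len(values)
    if n < 3:
        raise ValueError(f"centralisation undefined for n={n} < 3 nodes")
    base = metric.split("_")[0]  # degree_in -> degree
    if base == "degree":
        denom = float((n - 1) ** 2) if directed else float((n - 1) * (n - 2))
    elif base == "betweenness":
        denom = (n - 1) ** 2 * (n - 2) * (1.0 if directed else 0.5)
    elif base == "closeness":
        denom = float(n - 1) if directed else (n - 1) * (n - 2) / (2 * n - 3)
    elif base == "eigenvector":
        denom = float(n - 2)
    else:
        raise ValueError(f"no centralisation maximum known for metric {metric!r}")
    result = float(np.sum(values.max() - values) / denom)
    if not -1e-6 <= result <= 1 + 1e-6:
        raise RuntimeError(f"centralisation {result} outside [0, 1] for metric {metric!r}")
    return min(max(result, 0.0), 1.0)


def largest_clique_size(adj: np.ndarray) -> int:
    """Size of the maximum clique (Bron-Kerbosch with pivoting, bitsets).

    Directed networks are symmetrised first.  An edgeless network has
    largest clique size 1 (every animal is a trivial clique of itself).
    """
    adj = _check_adjacency(adj)
    adj = ((adj + adj.T) != 0).astype(np.int8)
    n = adj.shape[0]
    if n == 0:
        return 0
    nbr_mask = [int(sum(1 << j for j in np.flatnonzero(adj[i]))) for i in range(n)]
    best = 1

    def expand(r_size: int, p: int, x: int) -> None:
        nonlocal best
        if p == 0 and x == 0:
            best = max(best, r_size)
            return
        if r_size + int.bit_count(p) <= best:
            return  # cannot beat current best
        # pivot: vertex of P|X with most neighbours in P
        pux = p | x
        pivot, pivot_deg = -1, -1
        m = pux
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            d = int.bit_count(nbr_mask[v] & p)
            if d > pivot_deg:
                pivot, pivot_deg = v, d
        cand = p & ~nbr_mask[pivot]
        while cand:
            v = (cand & -cand).bit_length() - 1
            cand &= cand - 1
            vbit = 1 << v
            expand(r_size + 1, p & nbr_mask[v], x & nbr_mask[v])
            p &= ~vbit
            x |= vbit

    expand(0, (1 << n) - 1, 0)
    return best


def network_traits(network: PenNetwork) -> dict[str, float]:
    """All pen-level properties of one network, as a flat dict.

    Directed (bullying) networks additionally report in- and out-degree
    centralisation and use directed betweenness and closeness; their
    eigenvector centralisation and clique size are computed on the
    symmetrised network (engagement in aggression, given or received).
    Edgeless pens report every centralisation as 0 with a ``degenerate``
    flag instead of missing values.
    """
    adj = binary_adjacency(network)
    n = network.n
    out: dict[str, float] = {
        "pen_id": network.pen_id,
        "behaviour": network.behaviour_type,
        "n_nodes": n,
        "n_edges": network.n_edges,
    }
    degenerate = network.n_edges == 0
    out["degenerate"] = degenerate
    if degenerate:
        for key in (
            "degree_centralisation",
            "betweenness_centralisation",
            "eigenvector_centralisation",
            "closeness_centralisation",
        ):
            out[key] = 0.0
        if network.directed:
            out["in_degree_centralisation"] = 0.0
            out["out_degree_centralisation"] = 0.0
        out["largest_clique_size"] = 1 if n else 0
        return out

    directed = network.directed
    out["degree_centralisation"] = freeman_centralisation(
        degree_centrality(adj, "total"), "degree", directed=False
    )
    if directed:
        out["in_degree_centralisation"] = freeman_centralisation(degree_centrality(adj, "in"))
        out["out_degree_centralisation"] = freeman_centralisation(degree_centrality(adj, "out"))
    out["betweenness_centralisation"] = freeman_centralisation(
        betweenness_centrality(adj, directed=directed)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateNetworkWarning)
        out["eigenvector_centralisation"] = freeman_centralisation(eigenvector_centrality(adj))
    out["closeness_centralisation"] = freeman_centralisation(
        closeness_centrality(adj, directed=directed, mode="out")
    )
    out["largest_clique_size"] = largest_clique_size(adj)
    return out


def pen_trait_table(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    behaviours: tuple[str, ...] = BEHAVIOURS,
) -> pd.DataFrame:
    """Tidy table of network properties: one row per pen x behaviour type."""
    rows = []
    by_pen = dict(tuple(events.groupby("pen_id"))) if len(events) else {}
    empty = events.iloc[0:0]
    for pen_id, pen_roster in roster.groupby("pen_id", sort=False):
        pen_events = by_pen.get(pen_id, empty)
        for behaviour in behaviours:
            net = build_pen_network(pen_events, pen_roster, pen_id, behaviour)
            rows.append(network_traits(net))
    df = pd.DataFrame(rows)
    ordered = [
        "pen_id",
        "behaviour",
        "n_nodes",
        "n_edges",
        "degree_centralisation",
        "in_degree_centralisation",
        "out_degree_centralisation",
        "betweenness_centralisation",
        "eigenvector_centralisation",
        "closeness_centralisation",
        "largest_clique_size",
        "degenerate",
    ]
    return df.reindex(columns=[c for c in ordered if c in df.columns])
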