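"""Construction of per-pen agonistic interaction networks.

Each pen of pigs yields up to three networks built from the 24 h
post-mixing event log: a *fight* network (reciprocal aggression,
undirected), a *bully* network (unreciprocated aggression, directed
initiator -> receiver) and a *combined* network containing every
aggressive interaction (undirected).  Pen members that never engaged in
aggression are retained as isolates, so the node set always equals the
pen roster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "PenNetwork",
    "build_pen_network",
    "binary_adjacency",
    "write_edge_list",
    "write_graphml",
]

BEHAVIOURS = ("fight", "bully", "combined")


class DataIntegrityError(ValueError):
    """An event log is inconsistent with the roster it claims to describe."""


@dataclass
class PenNetwork:
    """One behaviour-class network for one pen.

    ``edges`` maps an (source, target) pair to ``(weight, total_duration)``
    where weight is the number of repeated interactions between that pair
    and total_duration their summed duration in seconds.  For undirected
    networks pairs are stored with source < target (string order).
    """

    pen_id: str
    behaviour_type: str
    nodes: list[str]
    directed: bool
    edges: dict[tuple[str, str], tuple[int, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": s, "target": t, "weight": w, "total_duration": d}
            for (s, t), (w, d) in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "total_duration"])


def _canonical_pair(a: str, b: str, directed: bool) -> tuple[str, str]:
    if directed or a <= b:
        return (a, b)
    return (b, a)


def build_pen_network(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    pen_id: str,
    behaviour_type: str = "fight",
) -> PenNetwork:
    """Build one pen's network from the event log.

    Fights are mutual by definition and give undirected edges; bullying is
    directed initiator -> receiver.  The combined network pools both
    behaviours and is undirected.  Repeated interactions between the same
    pair accumulate into a single edge's weight and total duration.
    """
    if behaviour_type not in BEHAVIOURS:
        raise ValueError(f"unknown behaviour_type {behaviour_type!r}")
    members = roster.loc[roster["pen_id"] == pen_id, "pig_id"].tolist()
    if not members:
        raise DataIntegrityError(f"pen {pen_id!r} has no pigs in the roster")
    member_set = set(members)

    ev = events[events["pen_id"] == pen_id]
    if behaviour_type != "combined":
        ev = ev[ev["behaviour"] == behaviour_type]

    directed = behaviour_type == "bully"
    edges: dict[tuple[str, str], tuple[int, float]] = {}
    for ini, rec, dur in zip(ev["initiator"], ev["receiver"], ev["duration"]):
        if ini == rec:
            raise DataIntegrityError(f"self-loop event for pig {ini!r} in pen {pen_id!r}")
        if ini not in member_set or rec not in member_set:
            missing = ini if ini not in member_set else rec
            raise DataIntegrityError(
                f"event in pen {pen_id!r} references pig {missing!r} not in roster"
            )
        key = _canonical_pair(str(ini), str(rec), directed)
        w, d = edges.get(key, (0, 0.0))
        edges[key] = (w + 1, d + float(dur))
    return PenNetwork(
        pen_id=pen_id,
        behaviour_type=behaviour_type,
        nodes=[str(m) for m in members],
        directed=directed,
        edges=edges,
    )


def binary_adjacency(network: PenNetwork) -> np.ndarray:
    """0/1 adjacency in roster node order; symmetric iff undirected.

    Centralities are computed on this binary structure (partner counts);
    edge weights are retained on the network for reporting only.
    """
    idx = {node: i for i, node in enumerate(network.nodes)}
    n = network.n
    adj = np.zeros((n, n), dtype=np.int8)
    for (s, t) in network.edges:
        i, j = idx[s], idx[t]
        adj[i, j] = 1
        if not network.directed:
            adj[j, i] = 1
    return adj


def write_edge_list(network: PenNetwork, path) -> None:
    network.edge_table().to_csv(path, index=False)


def write_graphml(network: PenNetwork, path) -> None:
    """Minimal GraphML export: nodes (isolates included) and weighted edges."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    root = ET.Element("graphml", xmlns=ns)
    for key_id, name, typ in (
        ("w", "weight", "int"),
        ("d", "total_duration", "double"),
    ):
        ET.SubElement(
            root, "key", id=key_id, **{"for": "edge", "attr.name": name, "attr.type": typ}
        )
    graph = ET.SubElement(
        root,
        "graph",
        id=f"{network.pen_id}_{network.behaviour_type}",
        edgedefault="directed" if network.directed else "undirected",
    )
    for node in network.nodes:
        ET.SubElement(graph, "node", id=node)
    for (s, t), (w, d) in sorted(network.edges.items()):
        e = ET.SubElement(graph, "edge", source=s, target=t)
        we = ET.SubElement(e, "data", key="w")
        we.text = str(w)
        de = ET.SubElement(e, "data", key="d")
        de.text = repr(float(d))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
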