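"""Areal adjacency graphs for the spatial priors.

The spatial components of the model (shared and disease-specific) are
intrinsic CAR fields on an undirected country-adjacency graph.  The default
study region is the seven East African Community member states with
queen-contiguity land borders; the lake-separated COD-TZA pair (facing each
other across Lake Tanganyika) is excluded by default but can be toggled.
"""

from __future__ import annotations

import csv

import networkx as nx
import numpy as np

EAC_COUNTRIES = ["BDI", "COD", "KEN", "RWA", "SSD", "TZA", "UGA"]

#: land-border adjacency (queen contiguity on shared land borders)
EAC_LAND_EDGES = [
    ("BDI", "RWA"),
    ("BDI", "COD"),
    ("BDI", "TZA"),
    ("RWA", "COD"),
    ("RWA", "UGA"),
    ("RWA", "TZA"),
    ("COD", "UGA"),
    ("COD", "SSD"),
    ("UGA", "KEN"),
    ("UGA", "TZA"),
    ("UGA", "SSD"),
    ("KEN", "TZA"),
    ("KEN", "SSD"),
]

#: pairs separated by a lake rather than a land border
EAC_LAKE_EDGES = [("COD", "TZA")]


class CountryGraph:
    """Undirected areal adjacency graph over labeled countries.

    Parameters
    ----------
    nodes : sequence of str
        Country identifiers; order fixes the row/column order of the
        adjacency and all derived structure matrices.
    edges : sequence of (str, str)
        Neighbor pairs.  Self-loops are rejected; duplicates (in either
        orientation) are collapsed.
    """

    def __init__(self, nodes, edges):
        self.nodes = list(nodes)
        if len(self.nodes) != len(set(self.nodes)):
            raise ValueError("duplicate node labels")
        if len(self.nodes) < 2:
            raise ValueError("need at least two areas for a spatial prior")
        node_set = set(self.nodes)
        seen = set()
        clean = []
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                clean.append(key)
        self.edges = sorted(clean)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        pos = {n: k for k, n in enumerate(self.nodes)}
        W = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.edges:
            W[pos[a], pos[b]] = 1.0
            W[pos[b], pos[a]] = 1.0
        return W

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of node indices (sorted)."""
        pos = {n: k for k, n in enumerate(self.nodes)}
        comps = nx.connected_components(self.to_networkx())
        out = [np.array(sorted(pos[n] for n in comp)) for comp in comps]
        return sorted(out, key=lambda a: a[0])

    @property
    def n_components(self) -> int:
        return len(self.components())

    def is_connected(self) -> bool:
        return self.n_components == 1

    def neighbors(self, node: str) -> list[str]:
        return sorted(b if a == node else a for a, b in self.edges if node in (a, b))

    def permute(self, new_order) -> "CountryGraph":
        """Same graph with nodes re-ordered (for exchangeability checks)."""
        if sorted(new_order) != sorted(self.nodes):
            raise ValueError("new_order must be a permutation of the node labels")
        return CountryGraph(new_order, self.edges)

    # -- I/O --------------------------------------------------------------
    def to_edge_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["from", "to"])
            for a, b in self.edges:
                w.writerow([a, b])

    @classmethod
    def from_edge_csv(cls, path, nodes=None) -> "CountryGraph":
        edges = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append((row["from"], row["to"]))
        if nodes is None:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes, edges)

    @classmethod
    def from_geojson(cls, path, id_property: str = "id") -> "CountryGraph":
        """Derive contiguity from polygon features (shared boundary => edge)."""
        import json

        from shapely.geometry import shape

        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"]
        labels = [f["properties"][id_property] for f in feats]
        geoms = [shape(f["geometry"]) for f in feats]
        edges = []
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                if geoms[i].touches(geoms[j]) or geoms[i].intersects(geoms[j]):
                    edges.append((labels[i], labels[j]))
        return cls(sorted(labels), edges)


def build_eac_graph(include_lake_borders: bool = False) -> CountryGraph:
    """The default 7-country EAC adjacency graph (connected)."""
    edges = list(EAC_LAND_EDGES)
    if include_lake_borders:
        edges += EAC_LAKE_EDGES
    return CountryGraph(EAC_COUNTRIES, edges)


def random_connected_graph(n_nodes: int, rng: np.random.Generator, extra_edge_prob: float = 0.3) -> CountryGraph:
    """Random connected labeled graph (spanning tree plus random extra edges)."""
    labels = [f"A{k:02d}" for k in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for k in range(1, n_nodes):
        j = order[rng.integers(0, k)]
        edges.append((labels[order[k]], labels[j]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < extra_edge_prob:
                edges.append((labels[i], labels[j]))
    return CountryGraph(labels, edges)
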