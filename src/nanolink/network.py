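"""Bonded nanostar network: graph construction, branching and interpenetration.

The bonded network is the object every structural and topological analysis
consumes: nodes are nanostars (positioned at their central bead), edges are
hybridized arm pairs. Because the box is periodic, each edge carries an
integer image-shift vector recording through which box face the bond passes;
summing shifts around a cycle yields that cycle's winding vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import VALENCE, Configuration, PeriodicBox


@dataclass
class NetworkGraph:
    """Arm-resolved bond graph of a nanostar configuration.

    graph : networkx.MultiGraph with node attributes ``pos`` (wrapped centre)
        and ``type``; edge attributes ``arms`` = (arm_u, arm_v) and
        ``shift`` = integer image shift oriented from attribute ``u`` to the
        other endpoint.
    """

    graph: nx.MultiGraph
    box: PeriodicBox

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node: int) -> np.ndarray:
        return self.graph.nodes[node]["pos"]

    def edge_shift(self, u: int, v: int, key: int = 0) -> np.ndarray:
        """Image shift for traversing the edge from u to v."""
        data = self.graph.edges[u, v, key]
        shift = data["shift"]
        return shift if data["u"] == u else -shift

    def step_vector(self, u: int, v: int, key: int = 0) -> np.ndarray:
        """Real-space displacement from u to the bonded image of v."""
        return (
            self.position(v)
            + self.edge_shift(u, v, key) * self.box.lengths
            - self.position(u)
        )

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()])


def build_bond_graph(config: Configuration, bonds) -> NetworkGraph:
    """Assemble the NetworkGraph from a configuration and its BondList.

    The image shift of each bond is determined by the minimum-image
    displacement between the two nanostar centres, i.e. a bond always joins
    nearest periodic images (bonds are short compared to the box).
    """
    g = nx.MultiGraph()
    n = config.n_nanostars
    centers = config.box.wrap(config.positions)
    for i in range(n):
        g.add_node(i, pos=centers[i], type=int(config.types[i]))
    L = config.box.lengths
    for (i, arm_i), (j, arm_j) in bonds:
        if i >= n or j >= n:
            raise ValueError(f"bond references missing nanostar ({i}, {j})")
        raw = centers[j] - centers[i]
        d = config.box.minimum_image(raw)
        shift = np.rint((d - raw) / L).astype(np.int64)
        g.add_edge(i, j, arms=(arm_i, arm_j), shift=shift, u=i)
    degrees = [d for _, d in g.degree()]
    if degrees and max(degrees) > VALENCE:
        raise ValueError(f"node degree exceeds valence f = {VALENCE}")
    return NetworkGraph(graph=g, box=config.box)


def branch_statistics(net: NetworkGraph) -> dict:
    """Degree histogram and fraction of branching points (degree-3 nodes)."""
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    degrees = net.degrees()
    hist = np.bincount(degrees, minlength=VALENCE + 1)
    fractions = hist / net.n_nodes
    return {
        "degree_histogram": hist,
        "degree_fractions": fractions,
        "branching_fraction": float(fractions[VALENCE]),
        "n_branching": int(hist[VALENCE]),
    }


@dataclass
class InterpenetrationReport:
    """Spherical-neighbourhood probe results.

    Each probe draws a sphere, takes the nanostars inside it, induces the
    bond subgraph on them and counts connected components (small components
    below ``min_component`` nodes are ignored). Two or more components in
    one neighbourhood signal interpenetrating networks.
    """

    centers: np.ndarray
    radius: float
    n_inside: np.ndarray
    n_components: np.ndarray
    included: np.ndarray  # probes with enough retained nodes to be informative
    min_component: int

    @property
    def fraction_multi(self) -> float:
        """Fraction of informative probes seeing >= 2 disjoint subnetworks."""
        if not np.any(self.included):
            return float("nan")
        return float(np.mean(self.n_components[self.included] >= 2))


def probe_interpenetration(
    config: Configuration,
    net: NetworkGraph,
    radius: float,
    n_probes: int = 200,
    min_component: int = 3,
    seed: int = 0,
) -> InterpenetrationReport:
    """Randomly probe spherical neighbourhoods for disjoint subnetworks.

    Probes whose sphere retains fewer than ``2 * min_component`` nodes after
    dropping small components are excluded from the summary fraction: they
    cannot distinguish one network from two.
    """
    box = config.box
    if radius >= box.min_edge / 2:
        raise ValueError(
            f"probe radius {radius} must be below half the smallest box edge"
        )
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, 1.0, size=(n_probes, 3)) * box.lengths
    positions = np.array([net.position(i) for i in sorted(net.graph.nodes)])
    nodes = np.array(sorted(net.graph.nodes))
    n_inside = np.zeros(n_probes, dtype=int)
    n_components = np.zeros(n_probes, dtype=int)
    included = np.zeros(n_probes, dtype=bool)
    for p in range(n_probes):
        d = box.minimum_image(positions - centers[p])
        mask = np.einsum("ij,ij->i", d, d) <= radius * radius
        inside = nodes[mask]
        n_inside[p] = len(inside)
        if len(inside) == 0:
            continue
        sub = net.graph.subgraph(inside)
        comps = [c for c in nx.connected_components(sub) if len(c) >= min_component]
        n_components[p] = len(comps)
        retained = sum(len(c) for c in comps)
        included[p] = retained >= 2 * min_component
    return InterpenetrationReport(
        centers=centers,
        radius=radius,
        n_inside=n_inside,
        n_components=n_components,
        included=included,
        min_component=min_component,
    )


def export_edge_list(net: NetworkGraph, path) -> None:
    """Write the bond graph as an edge-list CSV (i, j, shift_x, shift_y, shift_z)."""
    import pandas as pd

    rows = []
    for u, v, data in net.graph.edges(data=True):
        shift = data["shift"] if data["u"] == u else -data["shift"]
        rows.append((u, v, int(shift[0]), int(shift[1]), int(shift[2])))
    pd.DataFrame(rows, columns=["i", "j", "shift_x", "shift_y", "shift_z"]).to_csv(
        path, index=False
    )


def export_graphml(net: NetworkGraph, path) -> None:
    """Write the bond graph as GraphML (positions and shifts stringified)."""
    g = nx.MultiGraph()
    for node, data in net.graph.nodes(data=True):
        g.add_node(node, x=float(data["pos"][0]), y=float(data["pos"][1]),
                   z=float(data["pos"][2]), type=int(data["type"]))
    for u, v, data in net.graph.edges(data=True):
        shift = data["shift"] if data["u"] == u else -data["shift"]
        g.add_edge(u, v, shift=",".join(str(int(s)) for s in shift))
    nx.write_graphml(g, path)
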