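"""Subnetworks of significant edges: components, centrality, hub nodes.

The edges surviving the edge-wise contrast form a sparse undirected graph
("difference graph").  Its connected components are the subnetworks the
analysis reports.  Within each subnetwork, eigenvector centrality of the
binary adjacency ranks node importance, and hubs are the nodes whose
centrality exceeds the subnetwork mean by more than one (sample) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .contrast import ContrastResult


@dataclass
class DifferenceGraph:
    """Sparse graph of group-difference edges for one modality."""

    modality: str
    edges: list[tuple[int, int]]  # (i, j), i < j, 1-based node ids
    direction: dict[tuple[int, int], int] = field(default_factory=dict)
    r_effect: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) in difference graph")

    @property
    def nodes(self) -> set[int]:
        return {n for e in self.edges for n in e}

    @classmethod
    def from_contrast(cls, contrast: ContrastResult, which: str = "significant") -> "DifferenceGraph":
        """Build from a contrast's ``significant`` or ``candidate`` edge set."""
        mask = contrast.significant if which == "significant" else contrast.candidate_mask
        edges, direction, r_effect = [], {}, {}
        for k in np.flatnonzero(mask):
            e = (int(contrast.edge_i[k]), int(contrast.edge_j[k]))
            edges.append(e)
            direction[e] = int(contrast.direction[k])
            r_effect[e] = float(contrast.r_effect[k])
        return cls(modality=contrast.modality, edges=edges, direction=direction, r_effect=r_effect)


@dataclass
class Subnetwork:
    """One connected component of a difference graph."""

    nodes: tuple[int, ...]  # sorted ascending
    edges: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Binary adjacency in the order of ``self.nodes``."""
        idx = {n: k for k, n in enumerate(self.nodes)}
        a = np.zeros((self.size, self.size))
        for i, j in self.edges:
            a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1.0
        return a


def connected_components(graph: DifferenceGraph) -> list[Subnetwork]:
    """Connected components, sorted by node count desc, then edge count desc,
    then smallest member node id asc — so "the largest subnetwork" is
    well-defined even under ties."""
    g = nx.Graph()
    g.add_edges_from(graph.edges)
    subnets = []
    for comp in nx.connected_components(g):
        nodes = tuple(sorted(comp))
        edges = tuple(sorted((min(i, j), max(i, j)) for i, j in g.subgraph(comp).edges))
        subnets.append(Subnetwork(nodes=nodes, edges=edges))
    subnets.sort(key=lambda s: (-s.size, -s.edge_count, s.nodes[0]))
    return subnets


def eigenvector_centrality(
    subnet: Subnetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[int, float]:
    """Leading eigenvector of the binary adjacency, Euclidean norm 1.

    Power iteration from the uniform vector on A + I; the identity shift
    damps the period-2 oscillation a bipartite component would otherwise
    produce while leaving the eigenvectors unchanged.  All entries are
    non-negative (Perron-Frobenius, the component is connected).
    """
    if subnet.size < 2:
        raise ValueError("eigenvector centrality needs at least 2 nodes")
    a = subnet.adjacency() + np.eye(subnet.size)
    v = np.full(subnet.size, 1.0 / np.sqrt(subnet.size))
    for _ in range(max_iter):
        w = a @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} steps")
    v = np.abs(v)  # sign convention; entries are non-negative up to round-off
    v /= np.linalg.norm(v)
    return {n: float(c) for n, c in zip(subnet.nodes, v)}


def find_hubs(centralities: dict[int, float]) -> set[int]:
    """Hub nodes: centrality strictly greater than mean + 1 sample SD of the
    subnetwork's centrality distribution.  Empty when all values are equal."""
    if len(centralities) < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    vals = np.array(list(centralities.values()))
    cutoff = vals.mean() + vals.std(ddof=1)
    return {n for n, c in centralities.items() if c > cutoff}


def node_degree(subnet: Subnetwork, node: int) -> int:
    """Number of member edges incident to ``node``."""
    if node not in subnet.nodes:
        raise ValueError(f"node {node} is not a member of the subnetwork")
    return sum(1 for i, j in subnet.edges if node in (i, j))


@dataclass
class CentralityReport:
    """Centrality, degree and hub flags for one subnetwork."""

    subnet: Subnetwork
    centrality: dict[int, float]
    degree: dict[int, int]
    hubs: set[int]

    def to_dataframe(self) -> pd.DataFrame:
        nodes = list(self.subnet.nodes)
        return pd.DataFrame(
            {
                "node_id": nodes,
                "degree": [self.degree[n] for n in nodes],
                "centrality": [self.centrality[n] for n in nodes],
                "is_hub": [n in self.hubs for n in nodes],
            }
        )


def analyse_subnetworks(graph: DifferenceGraph) -> list[CentralityReport]:
    """Components plus centrality/degree/hub reports, in the sort order."""
    reports = []
    for subnet in connected_components(graph):
        cent = eigenvector_centrality(subnet)
        reports.append(
            CentralityReport(
                subnet=subnet,
                centrality=cent,
                degree={n: node_degree(subnet, n) for n in subnet.nodes},
                hubs=find_hubs(cent),
            )
        )
    return reports
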