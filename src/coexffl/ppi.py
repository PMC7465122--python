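"""Scored protein-interaction network and MCODE dense-cluster detection.

MCODE is re-implemented from the seed-and-expand description: vertices are
weighted by the density of the highest k-core of their closed neighborhood
times that core number; clusters grow outward from the highest-weight unused
seed, admitting neighbors whose weight stays within ``node_score_cutoff`` of
the seed weight; the haircut step prunes singly-connected vertices. A
cluster's score is its density times its vertex count,
score = (2E / (n(n-1))) * n. The fluff stage is not implemented (the
configured cut style is haircut).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be non-negative")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.fluff:
            raise NotImplementedError("fluff stage not implemented; use haircut")


def load_edges(path: str | Path, score_threshold: float = 0.9) -> nx.Graph:
    """Load a STRING-style TSV and keep edges with score strictly above threshold.

    Scores on the 0-1000 scale are auto-detected (max > 1) and divided by
    1000. The resulting graph is simple: self-loops dropped, duplicate edges
    collapsed keeping the highest score.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need two node columns and a score column")
    df = df.iloc[:, :3].copy()
    df.columns = ["a", "b", "score"]
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if df["score"].max() > 1.0:
        df["score"] = df["score"] / 1000.0
    return graph_from_frame(df, score_threshold)


def graph_from_frame(df: pd.DataFrame, score_threshold: float = 0.9) -> nx.Graph:
    """Build the simple thresholded graph from (a, b, score) rows."""
    g = nx.Graph()
    for a, b, s in df.itertuples(index=False):
        a, b = str(a), str(b)
        if a == b:
            continue
        s = float(s)
        if s > score_threshold:
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
    if g.number_of_edges() == 0:
        raise ValueError("no edges above the score threshold")
    return g


def cluster_score(n_nodes: int, n_edges: int) -> float:
    """Density times node count: (2E / (n(n-1))) * n."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1)) * n_nodes


def mcode_vertex_weights(graph: nx.Graph, params: MCODEParams | None = None) -> dict[str, float]:
    """Bader–Hogue vertex weights.

    weight(v) = (highest core number of the closed neighborhood of v) times
    (edge density of that highest k-core). Vertices with degree below
    ``degree_cutoff`` weigh 0.
    """
    params = params or MCODEParams()
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(list(graph.neighbors(v)) + [v])
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        core_nodes = [u for u, c in core.items() if c == kmax]
        core_sub = nbhd.subgraph(core_nodes)
        n = core_sub.number_of_nodes()
        density = (
            2.0 * core_sub.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        )
        weights[v] = kmax * density
    return weights


@dataclass
class Cluster:
    nodes: list[str]
    n_edges: int
    density: float
    score: float
    seed: str

    @property
    def node_set(self) -> set[str]:
        return set(self.nodes)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def top(self) -> Cluster | None:
        return self.clusters[0] if self.clusters else None


def _haircut(graph: nx.Graph, nodes: set[str]) -> set[str]:
    """Iteratively drop vertices with fewer than 2 connections in the cluster."""
    nodes = set(nodes)
    while True:
        sub = graph.subgraph(nodes)
        drop = {v for v in nodes if sub.degree(v) < 2}
        if not drop:
            return nodes
        nodes -= drop


def mcode_find_clusters(graph: nx.Graph, params: MCODEParams | None = None) -> ClusterResult:
    """Seeded breadth-first complex detection with haircut post-processing.

    Seeds are tried in decreasing weight order (node name breaks ties, so the
    output is deterministic); expansion admits unassigned neighbors whose
    weight is at least ``seed_weight * (1 - node_score_cutoff)``, up to
    ``max_depth`` hops. Vertices join at most one emitted cluster; clusters
    with fewer than 3 vertices after haircut are discarded. Clusters are
    ranked by score, then node count, then lexicographically smallest member.
    """
    params = params or MCODEParams()
    weights = mcode_vertex_weights(graph, params)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set[str] = set()
    clusters: list[Cluster] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        floor = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = deque([(seed, 0)])
        while frontier:
            v, depth = frontier.popleft()
            if depth >= params.max_depth:
                continue
            for u in graph.neighbors(v):
                if u in members or u in assigned:
                    continue
                if weights[u] >= floor:
                    members.add(u)
                    frontier.append((u, depth + 1))
        if params.haircut:
            members = _haircut(graph, members)
        if len(members) < 3:
            continue
        sub = graph.subgraph(members)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        clusters.append(
            Cluster(
                nodes=sorted(members),
                n_edges=e,
                density=2.0 * e / (n * (n - 1)),
                score=cluster_score(n, e),
                seed=seed,
            )
        )
        assigned |= members
    clusters.sort(key=lambda c: (-c.score, -len(c.nodes), min(c.nodes)))
    return ClusterResult(clusters=clusters, weights=weights)


def write_clusters(result: ClusterResult, path: str | Path) -> None:
    rows = []
    for rank, c in enumerate(result.clusters, start=1):
        for node in c.nodes:
            rows.append((rank, round(c.score, 3), len(c.nodes), c.n_edges, node))
    pd.DataFrame(rows, columns=["cluster", "score", "n_nodes", "n_edges", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_top_cluster_graphml(graph: nx.Graph, result: ClusterResult, path: str | Path) -> None:
    if result.top is None:
        raise ValueError("no cluster to export")
    nx.write_graphml(graph.subgraph(result.top.nodes), path)
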