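"""miRNA–TF–gene feed-forward-loop network assembly and motif extraction.

Regulatory edge tables (miRNA→gene, TF→gene, miRNA→TF) are filtered on the
database thresholds — miRNA target edges need a score strictly above 0.95 and
a 3'UTR binding region; TF edges need a binding p-value strictly below 0.001 —
then restricted by a two-tier screen: regulators must appear on a tier-1
literature list, and miRNAs must additionally be conserved in mouse (appear in
mouse target tables filtered with the same thresholds). Surviving edges merge
into a simple typed digraph; a closed 3-node FFL is a triple with edges
miRNA→TF, TF→gene and miRNA→gene, FFLs sharing a miRNA and gene merge into
composite instances, and the highest-order motif maximizes the summed
merged-network degree of its constituent nodes.

Species prefixes (hsa-/mmu-) are stripped and names lower-cased before
cross-species matching.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger("coexffl.ffl")

EDGE_TYPES = ("miRNA-gene", "TF-gene", "miRNA-TF")

MIRNA_SCORE_THRESHOLD = 0.95
TF_P_THRESHOLD = 0.001


def normalize_region(region: str) -> str:
    """Canonicalize a binding-region label ("3'UTR", "3′UTR", "3utr" -> "3UTR")."""
    return re.sub(r"[^0-9A-Z]", "", str(region).upper())


def normalize_name(name: str) -> str:
    """Species-agnostic regulator name: strip hsa-/mmu- prefixes, lower-case."""
    return re.sub(r"^(hsa|mmu)-", "", str(name).strip(), flags=re.IGNORECASE).lower()


def _role_of_source(etype: str) -> str:
    return "miRNA" if etype.startswith("miRNA") else "TF"


def _role_of_target(etype: str) -> str:
    return "TF" if etype.endswith("TF") else "gene"


def filter_edges(
    tables: list[pd.DataFrame],
    mirna_score: float = MIRNA_SCORE_THRESHOLD,
    tf_p: float = TF_P_THRESHOLD,
) -> pd.DataFrame:
    """Apply the per-type database thresholds and collapse duplicates."""
    frames = []
    for df in tables:
        if df.empty:
            continue
        unknown = set(df["type"]) - set(EDGE_TYPES)
        if unknown:
            raise ValueError(f"unknown edge type(s): {sorted(unknown)}")
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["source", "target", "type"])
    combined = pd.concat(frames, ignore_index=True)
    is_mirna = combined["type"].str.startswith("miRNA")
    region_ok = combined.get("binding_region", pd.Series("", index=combined.index)).map(normalize_region) == "3UTR"
    score = pd.to_numeric(combined.get("score"), errors="coerce")
    pval = pd.to_numeric(combined.get("p_value"), errors="coerce")
    keep = (is_mirna & (score > mirna_score) & region_ok) | (~is_mirna & (pval < tf_p))
    out = combined[keep.fillna(False)].drop_duplicates(subset=["source", "target", "type"])
    return out.reset_index(drop=True)


def two_tier_screen(
    edges: pd.DataFrame,
    tier1: list[str],
    mouse_tables: list[pd.DataFrame],
    mirna_score: float = MIRNA_SCORE_THRESHOLD,
    tf_p: float = TF_P_THRESHOLD,
    conserve_targets: str = "all",
) -> pd.DataFrame:
    """Restrict edges to tier-1 regulators with mouse-conserved miRNAs.

    The tier-2 miRNA set is the tier-1 miRNAs that also appear, after
    applying the same thresholds, in the mouse target tables (miRNA→gene
    only when ``conserve_targets="genes"``, both miRNA tables when
    ``"all"``). TFs pass on tier-1 membership alone.
    """
    if conserve_targets not in ("genes", "all"):
        raise ValueError("conserve_targets must be 'genes' or 'all'")
    if not tier1:
        warnings.warn("empty tier-1 list: all edges dropped", UserWarning, stacklevel=2)
        return edges.iloc[0:0]
    tier1_norm = {normalize_name(x) for x in tier1}
    mouse = filter_edges(mouse_tables, mirna_score=mirna_score, tf_p=tf_p)
    if conserve_targets == "genes" and len(mouse):
        mouse = mouse[mouse["type"] == "miRNA-gene"]
    mouse_mirnas = {
        normalize_name(s) for s, t in zip(mouse.get("source", []), mouse.get("type", []))
        if str(t).startswith("miRNA")
    }
    tier2_mirnas = tier1_norm & mouse_mirnas

    def regulator_ok(row) -> bool:
        src = normalize_name(row["source"])
        if _role_of_source(row["type"]) == "miRNA":
            return src in tier2_mirnas
        return src in tier1_norm

    keep = edges.apply(regulator_ok, axis=1) if len(edges) else pd.Series(dtype=bool)
    return edges[keep].reset_index(drop=True)


@dataclass
class FFLNetwork:
    graph: nx.DiGraph  # nodes carry role=, edges carry type=

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def roles(self) -> dict[str, str]:
        return nx.get_node_attributes(self.graph, "role")

    def degree(self, node: str) -> int:
        return self.graph.in_degree(node) + self.graph.out_degree(node)

    def edge_type_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(EDGE_TYPES, 0)
        for _, _, t in self.graph.edges.data("type"):
            counts[t] += 1
        return counts

    def summary_table(self) -> pd.DataFrame:
        """Per-relationship edge and node counts (one row per edge type)."""
        roles = self.roles
        rows = []
        for etype in EDGE_TYPES:
            sub = [(u, v) for u, v, t in self.graph.edges.data("type") if t == etype]
            mirnas = {u for u, _ in sub if roles[u] == "miRNA"}
            tfs = {n for e in sub for n in e if roles[n] == "TF"}
            genes = {v for _, v in sub if roles[v] == "gene"}
            rows.append((etype, len(sub), len(mirnas), len(genes), len(tfs)))
        return pd.DataFrame(rows, columns=["relationship", "n_edges", "n_mirnas", "n_genes", "n_tfs"])


def assemble_network(edges: pd.DataFrame) -> FFLNetwork:
    """Merge screened typed edges into a simple directed network."""
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        etype = row.type
        src, tgt = str(row.source), str(row.target)
        g.add_node(src, role=_role_of_source(etype))
        g.add_node(tgt, role=_role_of_target(etype))
        g.add_edge(src, tgt, type=etype)
    return FFLNetwork(graph=g)


@dataclass
class MotifInstance:
    mirna: str
    tfs: tuple[str, ...]
    gene: str
    order: int  # summed merged-network degree of constituent nodes
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.mirna,) + self.tfs + (self.gene,)


def enumerate_ffls(network: FFLNetwork) -> list[tuple[str, str, str]]:
    """All closed (miRNA, TF, gene) triples with the three defining edges."""
    g = network.graph
    roles = network.roles
    triples = []
    for m, tf, d in g.edges(data=True):
        if d["type"] != "miRNA-TF":
            continue
        for _, gene, d2 in g.out_edges(tf, data=True):
            if d2["type"] != "TF-gene":
                continue
            if g.has_edge(m, gene) and g[m][gene]["type"] == "miRNA-gene":
                assert roles[m] == "miRNA" and roles[tf] == "TF" and roles[gene] == "gene"
                triples.append((m, tf, gene))
    return sorted(triples)


def highest_order_motif(network: FFLNetwork) -> MotifInstance | None:
    """Composite FFL instance maximizing the summed node degree.

    Closed triples sharing the same miRNA and gene merge into one composite
    instance (1 miRNA, >=1 TF, 1 gene). Ties break toward more TFs, then
    lexicographic node names. Returns None when no closed FFL exists.
    """
    triples = enumerate_ffls(network)
    if not triples:
        log.info("no closed 3-node FFL in the network")
        return None
    grouped: dict[tuple[str, str], set[str]] = {}
    for m, tf, gene in triples:
        grouped.setdefault((m, gene), set()).add(tf)
    instances = []
    for (m, gene), tfs in grouped.items():
        tfs_sorted = tuple(sorted(tfs))
        order = network.degree(m) + network.degree(gene) + sum(network.degree(t) for t in tfs_sorted)
        edges = [(m, gene, "miRNA-gene")]
        for t in tfs_sorted:
            edges += [(m, t, "miRNA-TF"), (t, gene, "TF-gene")]
        instances.append(MotifInstance(mirna=m, tfs=tfs_sorted, gene=gene, order=order, edges=edges))
    instances.sort(key=lambda i: (-i.order, -len(i.tfs), i.mirna, i.gene))
    return instances[0]


def write_sif(network: FFLNetwork, path: str | Path) -> None:
    lines = [f"{u}\t{d['type']}\t{v}" for u, v, d in network.graph.edges(data=True)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(network: FFLNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)
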