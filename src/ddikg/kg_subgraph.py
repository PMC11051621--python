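"""Typed biomedical knowledge graph and enclosing-subgraph extraction.

A drug pair's *enclosing subgraph* is the induced subgraph on the nodes that
lie within ``k`` hops of **both** drugs (plus the two drugs themselves), with
every member labelled by its pair of shortest-path distances to the two drugs
("double-radius" labelling).  These labels, one-hot encoded and concatenated
onto a per-node embedding, form the initial node states consumed by the
relational graph network in :mod:`ddikg.graph_net`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .autodiff import xavier_uniform

logger = logging.getLogger(__name__)

#: distance value recorded when a retained endpoint cannot reach the other drug
UNREACHED = -1


@dataclass
class KnowledgeGraph:
    """Typed nodes and typed directed edges with a relation vocabulary."""

    node_types: dict[str, str]
    edges: list[tuple[str, str, str]]          # (head, relation, tail)
    relations: list[str]
    node_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {n: i for i, n in enumerate(sorted(self.node_types))}

    @property
    def nodes(self) -> list[str]:
        return list(self.node_index)

    def undirected_view(self) -> nx.Graph:
        """Simple undirected graph over the same nodes (for BFS distances)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_index)
        g.add_edges_from((h, t) for h, _, t in self.edges)
        return g

    def random_node_embeddings(self, dim: int = 75, seed: int = 0,
                               gain: float = 2.0) -> dict[str, np.ndarray]:
        """Xavier-uniform node embeddings, deterministic in node order and seed."""
        rng = np.random.default_rng(seed)
        mat = xavier_uniform(rng, (len(self.node_index), dim), gain=gain)
        return {n: mat[i] for n, i in self.node_index.items()}


@dataclass
class EnclosingSubgraph:
    """k-hop intersection neighbourhood of a drug pair with distance labels."""

    u: str
    v: str
    k: int
    members: list[str]                          # sorted by (dist_u, dist_v, id)
    induced_edges: list[tuple[str, str, str]]
    dist_u: dict[str, int]
    dist_v: dict[str, int]
    labels: np.ndarray | None = None            # (n, 2(k+1)) one-hot pairs
    init_states: np.ndarray | None = None       # (n, graph_dim + 2(k+1))

    @property
    def member_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.members)}

    def distance_labels(self) -> np.ndarray:
        """Concatenated one-hot pair [one-hot(d(i,u)) ; one-hot(d(i,v))].

        Distances are clamped to [0, k]; the unreached sentinel (possible only
        for the always-retained endpoints) maps to the outermost bucket k.
        """
        n, width = len(self.members), self.k + 1
        out = np.zeros((n, 2 * width))
        for i, m in enumerate(self.members):
            for block, dist in enumerate((self.dist_u[m], self.dist_v[m])):
                d = self.k if dist == UNREACHED else min(max(dist, 0), self.k)
                out[i, block * width + d] = 1.0
        return out


def load_knowledge_graph(path_or_records) -> KnowledgeGraph:
    """Load a typed edge list: TSV columns (head, head_type, relation, tail, tail_type).

    Lines beginning with ``#`` are comments.  Nodes and edges are deduplicated;
    node ordering is lexicographic so the node index is reproducible.
    """
    import os

    if isinstance(path_or_records, (str, bytes, os.PathLike)) \
            or hasattr(path_or_records, "read"):
        df = pd.read_csv(path_or_records, sep="\t", header=None, comment="#",
                         dtype=str, keep_default_na=False)
    else:
        df = pd.DataFrame(list(path_or_records), dtype=str)
    if df.shape[1] != 5:
        raise ValueError(f"expected 5 columns (head, head_type, relation, tail, "
                         f"tail_type), got {df.shape[1]}")
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        if any(str(x).strip() == "" for x in row):
            raise ValueError(f"malformed row {rownum}: empty field in {tuple(row)}")

    node_types: dict[str, str] = {}
    for rownum, (h, ht, _, t, tt) in enumerate(df.itertuples(index=False), start=1):
        for ident, typ in ((h, ht), (t, tt)):
            prev = node_types.setdefault(ident, typ)
            if prev != typ:
                raise ValueError(f"conflicting types for node {ident!r}: "
                                 f"{prev!r} vs {typ!r} (row {rownum})")

    edges = sorted({(h, r, t) for h, _, r, t, _ in df.itertuples(index=False)})
    relations = sorted({r for _, r, _ in edges})
    kg = KnowledgeGraph(node_types=node_types, edges=edges, relations=relations)
    logger.info("loaded KG: %d nodes, %d edges, %d relations",
                len(kg.node_index), len(edges), len(relations))
    return kg


def _bounded_bfs_distances(g: nx.Graph, source: str, cutoff: int) -> dict[str, int]:
    return nx.single_source_shortest_path_length(g, source, cutoff=cutoff)


def extract_enclosing_subgraph(kg: KnowledgeGraph, u: str, v: str,
                               k: int) -> EnclosingSubgraph:
    """Members are ``(N_k(u) ∩ N_k(v)) ∪ {u, v}`` on the undirected view of the KG.

    The two endpoints are always retained even when one cannot reach the other
    within k hops, since the pair representation needs both embeddings.
    """
    for node in (u, v):
        if node not in kg.node_index:
            raise KeyError(f"drug {node!r} is not a node of the knowledge graph")
    if u == v:
        raise ValueError(f"degenerate pair: u == v == {u!r}")
    if k < 1:
        raise ValueError(f"hop count must be >= 1, got {k}")

    g = kg.undirected_view()
    du = _bounded_bfs_distances(g, u, cutoff=k)
    dv = _bounded_bfs_distances(g, v, cutoff=k)
    members = (set(du) & set(dv)) | {u, v}

    dist_u = {m: du.get(m, UNREACHED) for m in members}
    dist_v = {m: dv.get(m, UNREACHED) for m in members}
    ordered = sorted(members, key=lambda m: (dist_u[m], dist_v[m], m))
    induced = [(h, r, t) for h, r, t in kg.edges if h in members and t in members]
    return EnclosingSubgraph(u=u, v=v, k=k, members=ordered,
                             induced_edges=induced, dist_u=dist_u, dist_v=dist_v)


def label_nodes(sub: EnclosingSubgraph,
                node_embeddings: Mapping[str, np.ndarray]) -> EnclosingSubgraph:
    """Attach initial node states: per-node embedding ⊕ double-radius one-hots."""
    dims = set()
    for m in sub.members:
        if m not in node_embeddings:
            raise KeyError(f"no embedding for subgraph member {m!r}")
        dims.add(len(np.asarray(node_embeddings[m]).ravel()))
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding lengths: {sorted(dims)}")
    sub.labels = sub.distance_labels()
    emb = np.stack([np.asarray(node_embeddings[m], dtype=float).ravel()
                    for m in sub.members])
    sub.init_states = np.concatenate([emb, sub.labels], axis=1)
    return sub
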