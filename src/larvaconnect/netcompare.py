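"""Community detection on connectivity networks and agreement with
genetic clusters.

Communities come from the walktrap algorithm (Pons & Latapy): short
random walks of length t define node profiles P^t_i.; communities are
merged agglomeratively, always picking the adjacent pair whose merge
least increases the mean squared walk-profile distance (a Ward-style
criterion), and the dendrogram level with maximum modularity is returned.
Agreement between a dispersal partition and a genetic partition is scored
with the adjusted Rand index and normalised mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "CommunityPartition",
    "AgreementResult",
    "build_graph",
    "partition_modularity",
    "walktrap_communities",
    "partition_agreement",
    "site_partition_from_individuals",
]


@dataclass
class CommunityPartition:
    """Node -> community labelling; labels are contiguous integers from 0."""

    nodes: list
    labels: np.ndarray
    method: str = "walktrap"
    score: float | None = None  # modularity for graph partitions

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.nodes),):
            raise ValueError("one label per node required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must be contiguous integers from 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.nodes, name="community")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class AgreementResult:
    ari: float
    nmi: float
    contingency: pd.DataFrame


def build_graph(C: ConnectivityMatrix, min_count: int = 1, symmetrise: bool = True):
    """Weighted graph from a connectivity matrix.

    Undirected edges carry counts[i][j] + counts[j][i] (walktrap is defined
    on undirected graphs); edges below ``min_count`` are dropped;
    self-recruitment (diagonal) never becomes an edge; isolated nodes are
    retained."""
    ids = C.site_ids
    M = C.counts
    G = nx.Graph() if symmetrise else nx.DiGraph()
    G.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        rng_j = range(i + 1, n) if symmetrise else range(n)
        for j in rng_j:
            if i == j:
                continue
            w = int(M[i, j] + M[j, i]) if symmetrise else int(M[i, j])
            if w >= min_count and w > 0:
                G.add_edge(ids[i], ids[j], weight=w)
    return G


def partition_modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a labelling over adjacency ``W``
    (diagonal ignored)."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    deg = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        q += W[np.ix_(members, members)].sum() / two_m - (deg[members].sum() / two_m) ** 2
    return float(q)


def _relabel_contiguous(raw: np.ndarray) -> np.ndarray:
    """Map labels to 0..k-1 in order of first appearance."""
    order: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in order:
            order[v] = len(order)
        out[i] = order[v]
    return out


def walktrap_communities(graph: nx.Graph, steps: int = 4, n_communities: int | None = None) -> CommunityPartition:
    """Walktrap partition of an undirected weighted graph.

    Deterministic given the graph: merge ties break on the smallest
    (node id, node id) pair.  By default the modularity-maximising level of
    the merge dendrogram is returned; ``n_communities`` instead cuts the
    dendrogram at a fixed community count (for comparison with a known
    genetic K).  Zero-degree nodes each form their own community.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(W, 0.0)
    if (W < 0).any():
        raise ValueError("negative edge weights")
    deg = W.sum(axis=1)
    act = np.flatnonzero(deg > 0)
    if act.size == 0:
        return CommunityPartition(nodes, np.arange(n), score=0.0)

    Wa = W[np.ix_(act, act)]
    da = Wa.sum(axis=1)
    P = Wa / da[:, None]
    Pt = np.linalg.matrix_power(P, steps)
    inv_d = 1.0 / da
    m = act.size

    comms: list[dict] = [
        {"members": [int(g)], "size": 1, "vec": Pt[i].copy(), "min_node": int(g)}
        for i, g in enumerate(act)
    ]
    adj = Wa > 0

    def current_labels() -> np.ndarray:
        raw = np.full(n, -1, dtype=int)
        nxt = 0
        for comm in comms:
            for g in comm["members"]:
                raw[g] = nxt
            nxt += 1
        for i in range(n):
            if raw[i] == -1:
                raw[i] = nxt
                nxt += 1
        return _relabel_contiguous(raw)

    levels = [current_labels()]
    while len(comms) > 1 and adj.any():
        sizes = np.array([c["size"] for c in comms], dtype=float)
        V = np.stack([c["vec"] for c in comms])
        S = (V**2) @ inv_d
        cross = V @ (V * inv_d).T
        dist2 = np.maximum(S[:, None] + S[None, :] - 2 * cross, 0.0)
        factor = sizes[:, None] * sizes[None, :] / (sizes[:, None] + sizes[None, :])
        ds = factor * dist2 / m
        cand = np.triu(adj, k=1)
        if not cand.any():
            break
        ds_masked = np.where(cand, ds, np.inf)
        best = ds_masked.min()
        ii, jj = np.nonzero(cand & (ds_masked <= best * (1 + 1e-12) + 1e-300))
        # deterministic tie-break: smallest (min node id, min node id) pair
        key = [
            tuple(sorted((comms[i]["min_node"], comms[j]["min_node"])))
            for i, j in zip(ii, jj)
        ]
        pick = int(np.lexsort(([k[1] for k in key], [k[0] for k in key]))[0])
        i, j = int(ii[pick]), int(jj[pick])

        ci, cj = comms[i], comms[j]
        merged = {
            "members": ci["members"] + cj["members"],
            "size": ci["size"] + cj["size"],
            "vec": (ci["size"] * ci["vec"] + cj["size"] * cj["vec"]) / (ci["size"] + cj["size"]),
            "min_node": min(ci["min_node"], cj["min_node"]),
        }
        adj[i] = adj[i] | adj[j]
        adj[:, i] = adj[:, i] | adj[:, j]
        adj[i, i] = False
        keep = [k for k in range(len(comms)) if k != j]
        adj = adj[np.ix_(keep, keep)]
        comms[i] = merged
        comms.pop(j)
        levels.append(current_labels())

    mods = [partition_modularity(W, lab) for lab in levels]
    if n_communities is not None:
        sizes = [int(lab.max()) + 1 for lab in levels]
        if n_communities not in sizes:
            raise ValueError(f"no dendrogram level with {n_communities} communities (have {sorted(set(sizes))})")
        idx = sizes.index(n_communities)
    else:
        idx = int(np.argmax(mods))
    return CommunityPartition(nodes, levels[idx], score=mods[idx])


def partition_agreement(P1: CommunityPartition, P2: CommunityPartition) -> AgreementResult:
    """Adjusted Rand index, NMI (arithmetic normalisation) and the label
    co-occurrence table between two partitions of the same node set."""
    if list(P1.nodes) != list(P2.nodes):
        if set(P1.nodes) != set(P2.nodes):
            raise ValueError("partitions cover different node sets")
        order = {nd: i for i, nd in enumerate(P1.nodes)}
        idx = np.array([order[nd] for nd in P2.nodes])
        l2 = np.empty_like(P2.labels)
        l2[idx] = P2.labels
    else:
        l2 = P2.labels
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    ari = float(adjusted_rand_score(P1.labels, l2))
    nmi = float(normalized_mutual_info_score(P1.labels, l2, average_method="arithmetic"))
    table = pd.crosstab(
        pd.Series(P1.labels, name=P1.method), pd.Series(l2, name=P2.method)
    )
    return AgreementResult(ari, nmi, table)


def site_partition_from_individuals(individual_labels: pd.Series, sites: pd.Series, site_order) -> CommunityPartition:
    """Project per-individual cluster labels to sites by majority vote
    (ties resolved toward the smallest cluster label)."""
    site_order = list(site_order)
    raw = np.empty(len(site_order), dtype=int)
    for i, s in enumerate(site_order):
        labs = individual_labels[sites.to_numpy() == s]
        if len(labs) == 0:
            raise ValueError(f"no individuals for site {s!r}")
        counts = pd.Series(labs).value_counts()
        top = counts[counts == counts.max()].index.min()
        raw[i] = int(top)
    return CommunityPartition(site_order, _relabel_contiguous(raw), method="admixture-argmax")
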