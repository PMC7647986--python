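"""Nodal graph metrics of weighted structural connectomes.

Six per-node metrics characterise hubness in the patch-level network
G = (V, E) with adjacency a_ij and weights w_ij:

* degree        d_i = sum_j a_ij
* strength      s_i = sum_j a_ij w_ij
* betweenness   b_i = sum_{s!=i!=t} sigma_st^i / sigma_st, unnormalised,
                with shortest paths measured on edge lengths 1 / w_ij
* efficiency    e_i = sum_{j,h in N_i, j!=h}
                (w_ij w_ih [p_jh(N_i)]^-1)^{1/3} / (d_i (d_i - 1)),
                where p_jh(N_i) is the shortest-path length between j and
                h through neighbours of i only (weighted local efficiency)
* clustering    c_i = 2 / (d_i (d_i - 1)) *
                sum_{j<k} (w~_ij w~_jk w~_ki)^{1/3} with weights scaled by
                the network maximum (Onnela)
* participation p_i = 1 - sum_m (d_i(m) / d_i)^2 over modules m of a
                modularity partition (resolution gamma, default 1)

Conventions for degenerate nodes: d_i < 2 gives c_i = e_i = 0 and
d_i = 0 gives p_i = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .connectome import WeightedNetwork
from .parcellation import CLASS_NAMES, PatchLabels

__all__ = ["ModulePartition", "degree", "strength", "betweenness",
           "local_efficiency", "clustering", "partition_modules",
           "participation", "compute_all_metrics", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["degree", "strength", "betweenness", "efficiency",
                  "clustering", "participation"]


@dataclass
class ModulePartition:
    """Modularity-maximising node partition at resolution gamma."""

    module_id: np.ndarray
    gamma: float
    modularity: float
    seed: int

    @property
    def n_modules(self) -> int:
        return int(self.module_id.max()) + 1 if self.module_id.size else 0


def degree(net: WeightedNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1).astype(np.int64)


def strength(net: WeightedNetwork) -> np.ndarray:
    return net.weights.sum(axis=1)


def _length_graph(net: WeightedNetwork, binarized: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    w = net.weights
    for i, j in zip(*np.nonzero(np.triu(w, k=1))):
        g.add_edge(int(i), int(j),
                   length=1.0 if binarized else 1.0 / w[i, j])
    return g


def betweenness(net: WeightedNetwork, binarized: bool = False) -> np.ndarray:
    """Unnormalised shortest-path betweenness over unordered node pairs."""
    if np.any(net.weights < 0):
        raise ValueError("negative weights")
    g = _length_graph(net, binarized)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)])


def local_efficiency(net: WeightedNetwork) -> np.ndarray:
    """Weighted local efficiency with neighbourhood-restricted paths.

    For each node i the shortest path p_jh(N_i) between neighbours j and h
    runs through the subgraph induced on N_i (i itself excluded), with
    edge lengths 1 / w.  Ordered neighbour pairs with no connecting path
    contribute 0.
    """
    w = net.weights
    n = net.n_nodes
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        d_i = len(nbrs)
        if d_i < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        lengths = np.zeros_like(sub)
        nz = sub > 0
        lengths[nz] = 1.0 / sub[nz]
        sp = csgraph.dijkstra(csr_matrix(lengths), directed=False)
        with np.errstate(divide="ignore"):
            inv_sp = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
        wi = w[i, nbrs]
        terms = np.cbrt(wi[:, None] * wi[None, :] * inv_sp)
        np.fill_diagonal(terms, 0.0)
        eff[i] = terms.sum() / (d_i * (d_i - 1))
    return eff


def clustering(net: WeightedNetwork) -> np.ndarray:
    """Onnela weighted clustering coefficient on max-scaled weights."""
    w_scaled = net.scaled_weights  # raises on all-zero weights
    c = np.cbrt(w_scaled)
    tri = np.diagonal(c @ c @ c).copy()  # counts ordered pairs (j, k)
    d = degree(net).astype(float)
    denom = d * (d - 1)
    out = np.zeros(net.n_nodes)
    mask = denom > 0
    out[mask] = tri[mask] / denom[mask]
    return out


def partition_modules(net: WeightedNetwork, gamma: float = 1.0,
                      seed: int = 0) -> ModulePartition:
    """Louvain modularity maximisation at resolution gamma.

    Module count is determined automatically by the optimiser; output is
    deterministic for a given seed, with module ids relabelled by their
    lowest member index.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if net.n_nodes == 0 or net.weights.max() == 0:
        raise ValueError("cannot partition an empty graph")
    g = nx.from_numpy_array(net.weights)
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=gamma, seed=seed)
    comms = sorted(comms, key=min)
    module_id = np.empty(net.n_nodes, dtype=np.int64)
    for m, nodes in enumerate(comms):
        for v in nodes:
            module_id[v] = m
    q = nx.community.modularity(g, comms, weight="weight",
                                resolution=gamma)
    return ModulePartition(module_id=module_id, gamma=gamma,
                           modularity=float(q), seed=seed)


def participation(net: WeightedNetwork,
                  partition: ModulePartition) -> np.ndarray:
    """p_i = 1 - sum_m (d_i(m) / d_i)^2 with binary connection counts."""
    if len(partition.module_id) != net.n_nodes:
        raise ValueError("partition does not cover all nodes")
    a = net.adjacency
    d = a.sum(axis=1)
    n_mod = partition.n_modules
    onehot = np.zeros((net.n_nodes, n_mod))
    onehot[np.arange(net.n_nodes), partition.module_id] = 1.0
    d_im = a @ onehot
    out = np.zeros(net.n_nodes)
    mask = d > 0
    out[mask] = 1.0 - ((d_im[mask] / d[mask, None]) ** 2).sum(axis=1)
    return out


def compute_all_metrics(net: WeightedNetwork, gamma: float = 1.0,
                        seed: int = 0, subject_id: str | int = 0,
                        labels: PatchLabels | None = None) -> pd.DataFrame:
    """All six nodal metrics plus module ids as a tidy per-node table."""
    labels = labels if labels is not None else net.labels
    part = partition_modules(net, gamma=gamma, seed=seed)
    df = pd.DataFrame({
        "subject_id": subject_id,
        "node": np.arange(net.n_nodes),
        "degree": degree(net),
        "strength": strength(net),
        "betweenness": betweenness(net),
        "efficiency": local_efficiency(net),
        "clustering": clustering(net),
        "participation": participation(net, part),
        "module_id": part.module_id,
    })
    if labels is not None:
        df["class"] = [CLASS_NAMES[int(c)] for c in labels.classes]
    return df
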