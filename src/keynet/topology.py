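"""Per-condition network construction and the seven topology criteria.

The report mirrors the standard Cytoscape network-analyzer panel: node and
edge counts, mean neighbors (2E/N), characteristic path length (mean
unweighted shortest-path length over connected unordered pairs),
clustering coefficient (mean local clustering over all nodes, nodes of
degree < 2 contributing 0), network heterogeneity (coefficient of
variation of the degree distribution, population sd) and Freeman degree
centralization.

Degrees are unweighted edge counts throughout; combined scores never
enter topology metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .datatypes import GeneList, WeightedNetwork

logger = logging.getLogger("keynet")

__all__ = [
    "TopologyReport",
    "build_condition_network",
    "topology_report",
    "node_degrees",
]


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    mean_neighbors: float
    char_path_length: float
    clustering_coefficient: float
    heterogeneity: float
    centralization: float

    def as_dict(self) -> dict:
        return asdict(self)


def build_condition_network(gene_list: GeneList, edges: WeightedNetwork) -> WeightedNetwork:
    """Induce the condition's PPI network from a gene list and an edge table.

    Takes the subgraph of ``edges`` on the list's symbols, then drops nodes
    left without any edge (the network of connected proteins). The dropped
    count is logged. Raises if the list shares no node with the edge table.
    """
    common = gene_list.as_set() & edges.nodes()
    if not common:
        raise ValueError(
            f"gene list {gene_list.label!r} shares no symbol with the edge table"
        )
    sub = edges.subgraph(common)
    isolated = [n for n in sub.nodes() if sub.degree(n) == 0]
    if isolated:
        logger.info(
            "condition %s: dropped %d unconnected proteins",
            gene_list.label or "?",
            len(isolated),
        )
        sub.g.remove_nodes_from(isolated)
    logger.info(
        "condition %s: %d/%d list symbols retained in network",
        gene_list.label or "?",
        sub.n_nodes,
        len(gene_list),
    )
    if sub.n_nodes == 0:
        raise ValueError(f"condition {gene_list.label!r}: no connected proteins remain")
    return sub


def node_degrees(net: WeightedNetwork) -> dict[str, int]:
    """Unweighted degree (number of incident edges) for every node."""
    return {n: int(d) for n, d in net.g.degree()}


# ---------------------------------------------------------------------------
# array kernels — shared with the permutation-null machinery, which calls
# them on raw edge arrays thousands of times
# ---------------------------------------------------------------------------

def _adjacency(n: int, edges: np.ndarray) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.float64)
    if len(edges):
        a[edges[:, 0], edges[:, 1]] = 1.0
        a[edges[:, 1], edges[:, 0]] = 1.0
    return a


def _char_path_length(adj: np.ndarray) -> float:
    """Mean BFS shortest-path length over connected unordered pairs.

    Disconnected pairs are excluded; NaN when no connected pair exists.
    """
    n = adj.shape[0]
    if n < 2:
        return math.nan
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = d[np.isfinite(d) & (d > 0)]
    if finite.size == 0:
        return math.nan
    return float(finite.mean())


def _local_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node local clustering; 0 for degree < 2."""
    deg = adj.sum(axis=1)
    # diag(A^3) counts 2x the triangles through each node
    tri = ((adj @ adj) * adj).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def _clustering_coefficient(adj: np.ndarray) -> float:
    return float(_local_clustering(adj).mean())


def _heterogeneity(deg: np.ndarray) -> float:
    mean = deg.mean()
    if mean == 0:
        return 0.0
    return float(deg.std() / mean)  # population sd


def _centralization(deg: np.ndarray) -> float:
    n = deg.size
    if n < 3:
        return 0.0
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def _node_index(net: WeightedNetwork) -> tuple[list[str], np.ndarray]:
    nodes = sorted(net.nodes())
    pos = {n: i for i, n in enumerate(nodes)}
    edges = np.array(
        [[pos[u], pos[v]] for u, v, _ in net.edges()], dtype=np.int64
    ).reshape(-1, 2)
    return nodes, edges


def topology_report(net: WeightedNetwork) -> TopologyReport:
    """Compute the seven topology criteria for one network."""
    n = net.n_nodes
    if n == 0:
        raise ValueError("topology_report: empty network")
    _, edges = _node_index(net)
    e = len(edges)
    adj = _adjacency(n, edges)
    deg = adj.sum(axis=1)
    if n == 1:
        logger.warning("topology_report: single-node graph, path length undefined")
    cpl = _char_path_length(adj)
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        mean_neighbors=2.0 * e / n,
        char_path_length=cpl,
        clustering_coefficient=_clustering_coefficient(adj) if n else math.nan,
        heterogeneity=_heterogeneity(deg),
        centralization=_centralization(deg),
    )


def node_mean_distances(net: WeightedNetwork) -> dict[str, float]:
    """Per-node mean shortest-path distance to the nodes it can reach."""
    nodes, edges = _node_index(net)
    adj = _adjacency(len(nodes), edges)
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    out: dict[str, float] = {}
    for i, name in enumerate(nodes):
        d = dist[i]
        reach = d[np.isfinite(d) & (d > 0)]
        out[name] = float(reach.mean()) if reach.size else math.nan
    return out


def local_clustering_values(net: WeightedNetwork) -> dict[str, float]:
    """Per-node local clustering coefficient (0 for degree < 2)."""
    nodes, edges = _node_index(net)
    c = _local_clustering(_adjacency(len(nodes), edges))
    return {name: float(c[i]) for i, name in enumerate(nodes)}
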