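"""Degree-preserving permutation nulls and between-network effect sizes.

The null model is the Maslov-Sneppen double-edge swap: repeatedly pick two
edges (a,b), (c,d) and rewire to (a,d), (c,b), rejecting proposals that
would create a self-loop or a duplicate edge. The degree sequence is
invariant by construction. Combined scores travel with their original edge
slot through the relabeling (the null statistics never read them).

Empirical significance uses the add-one permutation p-value
``(1 + #extreme) / (1 + n)``; "extreme" is two-sided, measured as absolute
deviation from the null mean at least as large as the observed deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import WeightedNetwork
from .topology import (
    _adjacency,
    _char_path_length,
    _clustering_coefficient,
    _node_index,
    local_clustering_values,
    node_mean_distances,
)

logger = logging.getLogger("keynet")

__all__ = [
    "PermutationResult",
    "EffectSizeResult",
    "rewire_preserving_degrees",
    "permutation_pvalue",
    "compare_networks_effect",
    "cohens_d",
]

_STATISTICS = {
    "char_path_length": _char_path_length,
    "clustering_coefficient": _clustering_coefficient,
}

_NODE_STATISTICS = {
    "node_mean_distance": node_mean_distances,
    "local_clustering": local_clustering_values,
}


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float
    null_values: tuple[float, ...]
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class EffectSizeResult:
    statistic_name: str
    d: float
    p_value: float
    group_sizes: tuple[int, int]


def _rewire_edge_array(
    edges: np.ndarray, attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Attempt ``attempts`` double-edge swaps on an (E, 2) int array.

    Returns the rewired array (same slots, scores stay aligned by index)
    and the number of accepted swaps.
    """
    e = len(edges)
    if e < 2:
        return edges.copy(), 0
    slots: list[tuple[int, int]] = [tuple(x) for x in edges.tolist()]
    edge_set = {(u, v) if u < v else (v, u) for u, v in slots}
    picks_i = rng.integers(0, e, size=attempts).tolist()
    picks_j = rng.integers(0, e, size=attempts).tolist()
    flips = rng.integers(0, 2, size=attempts).tolist()
    accepted = 0
    for i, j, flip in zip(picks_i, picks_j, flips):
        if i == j:
            continue
        a, b = slots[i]
        c, d = slots[j]
        if flip:
            c, d = d, c
        # proposed: (a, d), (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((a, b) if a < b else (b, a))
        edge_set.discard((c, d) if c < d else (d, c))
        slots[i] = (a, d)
        slots[j] = (c, b)
        edge_set.add(e1)
        edge_set.add(e2)
        accepted += 1
    return np.array(slots, dtype=np.int64), accepted


def rewire_preserving_degrees(
    net: WeightedNetwork, swap_factor: float = 10.0, seed: int = 0
) -> WeightedNetwork:
    """Return a degree-preserving randomization of ``net``.

    Performs ``ceil(swap_factor * E)`` attempted double-edge swaps. When the
    graph admits no valid swap (e.g. a triangle) the result is isomorphic to
    the input and the accepted-swap counter is 0. The returned network
    carries the counter as attribute ``n_accepted_swaps``.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if swap_factor <= 0:
        raise ValueError("swap_factor must be positive")
    nodes, edges = _node_index(net)
    scores = np.array([s for _, _, s in net.edges()], dtype=np.int64)
    rng = np.random.default_rng(seed)
    attempts = math.ceil(swap_factor * len(edges))
    rewired, accepted = _rewire_edge_array(edges, attempts, rng)
    if accepted == 0:
        logger.warning("rewiring: 0 accepted swaps (graph may admit none)")
    result = WeightedNetwork.from_edges(
        ((nodes[u], nodes[v], int(s)) for (u, v), s in zip(rewired, scores)),
        nodes=nodes,
    )
    result.n_accepted_swaps = accepted  # type: ignore[attr-defined]
    return result


def permutation_pvalue(
    net: WeightedNetwork,
    statistic: str = "clustering_coefficient",
    n: int = 1000,
    seed: int = 0,
    swap_factor: float = 10.0,
) -> PermutationResult:
    """Two-sided permutation p-value of a topology statistic vs. its null.

    The null is built from ``n`` independent rewirings of the observed
    network, each with ``swap_factor * E`` attempted swaps. Deterministic
    given ``seed``.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if n < 19:
        raise ValueError("need at least 19 permutations for a meaningful p-value")
    stat_fn = _STATISTICS[statistic]
    nodes, edges = _node_index(net)
    n_nodes = len(nodes)
    observed = stat_fn(_adjacency(n_nodes, edges))
    if not math.isfinite(observed):
        raise ValueError(f"statistic {statistic!r} undefined on this network")
    attempts = math.ceil(swap_factor * len(edges))
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    null = np.empty(n)
    for k in range(n):
        rng = np.random.default_rng(child_seeds[k])
        rewired, _ = _rewire_edge_array(edges, attempts, rng)
        null[k] = stat_fn(_adjacency(n_nodes, rewired))
    center = null.mean()
    extreme = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    p = (1 + extreme) / (1 + n)
    return PermutationResult(
        statistic_name=statistic,
        observed=float(observed),
        null_values=tuple(float(x) for x in null),
        p_value=float(p),
        n_permutations=n,
        seed=seed,
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled (n-1 weighted) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("cohens_d needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    diff = a.mean() - b.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / pooled)


def compare_networks_effect(
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    statistic: str = "local_clustering",
) -> EffectSizeResult:
    """Effect size between two networks on node-level distributions.

    ``statistic`` selects per-node mean shortest-path distance or per-node
    local clustering; groups are the two networks' node-value samples.
    Returns Cohen's d (pooled sd) and an unequal-variance t-test p-value.
    """
    if statistic not in _NODE_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(_NODE_STATISTICS)}"
        )
    fn = _NODE_STATISTICS[statistic]
    a = np.array([v for v in fn(net_a).values() if math.isfinite(v)])
    b = np.array([v for v in fn(net_b).values() if math.isfinite(v)])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both networks need at least 2 nodes with defined values")
    d = cohens_d(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return EffectSizeResult(
        statistic_name=statistic, d=d, p_value=p, group_sizes=(len(a), len(b))
    )
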