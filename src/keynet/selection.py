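"""Quantile-class analysis and HDP/HSIP key-protein selection.

The selection procedure ranks nodes by unweighted degree, keeps the top-k
high-degree proteins (HDPs, k = 3 by default), and attaches each HDP's
high-score interaction proteins (HSIPs): neighbors whose connecting edge's
combined score strictly exceeds the network-wide 90th-percentile score.
The union of HDPs and HSIPs is the network's key-protein set.

The quantile-class analysis bins degree and combined-score values into
five classes cut at the 20/40/60/80/100th percentiles; class 0.2 holds the
top 20% of values. Class-level means of degree vs. score, pooled across
networks, feed a Pearson correlation describing how tightly edge
confidence tracks hub status.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import WeightedNetwork
from .topology import node_degrees

logger = logging.getLogger("keynet")

__all__ = [
    "ClassSummary",
    "QuantileClassTable",
    "HDPRecord",
    "HSIPRecord",
    "KeyProteinSet",
    "quantile_class_table",
    "network_class_tables",
    "degree_class_score_points",
    "class_level_correlation",
    "select_hdps",
    "cs_percentile_threshold",
    "select_hsips",
    "assemble_key_proteins",
    "key_proteins",
]

CLASS_LABELS = (1.0, 0.8, 0.6, 0.4, 0.2)  # 0.2 = highest 20%


@dataclass(frozen=True)
class ClassSummary:
    class_label: float
    value_range: tuple[float, float]  # (lower cut, upper cut], lower = -inf for class 1.0
    member_count: int
    mean_value: float  # NaN when empty


@dataclass(frozen=True)
class QuantileClassTable:
    variable: str
    classes: tuple[ClassSummary, ...]
    cut_points: tuple[float, ...]  # 20/40/60/80/100th percentile values

    def class_summary(self, label: float) -> ClassSummary:
        for c in self.classes:
            if c.class_label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class HDPRecord:
    symbol: str
    degree: int


@dataclass(frozen=True)
class HSIPRecord:
    hub: str
    partner: str
    combined_score: int


@dataclass(frozen=True)
class KeyProteinSet:
    """Top-k HDPs plus their HSIPs, with the score threshold used.

    ``unique_members`` is the de-duplicated union of hub and partner
    symbols; a partner appearing under several hubs counts once.
    """

    condition_label: str
    hdps: tuple[HDPRecord, ...]
    hsips: tuple[HSIPRecord, ...]
    cs_threshold: int

    @property
    def unique_members(self) -> frozenset[str]:
        members = {h.symbol for h in self.hdps}
        members.update(r.partner for r in self.hsips)
        return frozenset(members)


def quantile_class_table(values, variable: str = "degree") -> QuantileClassTable:
    """Bin values into five quantile classes (class 0.2 = top 20%).

    Cut points use linear-interpolation percentiles. A value is assigned to
    the highest class whose lower cut it strictly exceeds; values equal to
    a cut point fall to the lower-valued class.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 5:
        raise ValueError("quantile classes need at least 5 values")
    cuts = np.percentile(vals, [20, 40, 60, 80, 100])
    if cuts[0] == cuts[-1]:
        logger.warning("quantile_class_table: all values identical; one occupied class")
    # lower cut per class, top class first: 0.2 > 80th pct, ..., 1.0 > -inf
    lowers = [cuts[3], cuts[2], cuts[1], cuts[0], -math.inf]
    uppers = [cuts[4], cuts[3], cuts[2], cuts[1], cuts[0]]
    labels_desc = (0.2, 0.4, 0.6, 0.8, 1.0)
    classes = []
    for label, lo, hi in zip(labels_desc, lowers, uppers):
        members = vals[(vals > lo) & (vals <= hi)]
        classes.append(
            ClassSummary(
                class_label=label,
                value_range=(float(lo), float(hi)),
                member_count=int(members.size),
                mean_value=float(members.mean()) if members.size else math.nan,
            )
        )
    # present in ascending label order (1.0 first) to mirror the frequency plot
    classes = tuple(sorted(classes, key=lambda c: -c.class_label))
    assert sum(c.member_count for c in classes) == vals.size
    return QuantileClassTable(
        variable=variable, classes=classes, cut_points=tuple(float(c) for c in cuts)
    )


def network_class_tables(net: WeightedNetwork) -> tuple[QuantileClassTable, QuantileClassTable]:
    """Degree-class and combined-score-class tables for one network."""
    degrees = list(node_degrees(net).values())
    scores = net.edge_scores()
    return (
        quantile_class_table(degrees, variable="degree"),
        quantile_class_table(scores, variable="combined_score"),
    )


def degree_class_score_points(net: WeightedNetwork) -> list[tuple[float, float]]:
    """Class-level (mean degree, mean incident combined score) points.

    Nodes are binned by the degree quantile classes; for each occupied
    class the point is (mean degree of its nodes, mean combined score over
    the edges incident to those nodes, counted once per incidence). Up to
    five points per network.
    """
    deg = node_degrees(net)
    table = quantile_class_table(list(deg.values()), variable="degree")
    points: list[tuple[float, float]] = []
    for c in table.classes:
        lo, hi = c.value_range
        members = [n for n, d in deg.items() if lo < d <= hi]
        if not members:
            continue
        scores = [
            net.score(n, nb) for n in members for nb in net.neighbors(n)
        ]
        if not scores:
            continue
        mean_deg = float(np.mean([deg[n] for n in members]))
        points.append((mean_deg, float(np.mean(scores))))
    return points


def class_level_correlation(
    point_groups: list[list[tuple[float, float]]],
) -> tuple[float, float]:
    """Pearson r between class-mean degree and class-mean combined score.

    Pools the class-level points of each supplied network (5 classes x
    networks pairs, from :func:`degree_class_score_points`); p is the
    two-sided t-test with df = n_pairs - 2. Returns (nan, nan) when either
    variable has zero variance.
    """
    xs: list[float] = []
    ys: list[float] = []
    for points in point_groups:
        for dm, sm in points:
            if math.isfinite(dm) and math.isfinite(sm):
                xs.append(dm)
                ys.append(sm)
    if len(xs) < 3:
        raise ValueError("class-level correlation needs >= 3 paired points")
    x = np.array(xs)
    y = np.array(ys)
    if x.std() == 0 or y.std() == 0:
        logger.warning("class_level_correlation: zero variance; r undefined")
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def _incident_score_sum(net: WeightedNetwork, node: str) -> int:
    return sum(net.score(node, nb) for nb in net.neighbors(node))


def select_hdps(net: WeightedNetwork, k: int = 3) -> tuple[HDPRecord, ...]:
    """Top-k nodes by degree (the high-degree proteins).

    Ties at the k-th rank break by larger summed incident combined score,
    then lexicographic symbol order; the tie-break is logged.
    """
    if k > net.n_nodes:
        raise ValueError(f"k={k} exceeds node count {net.n_nodes}")
    deg = node_degrees(net)
    ranked = sorted(
        deg,
        key=lambda n: (-deg[n], -_incident_score_sum(net, n), n),
    )
    if len(ranked) > k and deg[ranked[k - 1]] == deg[ranked[k]]:
        logger.info(
            "select_hdps: degree tie at rank %d (degree %d) broken by incident "
            "score then symbol order",
            k,
            deg[ranked[k - 1]],
        )
    return tuple(HDPRecord(symbol=n, degree=deg[n]) for n in ranked[:k])


def cs_percentile_threshold(net: WeightedNetwork, percentile: float = 90.0) -> int:
    """Network-wide combined-score percentile, rounded to nearest integer.

    Linear interpolation between closest ranks (the numpy default).
    """
    scores = net.edge_scores()
    if not scores:
        raise ValueError("network has no edges")
    return int(round(float(np.percentile(scores, percentile))))


def select_hsips(
    net: WeightedNetwork, hdps: tuple[HDPRecord, ...], threshold: int
) -> tuple[HSIPRecord, ...]:
    """High-score interaction partners of each HDP (score strictly > threshold).

    A partner may appear under multiple hubs; records are ordered by hub
    rank then descending score then symbol.
    """
    records: list[HSIPRecord] = []
    for hub in hdps:
        partners = [
            HSIPRecord(hub=hub.symbol, partner=nb, combined_score=net.score(hub.symbol, nb))
            for nb in net.neighbors(hub.symbol)
            if net.score(hub.symbol, nb) > threshold
        ]
        partners.sort(key=lambda r: (-r.combined_score, r.partner))
        records.extend(partners)
    return tuple(records)


def assemble_key_proteins(
    condition: str,
    hdps: tuple[HDPRecord, ...],
    hsips: tuple[HSIPRecord, ...],
    cs_threshold: int,
) -> KeyProteinSet:
    """Bundle HDPs and HSIPs into a key-protein set.

    Scores are not re-checked against the threshold here: published tables
    entered as fixtures may include boundary scores, and strictness is the
    job of :func:`select_hsips` on the computation path.
    """
    hub_symbols = {h.symbol for h in hdps}
    for r in hsips:
        if r.hub not in hub_symbols:
            raise ValueError(f"HSIP record {r.partner!r} references unknown hub {r.hub!r}")
    return KeyProteinSet(
        condition_label=condition, hdps=hdps, hsips=hsips, cs_threshold=cs_threshold
    )


def key_proteins(
    net: WeightedNetwork,
    condition: str,
    k: int = 3,
    hsip_percentile: float = 90.0,
) -> KeyProteinSet:
    """Full selection pipeline on one network: HDPs, threshold, HSIPs."""
    hdps = select_hdps(net, k)
    threshold = cs_percentile_threshold(net, hsip_percentile)
    hsips = select_hsips(net, hdps, threshold)
    return assemble_key_proteins(condition, hdps, hsips, threshold)
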