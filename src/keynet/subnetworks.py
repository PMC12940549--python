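"""Focal-protein subnetwork extraction at score thresholds.

Given one or more focal proteins (e.g. the neurotrophin receptors NTRK1/3,
the serotonin transporter SLC6A4, or the glucocorticoid receptor NR3C1),
extract the partners whose connecting edge's combined score strictly
exceeds a threshold taken from the WHOLE network's edge-score distribution
(median, or an arbitrary percentile such as the 90th), and build the
induced subgraph on focal + partners. Partner-partner edges are retained
regardless of score: only membership is score-gated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import WeightedNetwork
from .overlap import OverlapResult, venn
from .selection import cs_percentile_threshold

__all__ = ["SubnetworkResult", "focal_partners", "shared_partner_venn"]


@dataclass(frozen=True)
class SubnetworkResult:
    focal_symbols: frozenset[str]
    threshold_mode: str  # "median" or "percentile"
    threshold_value: int
    members: dict[str, int]  # partner -> best qualifying score
    induced_network: WeightedNetwork
    member_degrees: dict[str, int]  # degrees within the induced network

    @property
    def member_symbols(self) -> frozenset[str]:
        return frozenset(self.members)


def focal_partners(
    net: WeightedNetwork,
    focal,
    mode: str = "median",
    percentile: float | None = None,
) -> SubnetworkResult:
    """Partners of the focal proteins over a strict score threshold.

    ``mode='median'`` cuts at the 50th percentile of all edge scores;
    ``mode='percentile'`` requires ``percentile``. Median mode equals
    percentile mode at 50 by construction.
    """
    focal_set = frozenset(focal)
    missing = focal_set - net.nodes()
    if missing:
        raise ValueError(f"focal symbols absent from network: {sorted(missing)}")
    if mode == "median":
        pct = 50.0
    elif mode == "percentile":
        if percentile is None:
            raise ValueError("percentile mode requires a percentile value")
        pct = float(percentile)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    threshold = cs_percentile_threshold(net, pct)
    members: dict[str, int] = {}
    for f in focal_set:
        for nb in net.neighbors(f):
            if nb in focal_set:
                continue
            s = net.score(f, nb)
            if s > threshold:
                members[nb] = max(s, members.get(nb, 0))
    induced = net.subgraph(focal_set | set(members))
    degrees = {n: induced.degree(n) for n in induced.nodes()}
    return SubnetworkResult(
        focal_symbols=focal_set,
        threshold_mode=mode,
        threshold_value=threshold,
        members=members,
        induced_network=induced,
        member_degrees=degrees,
    )


def shared_partner_venn(results, labels=None) -> OverlapResult:
    """Venn of the partner sets of 2-3 focal-subnetwork analyses."""
    results = list(results)
    if labels is None:
        labels = ["+".join(sorted(r.focal_symbols)) for r in results]
    return venn({l: r.member_symbols for l, r in zip(labels, results)})
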