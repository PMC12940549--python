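"""Multi-set (Venn) overlap analysis over gene lists and key-protein sets.

Regions are exclusive: the AS-and-Tin region contains symbols in both AS
and Tin but not NH, and so on. Region membership therefore partitions the
union of the input sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import GeneList

__all__ = ["OverlapResult", "venn", "pairwise_overlap_matrix"]


@dataclass(frozen=True)
class OverlapResult:
    set_labels: tuple[str, ...]
    regions: dict[frozenset[str], tuple[str, ...]]  # exclusive regions, sorted members
    union_size: int

    def region(self, *labels: str) -> tuple[str, ...]:
        """Members of the exclusive region belonging to exactly these labels."""
        return self.regions.get(frozenset(labels), ())

    def region_counts(self) -> dict[str, int]:
        """Region sizes keyed by '+'-joined sorted labels."""
        return {
            "+".join(sorted(k)): len(v) for k, v in self.regions.items()
        }

    def total_intersection(self, *labels: str) -> tuple[str, ...]:
        """Members in ALL of the given labels (inclusive of deeper overlaps)."""
        want = set(labels)
        out: list[str] = []
        for key, members in self.regions.items():
            if want <= key:
                out.extend(members)
        return tuple(sorted(out))


def _coerce_sets(sets) -> dict[str, frozenset[str]]:
    if isinstance(sets, Mapping):
        return {str(k): frozenset(v) for k, v in sets.items()}
    out: dict[str, frozenset[str]] = {}
    for item in sets:
        if isinstance(item, GeneList):
            out[item.label] = item.as_set()
        else:
            label, members = item
            out[str(label)] = frozenset(members)
    return out


def venn(sets) -> OverlapResult:
    """Exclusive Venn regions of 2-3 labelled symbol sets.

    ``sets`` is a mapping label -> symbols, an iterable of GeneLists, or an
    iterable of (label, symbols) pairs. Members within each region are
    sorted lexicographically. More than 3 sets raises (use
    :func:`pairwise_overlap_matrix` instead).
    """
    labelled = _coerce_sets(sets)
    if not 2 <= len(labelled) <= 3:
        raise ValueError(
            f"venn supports 2-3 sets, got {len(labelled)}; "
            "use pairwise_overlap_matrix for more"
        )
    for label, members in labelled.items():
        if not members:
            raise ValueError(f"set {label!r} is empty")
    labels = tuple(labelled)
    universe = frozenset().union(*labelled.values())
    regions: dict[frozenset[str], tuple[str, ...]] = {}
    for symbol_holder in _nonempty_subsets(labels):
        inside = frozenset.intersection(*(labelled[l] for l in symbol_holder))
        outside = frozenset().union(
            *(labelled[l] for l in labels if l not in symbol_holder), frozenset()
        )
        members = inside - outside
        regions[frozenset(symbol_holder)] = tuple(sorted(members))
    return OverlapResult(
        set_labels=labels, regions=regions, union_size=len(universe)
    )


def _nonempty_subsets(labels: tuple[str, ...]):
    n = len(labels)
    for mask in range(1, 2**n):
        yield tuple(labels[i] for i in range(n) if mask & (1 << i))


def pairwise_overlap_matrix(sets) -> pd.DataFrame:
    """Symmetric matrix of pairwise intersection counts; diagonal = set sizes."""
    labelled = _coerce_sets(sets)
    if len(labelled) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(labelled)
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            mat[i, j] = len(labelled[a] & labelled[b])
    return pd.DataFrame(mat, index=labels, columns=labels)
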