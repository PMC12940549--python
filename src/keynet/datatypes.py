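"""Shared domain types for condition-specific PPI network analysis.

The pipeline operates on three kinds of objects: condition-labelled gene
lists (e.g. from a disease-gene database export), weighted undirected
protein-protein interaction networks with STRING-style integer combined
scores on the 0-1000 scale, and gene-set annotation collections (GO-CC /
GO-BP membership in GMT form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "GeneList",
    "WeightedNetwork",
    "Term",
    "AnnotationSet",
    "AnalysisConfig",
    "InvalidSymbolError",
]


class InvalidSymbolError(ValueError):
    """Raised when a gene symbol is empty or unparseable."""


@dataclass(frozen=True)
class GeneList:
    """A condition label plus an ordered set of normalized gene symbols.

    ``scores`` optionally carries a nonnegative relevance value per symbol
    (GeneCards-style); when present it must align one-to-one with
    ``symbols``.
    """

    label: str
    symbols: tuple[str, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene list {self.label!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene list {self.label!r} has duplicate symbols")
        if self.scores is not None:
            if len(self.scores) != len(self.symbols):
                raise ValueError(
                    f"gene list {self.label!r}: {len(self.scores)} scores for "
                    f"{len(self.symbols)} symbols"
                )
            if any(s < 0 for s in self.scores):
                raise ValueError(f"gene list {self.label!r} has negative scores")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


class WeightedNetwork:
    """Simple undirected graph over gene symbols with integer combined scores.

    Invariants: no self-loops, no duplicate edges, every endpoint is a node,
    scores are integers in [0, 1000]. Backed by a :class:`networkx.Graph`
    whose edges carry a ``score`` attribute.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.g: nx.Graph = graph if graph is not None else nx.Graph()
        self._validate()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, s in edges:
            g.add_edge(u, v, score=int(s))
        return cls(g)

    def _validate(self) -> None:
        for u, v, data in self.g.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            s = data.get("score")
            if s is None or not (0 <= int(s) <= 1000):
                raise ValueError(f"edge ({u!r}, {v!r}) score {s!r} outside [0, 1000]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.g.nodes())

    def edges(self) -> list[tuple[str, str, int]]:
        """Edges as (u, v, score) with u < v, sorted; deterministic order."""
        out = [
            (min(u, v), max(u, v), int(d["score"]))
            for u, v, d in self.g.edges(data=True)
        ]
        return sorted(out)

    def score(self, u: str, v: str) -> int:
        return int(self.g.edges[u, v]["score"])

    def edge_scores(self) -> list[int]:
        return [int(d["score"]) for _, _, d in self.g.edges(data=True)]

    def neighbors(self, u: str) -> Iterator[str]:
        return self.g.neighbors(u)

    def degree(self, u: str) -> int:
        return int(self.g.degree(u))

    def subgraph(self, symbols: Iterable[str]) -> "WeightedNetwork":
        return WeightedNetwork(nx.Graph(self.g.subgraph(symbols)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes() == other.nodes() and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class Term:
    """One annotation term: id, human-readable name, CC/BP category, members."""

    term_id: str
    name: str
    category: str  # "CC" or "BP"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in ("CC", "BP"):
            raise ValueError(f"term {self.term_id!r}: category must be CC or BP")
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass(frozen=True)
class AnnotationSet:
    """A collection of annotation terms and the background they annotate."""

    terms: tuple[Term, ...]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for t in self.terms:
            extra = t.members - self.background
            if extra:
                raise ValueError(
                    f"term {t.term_id!r} members outside background: {sorted(extra)[:5]}"
                )

    def by_category(self, category: str) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if t.category == category)


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the key-protein pipeline.

    Defaults follow the study conditions: top-3 high-degree proteins, a
    90th-percentile combined-score cut for their high-score partners,
    quantile classes at the 20/40/60/80/100th percentiles, a 1000-rewiring
    permutation null, and Fisher p < 0.01 with BH q < 0.05 for enrichment.
    """

    hdp_count: int = 3
    hsip_percentile: float = 90.0
    class_probabilities: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0)
    permutations: int = 1000
    enrichment_p_threshold: float = 0.01
    enrichment_q_threshold: float = 0.05
    top_terms: int = 5
    seed: int = 0
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hdp_count < 1:
            raise ValueError("hdp_count must be positive")
        if not 0 < self.hsip_percentile < 100:
            raise ValueError("hsip_percentile must lie in (0, 100)")
        probs: Sequence[float] = self.class_probabilities
        if list(probs) != sorted(set(probs)) or probs[-1] != 100:
            raise ValueError("class_probabilities must be strictly ascending, ending at 100")
        if self.permutations < 1:
            raise ValueError("permutations must be positive")
        for name in ("enrichment_p_threshold", "enrichment_q_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.top_terms < 1:
            raise ValueError("top_terms must be positive")
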