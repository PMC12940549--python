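"""Readers and writers for the external formats the pipeline touches.

Gene lists arrive as plain text (one symbol per line) or two-column TSV
(symbol, relevance score). Interaction networks arrive as STRING-export
style TSV with ``node1 / node2 / combined_score`` columns, on either the
integer 0-1000 scale or the unit interval. Annotations arrive as GMT.
All tabular I/O is tab-separated UTF-8 with ``#`` comment lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import IO, Mapping

import networkx as nx
import pandas as pd

from .datatypes import (
    AnnotationSet,
    GeneList,
    InvalidSymbolError,
    Term,
    WeightedNetwork,
)

logger = logging.getLogger("keynet")

__all__ = [
    "normalize_symbol",
    "read_gene_list",
    "write_gene_list",
    "read_edge_table",
    "write_edge_table",
    "read_gmt",
    "write_gmt",
    "write_graphml",
    "write_node_edge_tables",
    "BUILTIN_ALIASES",
]

#: Built-in symbol aliases, applied after uppercasing. The published tables
#: mix ApoE/APOE (handled by uppercasing) and use PSEN for PSEN1.
BUILTIN_ALIASES: dict[str, str] = {"PSEN": "PSEN1"}


def normalize_symbol(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Trim, uppercase and alias-map a gene symbol. Idempotent.

    Raises :class:`InvalidSymbolError` on empty/whitespace-only input.
    """
    sym = raw.strip().upper()
    if not sym:
        raise InvalidSymbolError(f"invalid gene symbol: {raw!r}")
    table = dict(BUILTIN_ALIASES)
    if aliases:
        table.update({k.strip().upper(): v.strip().upper() for k, v in aliases.items()})
    return table.get(sym, sym)


def _open(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_gene_list(
    source: str | Path | IO[str],
    dialect: str = "plain",
    label: str = "",
    aliases: Mapping[str, str] | None = None,
) -> GeneList:
    """Read a condition gene list from plain text or 2-column TSV.

    Duplicate symbols (after normalization) are dropped keeping first
    occurrence; the duplicate count is logged.
    """
    if dialect not in ("plain", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fh, close = _open(source)
    try:
        symbols: list[str] = []
        scores: list[float] = []
        seen: set[str] = set()
        n_dupes = 0
        any_score = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "plain":
                raw, score = line, None
            else:
                parts = line.split("\t")
                raw = parts[0]
                score = None
                if len(parts) > 1 and parts[1].strip():
                    try:
                        score = float(parts[1])
                    except ValueError:
                        raise ValueError(
                            f"line {lineno}: non-numeric score {parts[1]!r}"
                        ) from None
            sym = normalize_symbol(raw, aliases)
            if sym in seen:
                n_dupes += 1
                continue
            seen.add(sym)
            symbols.append(sym)
            if score is not None:
                any_score = True
                scores.append(score)
            else:
                scores.append(float("nan"))
        if not symbols:
            raise ValueError("empty gene list")
        if n_dupes:
            logger.info("gene list %s: dropped %d duplicate symbols", label or "?", n_dupes)
        return GeneList(
            label=label,
            symbols=tuple(symbols),
            scores=tuple(scores) if any_score else None,
        )
    finally:
        if close:
            fh.close()


def write_gene_list(gene_list: GeneList, dest: str | Path | IO[str]) -> None:
    fh, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for i, sym in enumerate(gene_list.symbols):
            if gene_list.scores is not None:
                fh.write(f"{sym}\t{gene_list.scores[i]:g}\n")
            else:
                fh.write(sym + "\n")
    finally:
        if close:
            fh.close()


def read_edge_table(
    source: str | Path | IO[str],
    score_scale: str = "int1000",
    column_map: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> WeightedNetwork:
    """Read a weighted edge table (STRING protein-links dialect).

    ``score_scale='unit'`` declares scores in [0, 1]; they are multiplied by
    1000 and rounded to the nearest integer. Reversed duplicate pairs are
    merged keeping the maximum score; self-loops are dropped and counted.
    ``column_map`` renames nonstandard headers onto
    ``node1/node2/combined_score``.
    """
    if score_scale not in ("int1000", "unit"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"node1", "node2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")

    g = nx.Graph()
    n_self = 0
    for row in df.itertuples(index=False):
        raw1 = getattr(row, "node1")
        raw2 = getattr(row, "node2")
        raw_s = getattr(row, "combined_score")
        u = normalize_symbol(str(raw1), aliases)
        # a row with an empty partner declares an isolated node
        if raw2 is None or (isinstance(raw2, float) and pd.isna(raw2)) or not str(raw2).strip():
            g.add_node(u)
            continue
        v = normalize_symbol(str(raw2), aliases)
        s = float(raw_s)
        if score_scale == "unit":
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1] on unit scale")
            score = int(round(s * 1000))
        else:
            if s != int(s) or not 0 <= s <= 1000:
                raise ValueError(f"score {raw_s!r} outside integer [0, 1000]")
            score = int(s)
        if u == v:
            n_self += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            g.edges[u, v]["score"] = max(g.edges[u, v]["score"], score)
        else:
            g.add_edge(u, v, score=score)
    if n_self:
        logger.info("edge table: dropped %d self-loops", n_self)
    return WeightedNetwork(g)


def write_edge_table(net: WeightedNetwork, dest: str | Path | IO[str]) -> None:
    fh, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        fh.write("node1\tnode2\tcombined_score\n")
        written: set[str] = set()
        for u, v, s in net.edges():
            fh.write(f"{u}\t{v}\t{s}\n")
            written.update((u, v))
        for n in sorted(net.nodes() - written):  # isolated nodes
            fh.write(f"{n}\t\t\n")
    finally:
        if close:
            fh.close()


def read_gmt(
    source: str | Path | IO[str],
    aliases: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read a GMT gene-set file: term, description, members...

    The category is parsed from a ``CC|`` / ``BP|`` prefix of the
    description field; the default category is BP. The background is the
    union of all members.
    """
    fh, close = _open(source)
    try:
        terms: list[Term] = []
        background: set[str] = set()
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            term_id, desc = parts[0], parts[1]
            category = "BP"
            if desc.startswith("CC|"):
                category, desc = "CC", desc[3:]
            elif desc.startswith("BP|"):
                category, desc = "BP", desc[3:]
            members = frozenset(
                normalize_symbol(m, aliases) for m in parts[2:] if m.strip()
            )
            if not members:
                raise ValueError(f"GMT line {lineno}: term {term_id!r} has no members")
            background |= members
            terms.append(Term(term_id=term_id, name=desc or term_id, category=category, members=members))
        return AnnotationSet(terms=tuple(terms), background=frozenset(background))
    finally:
        if close:
            fh.close()


def write_gmt(annotations: AnnotationSet, dest: str | Path | IO[str]) -> None:
    fh, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for t in annotations.terms:
            members = "\t".join(sorted(t.members))
            fh.write(f"{t.term_id}\t{t.category}|{t.name}\t{members}\n")
    finally:
        if close:
            fh.close()


def write_graphml(net: WeightedNetwork, dest: str | Path) -> None:
    nx.write_graphml(net.g, dest)


def write_node_edge_tables(net: WeightedNetwork, node_path: str | Path, edge_path: str | Path) -> None:
    """Export a node table (symbol, degree) and an edge table (u, v, score)."""
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tdegree\n")
        for n in sorted(net.nodes()):
            fh.write(f"{n}\t{net.degree(n)}\n")
    write_edge_table(net, edge_path)


def dump_json(obj: object, dest: str | Path) -> None:
    """Write a deterministic JSON report (sorted keys, stable float repr)."""
    with open(dest, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
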