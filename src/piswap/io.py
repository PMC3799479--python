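"""Readers and writers for the on-disk formats.

Networks come as 2-column TSV edge lists or 3-column SIF; similarities as
3-column TSV (x, y, score); mappings as 2-column TSV.  All of these accept
``#`` comment lines.  Ontology/annotation parsing lives in
:mod:`piswap.ontology` and is re-exported here as :func:`read_go`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

from .errors import ParseError, ValidationError
from .model import Mapping, Network, SimilarityStore
from .ontology import read_go  # noqa: F401  (public re-export)

__all__ = [
    "LoadReport",
    "read_network",
    "write_network",
    "read_similarity",
    "write_similarity",
    "read_mapping",
    "write_mapping",
    "read_go",
]


@dataclass
class LoadReport:
    """What a reader skipped: self-loops, duplicate rows, etc."""

    self_loops_dropped: int = 0
    duplicate_rows: int = 0


def _data_lines(path: str | os.PathLike, comment: str = "#"):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def read_network(path: str | os.PathLike, fmt: str = "edgelist",
                 name: str = "") -> Network:
    """Read an undirected network from an edge list or SIF file.

    Self-loops are dropped (counted on ``Network.dropped_self_loops``) and
    duplicate / reversed edges deduplicated.  An empty file yields an empty
    network.
    """
    if fmt not in ("edgelist", "sif"):
        raise ValidationError(f"unknown network format {fmt!r}")
    net = Network(name=name or os.path.basename(os.fspath(path)))
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if fmt == "edgelist":
            if len(cols) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(cols)}",
                    path=os.fspath(path), line=lineno)
            u, v = cols
        else:
            if len(cols) != 3:
                raise ParseError(
                    f"expected 3 SIF columns (source, type, target), got {len(cols)}",
                    path=os.fspath(path), line=lineno)
            u, _, v = cols
        if not u or not v:
            raise ParseError("empty node identifier", path=os.fspath(path), line=lineno)
        net.add_edge(u, v)
    return net


def write_network(net: Network, path: str | os.PathLike) -> None:
    """Write the canonical sorted edge list; isolated nodes as self-referential
    comments are not emitted (the edge list format carries edges only)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in net.edge_list():
            fh.write(f"{u}\t{v}\n")


def read_similarity(path: str | os.PathLike) -> SimilarityStore:
    """Read a 3-column (x, y, score) similarity table.

    Zero scores are omitted, negative scores are a validation error, and
    duplicate (x, y) rows resolve to the maximum score.
    """
    store = SimilarityStore()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(
                f"expected 3 tab-separated columns, got {len(cols)}",
                path=os.fspath(path), line=lineno)
        x, y, raw = cols
        try:
            score = float(raw)
        except ValueError:
            raise ParseError(f"non-numeric score {raw!r}",
                             path=os.fspath(path), line=lineno) from None
        if score < 0:
            raise ValidationError(
                f"{os.fspath(path)}:{lineno}: negative score {score} for ({x}, {y})")
        if score == 0:
            continue
        prev = store._scores.get((x, y), 0.0)
        if score > prev:
            store.set(x, y, score)
    return store


def write_similarity(store: SimilarityStore, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for (x, y), v in sorted(store.items()):
            fh.write(f"{x}\t{y}\t{v:.10g}\n")


def read_mapping(path: str | os.PathLike) -> Mapping:
    """Read a 2-column (x, y) mapping; repeated x or y is an injectivity error."""
    m = Mapping()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(cols)}",
                path=os.fspath(path), line=lineno)
        x, y = cols
        if x in m.fwd:
            raise ValidationError(
                f"{os.fspath(path)}:{lineno}: x-identifier {x!r} repeated")
        if y in m.bwd:
            raise ValidationError(
                f"{os.fspath(path)}:{lineno}: y-identifier {y!r} repeated")
        m.add(x, y)
    return m


def write_mapping(m: Mapping, path: str | os.PathLike) -> None:
    """Write pairs sorted by x-identifier (round-trips with read_mapping)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for x, y in m.sorted_pairs():
            fh.write(f"{x}\t{y}\n")
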