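"""Gene Ontology structure and protein annotations.

The ontology is reduced to its ``is_a`` hierarchy ("the GO tree"): per-term
parent sets, the namespace roots, and each term's depth — the shortest
``is_a`` hop count from its root.  Annotations map protein identifiers to GO
term sets; annotations naming unknown (or obsolete) terms are dropped and
counted, since the functional-coherence metric can only use
terms whose ancestry is known.
"""

from __future__ import annotations

import os
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping as TMapping

import networkx as nx
import obonet

from .errors import ParseError, ValidationError

__all__ = ["GoDag", "GoAnnotations", "read_go", "read_obo", "read_annotations"]


class GoDag:
    """Acyclic ``is_a`` hierarchy with precomputed root distances."""

    def __init__(self, parents: TMapping[str, Iterable[str]]):
        self.parents: dict[str, set[str]] = {}
        terms: set[str] = set(parents)
        for t, ps in parents.items():
            ps = set(ps)
            terms |= ps
            self.parents[t] = ps
        for t in terms:
            self.parents.setdefault(t, set())
        self.terms: set[str] = terms
        self._check_acyclic()
        self.roots: set[str] = {t for t, ps in self.parents.items() if not ps}
        self.children: dict[str, set[str]] = {t: set() for t in terms}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        self.depth: dict[str, int] = self._depths()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("cyclic is_a structure in ontology")

    def _depths(self) -> dict[str, int]:
        depth = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            t = queue.popleft()
            for c in self.children[t]:
                if c not in depth:
                    depth[c] = depth[t] + 1
                    queue.append(c)
        return depth

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """Transitive ``is_a`` closure of a term."""
        if term not in self.terms:
            raise ValidationError(f"unknown GO term {term!r}")
        out: set[str] = {term} if include_self else set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        return out


@dataclass
class GoAnnotations:
    """Protein identifier -> set of GO terms, restricted to a GoDag."""

    terms_of: dict[str, set[str]] = field(default_factory=dict)
    dropped_terms: int = 0

    def add(self, protein: str, term: str, dag: GoDag) -> None:
        if term not in dag:
            self.dropped_terms += 1
            return
        self.terms_of.setdefault(protein, set()).add(term)

    def get(self, protein: str) -> set[str]:
        return self.terms_of.get(protein, set())


def read_obo(path: str | os.PathLike) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology, keeping only ``is_a`` edges.

    Obsolete terms are skipped (obonet default).
    """
    graph = obonet.read_obo(os.fspath(path), ignore_obsolete=True)
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return GoDag(parents)


def _read_gaf(path: str | os.PathLike, dag: GoDag) -> GoAnnotations:
    ann = GoAnnotations()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"GAF line has {len(cols)} columns, expected >= 5",
                                 path=os.fspath(path), line=lineno)
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            ann.add(cols[1], cols[4], dag)
    return ann


def _read_twocol(path: str | os.PathLike, dag: GoDag) -> GoAnnotations:
    ann = GoAnnotations()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"expected 2 tab-separated columns, got {len(cols)}",
                                 path=os.fspath(path), line=lineno)
            ann.add(cols[0], cols[1], dag)
    return ann


def read_annotations(path: str | os.PathLike, dag: GoDag,
                     fmt: str = "twocol") -> GoAnnotations:
    if fmt == "gaf":
        return _read_gaf(path, dag)
    if fmt == "twocol":
        return _read_twocol(path, dag)
    raise ValidationError(f"unknown annotation format {fmt!r}")


def read_go(obo_path: str | os.PathLike, annot_path: str | os.PathLike,
            annot_fmt: str = "twocol") -> tuple[GoDag, GoAnnotations]:
    """Load an ontology and a matching annotation table."""
    dag = read_obo(obo_path)
    ann = read_annotations(annot_path, dag, fmt=annot_fmt)
    return dag, ann
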