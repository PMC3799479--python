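"""Domain types and the alignment objective.

The alignment of two protein-interaction networks ``G_X`` and ``G_Y`` is an
injective partial mapping ``M`` between their vertex sets, viewed as a
matching in the complete bipartite graph on ``X x Y``.  Its quality is the
convex combination

    w(M) = alpha * sum_{e in M} t(e|M)  +  (1 - alpha) * sum_{e in M} s(e)

where ``s(x, y)`` is the (sequence-similarity) weight of the pair and
``t((x, y)|M)`` counts the interactions conserved around the pair: the
matched pairs ``(x', y')`` with ``x'`` adjacent to ``x`` and ``y'`` adjacent
to ``y``.  Each conserved edge is seen from both of its endpoints, so the
topology total equals twice the conserved-edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping as TMapping

import networkx as nx

from .errors import ContractViolation, InjectivityError, ValidationError

__all__ = [
    "Network",
    "SimilarityStore",
    "Mapping",
    "AlignmentInstance",
    "ObjectiveParams",
    "topology_similarity",
    "conserved_edge_count",
    "sequence_score",
    "total_topology",
    "objective",
]


class Network:
    """An undirected, simple PPI graph (no self-loops, no multi-edges)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = (), name: str = ""):
        self.name = name
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self._adj.setdefault(n, set())
        self.dropped_self_loops = 0
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, n: str) -> None:
        self._adj.setdefault(n, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            self.dropped_self_loops += 1
            self.add_node(u)
            return
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def neighbors(self, n: str) -> set[str]:
        return self._adj.get(n, set())

    def has_node(self, n: str) -> bool:
        return n in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, nbrs in self._adj.items()
                for v in nbrs if u < v}

    def edge_list(self) -> list[tuple[str, str]]:
        """Sorted canonical edge list (min endpoint first)."""
        return sorted((u, v) if u < v else (v, u)
                      for u, nbrs in self._adj.items() for v in nbrs if u < v)

    @property
    def node_count(self) -> int:
        return len(self._adj)

    @property
    def edge_count(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def degree(self, n: str) -> int:
        return len(self._adj.get(n, ()))

    @property
    def max_degree(self) -> int:
        return max((len(nbrs) for nbrs in self._adj.values()), default=0)

    def adjacency(self) -> TMapping[str, set[str]]:
        return self._adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edge_list())
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "") -> "Network":
        net = cls(name=name or str(g.name or ""))
        for n in g.nodes:
            net.add_node(str(n))
        for u, v in g.edges:
            net.add_edge(str(u), str(v))
        return net

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = f" {self.name!r}" if self.name else ""
        return f"<Network{label}: {self.node_count} nodes, {self.edge_count} edges>"


class SimilarityStore:
    """Sparse non-negative similarity scores between cross-network pairs.

    Absent pairs score 0; stored scores are strictly positive.  Lookup is
    symmetric: ``get(x, y) == get(y, x)``.
    """

    def __init__(self, scores: TMapping[tuple[str, str], float] | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        if scores:
            for (x, y), v in scores.items():
                self.set(x, y, v)

    def set(self, x: str, y: str, value: float) -> None:
        value = float(value)
        if value < 0:
            raise ValidationError(f"negative similarity score {value} for ({x}, {y})")
        if value == 0:
            self._scores.pop((x, y), None)
        else:
            self._scores[(x, y)] = value

    def get(self, x: str, y: str) -> float:
        v = self._scores.get((x, y))
        if v is None:
            v = self._scores.get((y, x), 0.0)
        return v

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._scores.items())

    def pairs_for_x(self, x: str) -> list[tuple[str, float]]:
        """All (y, score) with a stored entry keyed on x's side."""
        return [(y, v) for (x_, y), v in self._scores.items() if x_ == x]

    @property
    def x_ids(self) -> set[str]:
        return {x for x, _ in self._scores}

    @property
    def y_ids(self) -> set[str]:
        return {y for _, y in self._scores}

    def __len__(self) -> int:
        return len(self._scores)

    def __bool__(self) -> bool:
        return bool(self._scores)

    def max_score(self) -> float:
        if not self._scores:
            raise ValidationError("empty similarity store has no maximum")
        return max(self._scores.values())

    def copy(self) -> "SimilarityStore":
        out = SimilarityStore()
        out._scores = dict(self._scores)
        return out


class Mapping:
    """An injective partial map X -> Y, stored as a set of (x, y) pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self.fwd: dict[str, str] = {}
        self.bwd: dict[str, str] = {}
        for x, y in pairs:
            self.add(x, y)

    def add(self, x: str, y: str) -> None:
        if x in self.fwd:
            raise InjectivityError(f"x-identifier {x!r} mapped twice")
        if y in self.bwd:
            raise InjectivityError(f"y-identifier {y!r} mapped twice")
        self.fwd[x] = y
        self.bwd[y] = x

    def remove(self, x: str) -> None:
        y = self.fwd.pop(x)
        del self.bwd[y]

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.fwd.items())

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.fwd.items())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        x, y = pair
        return self.fwd.get(x) == y

    def __len__(self) -> int:
        return len(self.fwd)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Mapping) and self.fwd == other.fwd

    def copy(self) -> "Mapping":
        m = Mapping()
        m.fwd = dict(self.fwd)
        m.bwd = dict(self.bwd)
        return m

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Mapping: {len(self.fwd)} pairs>"


@dataclass
class AlignmentInstance:
    """The two networks plus the cross-network similarity scores.

    Similarity entries whose endpoints are unknown to the corresponding
    network are dropped (counted in ``dropped_similarities``): scores can
    only reward pairs the mapping may actually contain.
    """

    net_x: Network
    net_y: Network
    sim: SimilarityStore
    dropped_similarities: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        kept = SimilarityStore()
        dropped = 0
        for (x, y), v in self.sim.items():
            if self.net_x.has_node(x) and self.net_y.has_node(y):
                kept.set(x, y, v)
            else:
                dropped += 1
        self.sim = kept
        self.dropped_similarities = dropped

    def validate_mapping(self, m: Mapping) -> None:
        for x, y in m.fwd.items():
            if not self.net_x.has_node(x):
                raise ValidationError(f"mapped x-identifier {x!r} not in network X")
            if not self.net_y.has_node(y):
                raise ValidationError(f"mapped y-identifier {y!r} not in network Y")


@dataclass(frozen=True)
class ObjectiveParams:
    """Weight ``alpha`` trading topology (alpha=1) against sequence (alpha=0)."""

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")


def topology_similarity(pair: tuple[str, str], mapping: Mapping,
                        inst: AlignmentInstance) -> int:
    """Conserved interactions incident to a matched pair.

    t((x,y)|M) = |{(x', y') in M : x' ~ x in G_X and y' ~ y in G_Y}|.
    """
    x, y = pair
    if mapping.fwd.get(x) != y:
        raise ContractViolation(f"pair ({x}, {y}) is not in the mapping")
    nbrs_y = inst.net_y.neighbors(y)
    count = 0
    for xn in inst.net_x.neighbors(x):
        yn = mapping.fwd.get(xn)
        if yn is not None and yn in nbrs_y:
            count += 1
    return count


def conserved_edge_count(mapping: Mapping, inst: AlignmentInstance) -> int:
    """Number of G_X edges whose image under the mapping is a G_Y edge."""
    adj_y = inst.net_y
    count = 0
    for x, y in mapping.fwd.items():
        for xn in inst.net_x.neighbors(x):
            if xn > x:
                continue  # each X edge once (canonical endpoint order)
            yn = mapping.fwd.get(xn)
            if yn is not None and adj_y.has_edge(y, yn):
                count += 1
    return count


def sequence_score(mapping: Mapping, inst: AlignmentInstance) -> float:
    """Sum of similarity scores over mapped pairs (absent pairs add 0)."""
    return float(sum(inst.sim.get(x, y) for x, y in mapping.fwd.items()))


def total_topology(mapping: Mapping, inst: AlignmentInstance) -> int:
    """Sum of t(e|M) over the mapping; equals 2 * conserved_edge_count."""
    return 2 * conserved_edge_count(mapping, inst)


def objective(mapping: Mapping, inst: AlignmentInstance,
              params: ObjectiveParams) -> float:
    """w(M) = alpha * sum t(e|M) + (1 - alpha) * sum s(e)."""
    a = params.alpha
    return a * total_topology(mapping, inst) + (1.0 - a) * sequence_score(mapping, inst)
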