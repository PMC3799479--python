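"""Synthetic instances: geometric random graphs and planted alignments.

Geometric random graphs are the standard null model for PPI topology:
proteins are points in a metric ("biochemical") space, interacting when
close.  :func:`geometric_random_graph` pins both the vertex *and* edge
count so a randomized network is directly comparable to the real one.

:func:`planted_instance` builds an alignment problem with a known answer:
network Y is a relabeled copy of network X whose edge set is perturbed
(false negatives + false positives, fraction ``rho_e``), and the similarity
table supports the planted bijection except for a fraction ``rho_s`` of
proteins whose true-pair score is replaced by random decoy scores —
emulating orthologs that sequence similarity alone cannot identify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .model import AlignmentInstance, Mapping, Network, SimilarityStore

__all__ = ["PlantedParams", "PlantedInstance", "geometric_random_graph",
           "erdos_renyi_graph", "planted_instance", "node_correctness"]


def geometric_random_graph(n: int, m: int, seed: int, dim: int = 2,
                           prefix: str = "g") -> Network:
    """Geometric random graph with exactly ``n`` nodes and ``m`` edges.

    Points are uniform in the unit hypercube and the ``m`` closest pairs
    are connected — the disk graph at the smallest radius admitting ``m``
    edges, trimmed to the exact count.  Deterministic given ``seed``.
    """
    if n < 0 or m < 0:
        raise ValidationError("n and m must be non-negative")
    max_m = n * (n - 1) // 2
    if m > max_m:
        raise ValidationError(f"m={m} exceeds the {max_m} possible edges on {n} nodes")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, dim))
    names = [f"{prefix}{i}" for i in range(n)]
    net = Network(nodes=names, name=f"grg_n{n}_m{m}")
    if m == 0:
        return net
    idx_pairs = list(combinations(range(n), 2))
    d2 = np.array([np.sum((pts[i] - pts[j]) ** 2) for i, j in idx_pairs])
    order = np.argsort(d2, kind="stable")[:m]
    for k in order:
        i, j = idx_pairs[k]
        net.add_edge(names[i], names[j])
    return net


def erdos_renyi_graph(n: int, p: float, seed: int, prefix: str = "g") -> Network:
    """G(n, p) with deterministic seeding and string node names."""
    if not 0 < p <= 1:
        raise ValidationError("edge density p must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"{prefix}{i}" for i in range(n)]
    net = Network(nodes=names, name=f"er_n{n}")
    for i, j in combinations(range(n), 2):
        if rng.random() < p:
            net.add_edge(names[i], names[j])
    return net


@dataclass(frozen=True)
class PlantedParams:
    """Study conditions for a planted-alignment instance.

    ``rho_e`` rewires that fraction of edges in the copy (equal numbers of
    false negatives and false positives); ``rho_s`` scrambles that fraction
    of proteins' similarity signal.  True pairs score near ``s_true``
    (+/-10%), decoys uniformly in (0, ``s_noise``].
    """

    n: int = 100
    p: float = 0.1
    rho_e: float = 0.2
    rho_s: float = 0.3
    s_true: float = 1.0
    s_noise: float = 0.5
    model: str = "er"  # or "grg"
    grg_edges: int | None = None  # edge count when model == "grg"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("planted instance needs n >= 2")
        if not 0 < self.p <= 1:
            raise ValidationError("edge density p must lie in (0, 1]")
        for name in ("rho_e", "rho_s"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.model not in ("er", "grg"):
            raise ValidationError("model must be 'er' or 'grg'")


@dataclass
class PlantedInstance:
    inst: AlignmentInstance
    truth: Mapping
    params: PlantedParams
    seed: int = field(default=0)


def _perturb_edges(net: Network, relabel: dict[str, str], rho_e: float,
                   rng: np.random.Generator, name: str) -> Network:
    """Relabeled copy with a fraction rho_e of edges rewired."""
    nodes = sorted(relabel.values())
    out = Network(nodes=nodes, name=name)
    edges = [(relabel[u], relabel[v]) for u, v in net.edge_list()]
    edges = [tuple(sorted(e)) for e in edges]
    k = int(round(rho_e * len(edges)))
    keep = set(range(len(edges)))
    if k > 0:
        drop = rng.choice(len(edges), size=k, replace=False)
        keep -= set(int(i) for i in drop)
    for i in sorted(keep):
        out.add_edge(*edges[i])
    present = {frozenset(e) for e in edges}
    added = 0
    while added < k:
        u, v = rng.choice(len(nodes), size=2, replace=False)
        e = frozenset((nodes[int(u)], nodes[int(v)]))
        if e not in present and not out.has_edge(nodes[int(u)], nodes[int(v)]):
            out.add_edge(nodes[int(u)], nodes[int(v)])
            added += 1
    return out


def planted_instance(params: PlantedParams, seed: int) -> PlantedInstance:
    """Generate an alignment instance with a planted ground-truth bijection."""
    rng = np.random.default_rng(seed)
    if params.model == "grg":
        m = params.grg_edges
        if m is None:
            m = int(round(params.p * params.n * (params.n - 1) / 2))
        net_x = geometric_random_graph(params.n, m, seed=int(rng.integers(2**31)),
                                       prefix="x")
    else:
        net_x = erdos_renyi_graph(params.n, params.p,
                                  seed=int(rng.integers(2**31)), prefix="x")
    xs = sorted(net_x.nodes)
    perm = rng.permutation(len(xs))
    relabel = {xs[i]: f"y{int(perm[i])}" for i in range(len(xs))}
    truth = Mapping((x, relabel[x]) for x in xs)
    net_y = _perturb_edges(net_x, relabel, params.rho_e, rng,
                           name=f"planted_copy_of_{net_x.name}")

    sim = SimilarityStore()
    ys = sorted(net_y.nodes)
    n_scrambled = int(round(params.rho_s * len(xs)))
    scrambled = {xs[int(i)] for i in rng.choice(len(xs), size=n_scrambled,
                                                replace=False)}
    for x in xs:
        if x in scrambled:
            decoys = rng.choice(len(ys), size=min(3, len(ys)), replace=False)
            for j in decoys:
                y = ys[int(j)]
                if y == relabel[x]:
                    continue  # decoys never reveal the true pair
                score = float(rng.uniform(0.0, params.s_noise))
                if score > 0:
                    sim.set(x, y, max(sim.get(x, y), score))
        else:
            jitter = float(rng.uniform(0.9, 1.1))
            sim.set(x, relabel[x], params.s_true * jitter)
    inst = AlignmentInstance(net_x=net_x, net_y=net_y, sim=sim)
    return PlantedInstance(inst=inst, truth=truth, params=params, seed=seed)


def node_correctness(m: Mapping, truth: Mapping) -> float:
    """|m ∩ truth| / |truth| — fraction of planted pairs recovered."""
    if len(truth) == 0:
        raise ValidationError("truth mapping is empty")
    hits = sum(1 for p in truth.fwd.items() if p in m)
    return hits / len(truth)
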