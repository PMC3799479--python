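"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's incremental machinery:
``naive_objective`` evaluates the alignment objective straight from its
definition (double loop over matched pairs), and ``brute_force_best`` scans
every injective partial mapping of a small instance.  Property tests check
the fast implementations against these.
"""

from __future__ import annotations

import random

import pytest

from piswap import (AlignmentInstance, Mapping, Network, SimilarityStore)


def naive_objective(pairs, inst: AlignmentInstance, alpha: float) -> float:
    """alpha * sum_t + (1-alpha) * sum_s computed from the raw definition."""
    pairs = list(pairs)
    t_sum = 0
    for x, y in pairs:
        for x2, y2 in pairs:
            if (x2, y2) == (x, y):
                continue
            if inst.net_x.has_edge(x, x2) and inst.net_y.has_edge(y, y2):
                t_sum += 1
    s_sum = sum(inst.sim.get(x, y) for x, y in pairs)
    return alpha * t_sum + (1.0 - alpha) * s_sum


def all_matchings(xs, ys):
    """Every injective partial mapping between two identifier lists."""
    xs = list(xs)

    def rec(i, used, current):
        if i == len(xs):
            yield list(current)
            return
        yield from rec(i + 1, used, current)  # leave xs[i] unmatched
        for y in ys:
            if y not in used:
                current.append((xs[i], y))
                used.add(y)
                yield from rec(i + 1, used, current)
                used.pop()
                current.pop()

    class _OrderedSet:
        def __init__(self):
            self._d = {}

        def add(self, v):
            self._d[v] = None

        def pop(self):
            self._d.popitem()

        def __contains__(self, v):
            return v in self._d

    yield from rec(0, _OrderedSet(), [])


def brute_force_best(inst: AlignmentInstance, alpha: float):
    """(best objective, best pair list) by exhaustive enumeration."""
    xs = sorted(inst.net_x.nodes)
    ys = sorted(inst.net_y.nodes)
    best_w, best_pairs = float("-inf"), []
    for pairs in all_matchings(xs, ys):
        w = naive_objective(pairs, inst, alpha)
        if w > best_w:
            best_w, best_pairs = w, pairs
    return best_w, best_pairs


def random_instance(rng: random.Random, max_n: int = 6,
                    min_n: int = 2) -> AlignmentInstance:
    """Small random alignment instance: ER networks + sparse scores."""
    nx_n = rng.randint(min_n, max_n)
    ny_n = rng.randint(min_n, max_n)
    xs = [f"x{i}" for i in range(nx_n)]
    ys = [f"y{i}" for i in range(ny_n)]
    p_x, p_y = rng.uniform(0.2, 0.7), rng.uniform(0.2, 0.7)
    net_x = Network(nodes=xs)
    for i in range(nx_n):
        for j in range(i + 1, nx_n):
            if rng.random() < p_x:
                net_x.add_edge(xs[i], xs[j])
    net_y = Network(nodes=ys)
    for i in range(ny_n):
        for j in range(i + 1, ny_n):
            if rng.random() < p_y:
                net_y.add_edge(ys[i], ys[j])
    sim = SimilarityStore()
    for x in xs:
        for y in ys:
            if rng.random() < 0.5:
                sim.set(x, y, round(rng.uniform(0.05, 1.0), 3))
    return AlignmentInstance(net_x, net_y, sim)


def random_mapping(inst: AlignmentInstance, rng: random.Random) -> Mapping:
    """Random injective partial mapping over an instance's node sets."""
    xs = sorted(inst.net_x.nodes)
    ys = sorted(inst.net_y.nodes)
    rng.shuffle(xs)
    rng.shuffle(ys)
    k = rng.randint(0, min(len(xs), len(ys)))
    return Mapping(zip(xs[:k], ys[:k]))


@pytest.fixture
def toy_a():
    """X = triangle {a,b,c}; Y = path 1-2-3; M maps a->1, b->2, c->3."""
    net_x = Network([("a", "b"), ("b", "c"), ("a", "c")])
    net_y = Network([("1", "2"), ("2", "3")])
    inst = AlignmentInstance(net_x, net_y, SimilarityStore())
    m = Mapping([("a", "1"), ("b", "2"), ("c", "3")])
    return inst, m


@pytest.fixture
def toy_b():
    """One X edge, one Y edge; sequence scores favour a topology-poor start."""
    net_x = Network([("x1", "x2")], nodes=["x1", "x2", "x3"])
    net_y = Network([("y1", "y2")], nodes=["y1", "y2", "y3"])
    sim = SimilarityStore({("x1", "y1"): 1.0, ("x2", "y3"): 0.6,
                           ("x3", "y2"): 0.6, ("x2", "y2"): 0.5,
                           ("x3", "y3"): 0.5})
    return AlignmentInstance(net_x, net_y, sim)


@pytest.fixture
def toy_c():
    """Two 3-paths; the cyclically shifted start needs a 3-cycle move."""
    net_x = Network([("x1", "x2"), ("x2", "x3")])
    net_y = Network([("y1", "y2"), ("y2", "y3")])
    sim = SimilarityStore({("x1", "y2"): 1.0, ("x2", "y3"): 1.0,
                           ("x3", "y1"): 1.0, ("x1", "y1"): 0.9,
                           ("x3", "y3"): 0.9})
    inst = AlignmentInstance(net_x, net_y, sim)
    m0 = Mapping([("x1", "y2"), ("x2", "y3"), ("x3", "y1")])
    return inst, m0
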