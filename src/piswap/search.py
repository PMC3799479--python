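"""2-Opt / 3-Opt local search over bipartite matchings.

The refinement loop repeatedly scans a restricted move neighborhood and
applies the first move that strictly increases the objective, stopping at a
local optimum (or an iteration cap).  Moves are:

* a 2-swap exchanging the partners of two matched pairs,
* a reassignment of a matched protein to a currently unmatched partner,
* (3-Opt) any of the five non-identity reassignments of the partners of a
  triple of matched pairs — three pairwise swaps plus two 3-cycles.

The neighborhood is pruned by candidate sets ``N_c``: for each vertex the
``c`` best-scoring partners on the other side, ranked by sequence
similarity, or, for sequence-free alignments, by degree similarity.  A
2-swap of pairs (x, y), (x', y') is admissible when y' is a candidate of x
or x' is a candidate of y; a 3-move needs at least one introduced edge
whose partner lies in a candidate list.

Move gains are computed incrementally: only conserved edges touching a
reassigned vertex can change, so each delta costs O(local degree) instead
of a full objective evaluation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import ContractViolation, ValidationError
from .model import (AlignmentInstance, Mapping, ObjectiveParams, objective)

__all__ = ["CandidateIndex", "RefineParams", "RefineResult", "build_candidates",
           "swap_delta_2", "swap_delta_unmatched", "best_3opt_move", "refine",
           "find_improving_move", "IMPROVEMENT_TOL"]

#: Gains at or below this tolerance are treated as ties and never accepted.
IMPROVEMENT_TOL = 1e-9

#: The five non-identity reassignments of three partners (index permutations).
_PERMS_3 = ((1, 0, 2), (0, 2, 1), (2, 1, 0), (1, 2, 0), (2, 0, 1))


@dataclass
class CandidateIndex:
    """Pruned swap-partner lists N_c for both sides of the bipartition."""

    for_x: dict[str, list[str]]
    for_y: dict[str, list[str]]
    mode: str
    c: int


@dataclass
class RefineParams:
    alpha: float
    c: int = 20
    opt_order: int = 2
    max_iterations: int = 10000
    allow_unmatched_swaps: bool = True
    seed: int | None = None  # shuffles the scan order only

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.c < 1:
            raise ValidationError("candidate-list size c must be >= 1")
        if self.opt_order not in (2, 3):
            raise ValidationError("opt_order must be 2 or 3")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class RefineResult:
    """Refined mapping plus the trajectory of the accepted-move sequence."""

    mapping: Mapping
    swap_count: int
    objective_trajectory: list[float]
    terminated_by: str  # "local_optimum" | "iteration_cap"
    alpha: float
    moves: list[tuple[int, str, float]] = field(default_factory=list)


def build_candidates(inst: AlignmentInstance, mode: str = "sequence",
                     c: int = 20) -> CandidateIndex:
    """Rank each vertex's potential partners and keep the top ``c``.

    ``sequence`` mode ranks by similarity score over pairs with s > 0.
    ``topology`` mode (for sequence-free alignments) ranks every opposite
    vertex by degree closeness: smaller |deg(x) - deg(y)| first, ties broken
    by larger min-degree, then identifier.
    """
    if c < 1:
        raise ValidationError("candidate-list size c must be >= 1")
    if mode == "sequence":
        by_x: dict[str, list[tuple[float, str]]] = {}
        by_y: dict[str, list[tuple[float, str]]] = {}
        for (x, y), v in inst.sim.items():
            by_x.setdefault(x, []).append((v, y))
            by_y.setdefault(y, []).append((v, x))
        for_x = {x: [n for _, n in sorted(lst, key=lambda t: (-t[0], t[1]))][:c]
                 for x, lst in by_x.items()}
        for_y = {y: [n for _, n in sorted(lst, key=lambda t: (-t[0], t[1]))][:c]
                 for y, lst in by_y.items()}
    elif mode == "topology":
        def rank(node, net_from, net_to):
            d = net_from.degree(node)
            scored = sorted(
                net_to.nodes,
                key=lambda o: (abs(d - net_to.degree(o)),
                               -min(d, net_to.degree(o)), o))
            return scored[:c]
        for_x = {x: rank(x, inst.net_x, inst.net_y) for x in inst.net_x.nodes}
        for_y = {y: rank(y, inst.net_y, inst.net_x) for y in inst.net_y.nodes}
    else:
        raise ValidationError(f"unknown candidate mode {mode!r}")
    return CandidateIndex(for_x=for_x, for_y=for_y, mode=mode, c=c)


def _conserved_touching(inst: AlignmentInstance, fwd: dict[str, str],
                        xs: set[str]) -> int:
    """Conserved X-edges with at least one endpoint in ``xs`` (each once)."""
    net_y = inst.net_y
    count = 0
    for u in xs:
        fu = fwd.get(u)
        if fu is None:
            continue
        for v in inst.net_x.neighbors(u):
            if v in xs and v < u:
                continue  # counted from v's side
            fv = fwd.get(v)
            if fv is not None and net_y.has_edge(fu, fv):
                count += 1
    return count


def _delta(m: Mapping, inst: AlignmentInstance, alpha: float,
           removals: list[tuple[str, str]],
           additions: list[tuple[str, str]]) -> float:
    """Objective change of replacing ``removals`` by ``additions``.

    Exactly mirrors a full recomputation: only conserved edges touching a
    reassigned x can change, and the topology total is twice their count.
    """
    fwd = m.fwd
    changed = {x for x, _ in removals} | {x for x, _ in additions}
    old_c = _conserved_touching(inst, fwd, changed)
    ds = (sum(inst.sim.get(x, y) for x, y in additions)
          - sum(inst.sim.get(x, y) for x, y in removals))
    saved = {x: fwd.get(x) for x in changed}
    try:
        for x, _ in removals:
            del fwd[x]
        for x, y in additions:
            fwd[x] = y
        new_c = _conserved_touching(inst, fwd, changed)
    finally:
        for x, v in saved.items():
            if v is None:
                fwd.pop(x, None)
            else:
                fwd[x] = v
    return alpha * 2.0 * (new_c - old_c) + (1.0 - alpha) * ds


def swap_delta_2(m: Mapping, e: tuple[str, str], e2: tuple[str, str],
                 inst: AlignmentInstance, alpha: float) -> float:
    """Gain of exchanging the partners of two matched pairs."""
    if e not in m:
        raise ContractViolation(f"pair {e} is not in the mapping")
    if e2 not in m:
        raise ContractViolation(f"pair {e2} is not in the mapping")
    if e == e2:
        raise ContractViolation("cannot swap a pair with itself")
    (x, y), (x2, y2) = e, e2
    return _delta(m, inst, alpha, [e, e2], [(x, y2), (x2, y)])


def swap_delta_unmatched(m: Mapping, e: tuple[str, str], y_new: str,
                         inst: AlignmentInstance, alpha: float) -> float:
    """Gain of reassigning a matched x to a currently unmatched y."""
    if e not in m:
        raise ContractViolation(f"pair {e} is not in the mapping")
    if y_new in m.bwd:
        raise ContractViolation(f"{y_new!r} is already matched")
    x, _ = e
    return _delta(m, inst, alpha, [e], [(x, y_new)])


def best_3opt_move(m: Mapping, triple: tuple[tuple[str, str], ...],
                   inst: AlignmentInstance, alpha: float
                   ) -> tuple[list[tuple[str, str]], float]:
    """Best of the five non-identity partner reassignments of a triple.

    Returns ``(additions, delta)`` where ``additions`` replace the triple;
    ties resolve to the first permutation in a fixed enumeration order.
    """
    if len(set(triple)) != 3:
        raise ContractViolation("3-Opt needs three distinct pairs")
    for e in triple:
        if e not in m:
            raise ContractViolation(f"pair {e} is not in the mapping")
    xs = [e[0] for e in triple]
    ys = [e[1] for e in triple]
    removals = list(triple)
    best: tuple[list[tuple[str, str]], float] | None = None
    for perm in _PERMS_3:
        additions = [(xs[i], ys[perm[i]]) for i in range(3)]
        dw = _delta(m, inst, alpha, removals, additions)
        if best is None or dw > best[1]:
            best = (additions, dw)
    assert best is not None
    return best


def _scan_pairs(m: Mapping, seed: int | None) -> list[tuple[str, str]]:
    pairs = m.sorted_pairs()
    if seed is not None:
        random.Random(seed).shuffle(pairs)
    return pairs


def _two_swap_partners(m: Mapping, cand: CandidateIndex, x: str, y: str):
    """Admissible counterpart pairs / unmatched targets for pair (x, y)."""
    seen: set[str] = set()
    for y2 in cand.for_x.get(x, ()):
        if y2 == y:
            continue
        x2 = m.bwd.get(y2)
        if x2 is None:
            yield None, y2  # unmatched target
        elif x2 not in seen:
            seen.add(x2)
            yield (x2, y2), None
    for x2 in cand.for_y.get(y, ()):
        if x2 == x or x2 in seen:
            continue
        y2 = m.fwd.get(x2)
        if y2 is not None:
            seen.add(x2)
            yield (x2, y2), None


def find_improving_move(m: Mapping, inst: AlignmentInstance,
                        cand: CandidateIndex, params: RefineParams
                        ) -> tuple[str, list, list, float] | None:
    """First strictly improving admissible move, or None at a local optimum.

    2-moves are scanned to exhaustion before any 3-move is considered, so
    enabling 3-Opt can only extend — never divert — the 2-Opt descent.
    """
    alpha = params.alpha
    pairs = _scan_pairs(m, params.seed)
    for x, y in pairs:
        for counterpart, y_new in _two_swap_partners(m, cand, x, y):
            if counterpart is not None:
                dw = swap_delta_2(m, (x, y), counterpart, inst, alpha)
                if dw > IMPROVEMENT_TOL:
                    x2, y2 = counterpart
                    return ("swap2", [(x, y), counterpart],
                            [(x, y2), (x2, y)], dw)
            elif params.allow_unmatched_swaps:
                dw = swap_delta_unmatched(m, (x, y), y_new, inst, alpha)
                if dw > IMPROVEMENT_TOL:
                    return ("move_unmatched", [(x, y)], [(x, y_new)], dw)
    if params.opt_order < 3 or len(m) < 3:
        return None
    budget = 10 * len(m)
    tried = 0
    for x, y in pairs:
        for counterpart, _ in _two_swap_partners(m, cand, x, y):
            if counterpart is None:
                continue
            x2, y2 = counterpart
            thirds: list[tuple[str, str]] = []
            seen_third: set[str] = set()
            for xn in sorted(inst.net_x.neighbors(x) | inst.net_x.neighbors(x2)):
                if xn in (x, x2) or xn in seen_third:
                    continue
                yn = m.fwd.get(xn)
                if yn is not None:
                    seen_third.add(xn)
                    thirds.append((xn, yn))
            for yn in sorted(inst.net_y.neighbors(y) | inst.net_y.neighbors(y2)):
                if yn in (y, y2):
                    continue
                xn = m.bwd.get(yn)
                if xn is not None and xn not in (x, x2) and xn not in seen_third:
                    seen_third.add(xn)
                    thirds.append((xn, yn))
            for e3 in thirds:
                tried += 1
                triple = ((x, y), (x2, y2), e3)
                additions, dw = best_3opt_move(m, triple, inst, alpha)
                if dw > IMPROVEMENT_TOL:
                    return ("opt3", list(triple), additions, dw)
                if tried >= budget:
                    return None
    return None


def refine(m0: Mapping, inst: AlignmentInstance, cand: CandidateIndex,
           params: RefineParams) -> RefineResult:
    """Run the local search from ``m0`` until a local optimum or the cap.

    The trajectory records the objective before any move and after each
    accepted move; it is strictly increasing by construction.
    """
    inst.validate_mapping(m0)
    m = m0.copy()
    obj_params = ObjectiveParams(params.alpha)
    trajectory = [objective(m, inst, obj_params)]
    moves: list[tuple[int, str, float]] = []
    terminated = "local_optimum"
    while True:
        if len(moves) >= params.max_iterations:
            terminated = "iteration_cap"
            break
        found = find_improving_move(m, inst, cand, params)
        if found is None:
            break
        kind, removals, additions, dw = found
        for x, _ in removals:
            m.remove(x)
        for x, y in additions:
            m.add(x, y)
        moves.append((len(moves) + 1, kind, dw))
        trajectory.append(objective(m, inst, obj_params))
    return RefineResult(mapping=m, swap_count=len(moves),
                        objective_trajectory=trajectory,
                        terminated_by=terminated, alpha=params.alpha,
                        moves=moves)
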