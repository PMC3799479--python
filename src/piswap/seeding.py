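"""Initial alignment and score preprocessing.

The refinement loop needs a starting matching; the classic choice is the
maximum-weight bipartite matching on sequence similarity alone (Hungarian /
assignment problem), which is what :func:`initial_matching` computes.  Raw
BLAST bit scores are asymmetric, so :func:`symmetrize_scores` keeps the max
of the two directions, and :func:`normalize_scores` rescales to (0, 1] by
the global maximum.

:func:`auto_alpha` picks the topology/sequence trade-off so that the
topology term of the objective carries twice the weight the sequence term
carries on the initial mapping — the rule of thumb that favours topology
twice as much as a purely sequence-based start did.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .model import (AlignmentInstance, Mapping, SimilarityStore,
                    sequence_score, total_topology)

__all__ = ["symmetrize_scores", "normalize_scores", "initial_matching",
           "auto_alpha", "ALPHA_CLAMP"]

ALPHA_CLAMP = (0.01, 0.99)


def symmetrize_scores(raw: SimilarityStore) -> SimilarityStore:
    """Collapse directed (i, j)/(j, i) entries to max-valued unordered pairs."""
    out = SimilarityStore()
    for (i, j), v in raw.items():
        key = (i, j) if i <= j else (j, i)
        if v > out.get(*key):
            out.set(*key, value=v)
    return out


def normalize_scores(sym: SimilarityStore) -> SimilarityStore:
    """Divide every score by the global maximum; results lie in (0, 1]."""
    if not sym:
        raise ValidationError("cannot normalize an empty similarity store")
    m = sym.max_score()
    out = SimilarityStore()
    for (x, y), v in sym.items():
        out.set(x, y, v / m)
    return out


def initial_matching(inst: AlignmentInstance) -> Mapping:
    """Maximum-weight bipartite matching on sequence similarity.

    Solved as a linear assignment problem on the identifier-sorted score
    matrix; pairs with zero similarity are never matched.  Among equal-weight
    optima a weight-neutral pairwise-exchange pass pushes the result toward
    the lexicographically smallest pair list, so the output is deterministic.
    """
    sim = inst.sim
    if not sim:
        return Mapping()
    xs = sorted({x for x, _ in (k for k, _ in sim.items())})
    ys = sorted({y for _, y in (k for k, _ in sim.items())})
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    w = np.zeros((len(xs), len(ys)))
    for (x, y), v in sim.items():
        w[xi[x], yi[y]] = max(w[xi[x], yi[y]], v)
    rows, cols = linear_sum_assignment(w, maximize=True)
    m = Mapping((xs[i], ys[j]) for i, j in zip(rows, cols) if w[i, j] > 0)
    _lexicographic_canonicalize(m, sim)
    return m


def _lexicographic_canonicalize(m: Mapping, sim: SimilarityStore) -> None:
    """Apply weight-neutral 2-exchanges that lower the sorted pair list."""
    changed = True
    while changed:
        changed = False
        pairs = m.sorted_pairs()
        for i in range(len(pairs)):
            x1, y1 = pairs[i]
            for j in range(i + 1, len(pairs)):
                x2, y2 = pairs[j]
                if min(y1, y2) == y1:
                    continue  # already lexicographically ordered on this pair
                old = sim.get(x1, y1) + sim.get(x2, y2)
                new = sim.get(x1, y2) + sim.get(x2, y1)
                if new == old and sim.get(x1, y2) > 0 and sim.get(x2, y1) > 0:
                    m.remove(x1)
                    m.remove(x2)
                    m.add(x1, y2)
                    m.add(x2, y1)
                    changed = True
                    break
            if changed:
                break


def auto_alpha(m0: Mapping, inst: AlignmentInstance) -> float:
    """alpha* = 2*S0 / (2*S0 + T0), clamped to [0.01, 0.99].

    S0 is the initial mapping's sequence total, T0 its topology total.  At
    alpha*, the realized topology contribution alpha*·T0 equals twice the
    realized sequence contribution (1 - alpha*)·S0.  With no sequence signal
    (S0 = 0) the objective degenerates to pure topology and alpha = 1.
    """
    s0 = sequence_score(m0, inst)
    if s0 == 0.0:
        return 1.0
    t0 = float(total_topology(m0, inst))
    alpha = 2.0 * s0 / (2.0 * s0 + t0)
    lo, hi = ALPHA_CLAMP
    return min(max(alpha, lo), hi)
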