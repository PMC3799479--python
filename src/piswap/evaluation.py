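"""Alignment quality metrics.

Edge correctness (EC) measures topology preservation: the fraction of the
smaller network's interactions whose image under the alignment is again an
interaction.  Functional coherence (FC) measures biological plausibility via
the Gene Ontology: each GO term is first *standardized* to its is_a
ancestors lying within distance five of the ontology root, each aligned
protein pair scores the median Jaccard overlap between the standardized
sets of its term pairs, and the mapping's FC is the mean over the aligned
pairs that carry usable annotations.
"""

from __future__ import annotations

from statistics import median

from .errors import ValidationError
from .model import AlignmentInstance, Mapping, conserved_edge_count
from .ontology import GoAnnotations, GoDag

__all__ = ["ec_ratio", "standardized_terms", "fc_pair", "fc_mapping",
           "STANDARDIZATION_DEPTH"]

#: Maximum root distance of a standardized ancestor ("distance five").
STANDARDIZATION_DEPTH = 5


def ec_ratio(m: Mapping, inst: AlignmentInstance) -> float:
    """conserved edges / min(|E_X|, |E_Y|); 0 if either edge set is empty."""
    denom = min(inst.net_x.edge_count, inst.net_y.edge_count)
    if denom == 0:
        return 0.0
    return conserved_edge_count(m, inst) / denom


def standardized_terms(term: str, dag: GoDag) -> set[str]:
    """The term and its is_a ancestors at depth 1..5 (roots excluded)."""
    if term not in dag:
        raise ValidationError(f"unknown GO term {term!r}")
    return {a for a in dag.ancestors(term, include_self=True)
            if 1 <= dag.depth.get(a, -1) <= STANDARDIZATION_DEPTH}


def fc_pair(x: str, y: str, ann: GoAnnotations, dag: GoDag) -> float | None:
    """Median fractional overlap of standardized GO-term sets, or None.

    Every term pair (g_x, g_y) with non-empty standardized sets contributes
    |Std(g_x) & Std(g_y)| / |Std(g_x) | Std(g_y)|; a protein with no usable
    terms makes the pair unscorable (None, not 0).
    """
    std_x = [s for g in sorted(ann.get(x)) if (s := standardized_terms(g, dag))]
    std_y = [s for g in sorted(ann.get(y)) if (s := standardized_terms(g, dag))]
    if not std_x or not std_y:
        return None
    overlaps = [len(sx & sy) / len(sx | sy) for sx in std_x for sy in std_y]
    return float(median(overlaps))


def fc_mapping(m: Mapping, ann: GoAnnotations, dag: GoDag
               ) -> tuple[float | None, int]:
    """Mean pairwise FC over scorable aligned pairs, with their count.

    Unannotated pairs are skipped rather than scored 0 (typically only
    60-70% of network proteins carry a GO annotation); returns (None, 0)
    when no pair is scorable.
    """
    values = []
    for x, y in m.sorted_pairs():
        v = fc_pair(x, y, ann, dag)
        if v is not None:
            values.append(v)
    if not values:
        return None, 0
    return sum(values) / len(values), len(values)
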