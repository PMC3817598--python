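"""Map name records from one database onto taxon records of another.

Two databases rarely store the same name identically: one may write
"Nystactes Bohlke", the other "Nystactes Bohlke, 1957".  To link them, the
records sharing a canonical name are arranged as a bipartite graph — one
side per database — with edge weights equal to the LCS similarity of the
full name strings (fingerprinted).  The maximum weighted bipartite matching
of that graph is the record-to-record map: each record pairs with at most
one partner and the total similarity is maximal, so "Gloger 1827" pairs
with "Gloger, 1827" even when a greedy pass would have stolen its partner.

Edges below ``min_weight`` (default 0.5) are not admitted: without a floor
a bare genus name, which is a subsequence of every authored variant, would
attach to an arbitrary leftover taxon.

The solver is :func:`scipy.optimize.linear_sum_assignment` per canonical
block; among equally-optimal matchings the one whose sorted pair list is
lexicographically smallest is returned, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .namemodel import NameRecord, group_by_canonical
from .textnorm import similarity

__all__ = [
    "DEFAULT_MIN_WEIGHT",
    "BipartiteNameGraph",
    "Matching",
    "build_bipartite",
    "max_weight_matching",
    "map_names_to_taxa",
]

DEFAULT_MIN_WEIGHT = 0.5
_EPS = 1e-9


@dataclass
class BipartiteNameGraph:
    """Admitted edges between two sets of name records.

    ``left`` and ``right`` come from different source databases; every edge
    weight is in [``min_weight``, 1].
    """

    left: list[NameRecord]
    right: list[NameRecord]
    edges: list[tuple[str, str, float]]
    min_weight: float = DEFAULT_MIN_WEIGHT


@dataclass
class Matching:
    """A valid matching: no record id appears in more than one pair."""

    pairs: list[tuple[str, str, float]]
    unmatched_left: list[str] = field(default_factory=list)
    unmatched_right: list[str] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.pairs)


def build_bipartite(
    left: Sequence[NameRecord],
    right: Sequence[NameRecord],
    min_weight: float = DEFAULT_MIN_WEIGHT,
) -> BipartiteNameGraph:
    """Weight every left/right pair by full-name-string LCS similarity.

    Pairs scoring below ``min_weight`` get no edge.  Callers normally block
    by canonical name first (see :func:`map_names_to_taxa`); this function
    weights all pairs it is given.
    """
    edges = []
    for lrec in left:
        for rrec in right:
            s = similarity(lrec.name_string, rrec.name_string).score
            if s >= min_weight:
                edges.append((lrec.record_id, rrec.record_id, s))
    return BipartiteNameGraph(left=list(left), right=list(right), edges=edges, min_weight=min_weight)


def _solve_block(
    left_ids: list[str], right_ids: list[str], weights: dict[tuple[str, str], float]
) -> list[tuple[str, str, float]]:
    """Max-weight matching of one block, lexicographically smallest among optima.

    linear_sum_assignment maximizes over a dense matrix with zeros standing
    for missing edges; zero-weight assignments are discarded afterwards.
    The lexicographic refinement walks candidate pairs in sorted order and
    keeps a pair iff forcing it preserves the optimal total weight.
    """
    if not weights:
        return []
    lidx = {rid: i for i, rid in enumerate(left_ids)}
    ridx = {rid: j for j, rid in enumerate(right_ids)}
    w = np.zeros((len(left_ids), len(right_ids)))
    for (lid, rid), s in weights.items():
        w[lidx[lid], ridx[rid]] = s

    def best(matrix: np.ndarray) -> float:
        if matrix.size == 0:
            return 0.0
        rows, cols = linear_sum_assignment(matrix, maximize=True)
        return float(matrix[rows, cols].sum())

    optimum = best(w)
    chosen: list[tuple[str, str, float]] = []
    live_rows = list(range(len(left_ids)))
    live_cols = list(range(len(right_ids)))
    sub = w
    target = optimum
    for lid, rid in sorted(weights):
        if lidx[lid] not in live_rows or ridx[rid] not in live_cols:
            continue
        i = live_rows.index(lidx[lid])
        j = live_cols.index(ridx[rid])
        reduced = np.delete(np.delete(sub, i, axis=0), j, axis=1)
        forced = sub[i, j] + best(reduced)
        if forced >= target - _EPS:
            chosen.append((lid, rid, weights[(lid, rid)]))
            live_rows.pop(i)
            live_cols.pop(j)
            sub = reduced
            target -= weights[(lid, rid)]
    return chosen


def max_weight_matching(graph: BipartiteNameGraph) -> Matching:
    """Maximum weighted bipartite matching of an edge-admitted graph.

    Deterministic: among equal-weight optima the matching whose sorted
    (left_id, right_id) list is lexicographically smallest is returned.
    """
    weights = {(l, r): s for l, r, s in graph.edges}
    left_ids = sorted({rec.record_id for rec in graph.left})
    right_ids = sorted({rec.record_id for rec in graph.right})
    pairs = sorted(_solve_block(left_ids, right_ids, weights))
    in_l = {p[0] for p in pairs}
    in_r = {p[1] for p in pairs}
    return Matching(
        pairs=pairs,
        unmatched_left=[i for i in left_ids if i not in in_l],
        unmatched_right=[i for i in right_ids if i not in in_r],
    )


def map_names_to_taxa(
    left: Sequence[NameRecord],
    right: Sequence[NameRecord],
    min_weight: float = DEFAULT_MIN_WEIGHT,
) -> Matching:
    """Match two databases' name records, blocked by canonical name.

    Only records with the same canonical component are compared (names with
    different canonicals are never the same name, and blocking bounds the
    pairwise cost).  Records whose canonical exists only on one side, and
    unparseable records, come back unmatched.  Duplicate record ids within
    one side are an input error.
    """
    for side, recs in (("left", left), ("right", right)):
        ids = [r.record_id for r in recs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})[0]
            raise ValueError(f"duplicate record_id {dup!r} in {side} input")

    gl = group_by_canonical(left)
    gr = group_by_canonical(right)
    all_pairs: list[tuple[str, str, float]] = []
    for canonical in sorted(set(gl.groups) & set(gr.groups)):
        block = build_bipartite(gl.groups[canonical], gr.groups[canonical], min_weight)
        all_pairs.extend(max_weight_matching(block).pairs)

    in_l = {p[0] for p in all_pairs}
    in_r = {p[1] for p in all_pairs}
    return Matching(
        pairs=sorted(all_pairs),
        unmatched_left=sorted(r.record_id for r in left if r.record_id not in in_l),
        unmatched_right=sorted(r.record_id for r in right if r.record_id not in in_r),
    )
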