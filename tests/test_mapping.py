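"""Bipartite name-to-taxon matching: weights, optimality, determinism."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from taxonrec.mapping import (
    BipartiteNameGraph,
    build_bipartite,
    map_names_to_taxa,
    max_weight_matching,
)
from taxonrec.namemodel import NameRecord

from conftest import brute_force_matching


def _rec(i, name, source="A"):
    return NameRecord(record_id=str(i), name_string=name, source=source)


def test_nystactes_graph_weights(examples):
    g = build_bipartite(examples.ion_nystactes, examples.gbif_nystactes, 0.5)
    w = {(l.split(":")[-1], r): s for l, r, s in g.edges}
    # same-author pairs all admitted with weight >= 0.75
    assert w[("2735131", "2403398")] >= 0.75  # Bohlke ~ Bohlke, 1957
    assert w[("4888093", "2475109")] == 1.0  # Gloger 1827 ~ Gloger, 1827
    assert w[("4888094", "3239722")] == 1.0  # Kaup 1829 ~ Kaup, 1829
    # the bare "Nystactes" is a subsequence of everything but fails the floor
    assert ("2787598", "3239722") not in w
    assert all(s >= 0.5 for _, _, s in g.edges)


def test_identical_strings_single_unit_edge():
    g = build_bipartite([_rec(1, "Aus bus Smith")], [_rec(2, "Aus bus Smith", "B")])
    assert g.edges == [("1", "2", 1.0)]


def test_nystactes_matching_three_pairs(examples):
    m = map_names_to_taxa(examples.ion_nystactes, examples.gbif_nystactes)
    got = {(l.split(":")[-1], r) for l, r, _ in m.pairs}
    assert got == {("2735131", "2403398"), ("4888093", "2475109"), ("4888094", "3239722")}
    assert m.unmatched_left == ["urn:lsid:organismnames.com:name:2787598"]
    assert m.unmatched_right == []


def test_matching_beats_greedy_on_crossing_weights():
    # greedy grabs (1,1)=0.9 then only (2,2)=0.6; the optimum crosses
    g = BipartiteNameGraph(
        left=[_rec("l1", "Aus"), _rec("l2", "Aus")],
        right=[_rec("r1", "Aus", "B"), _rec("r2", "Aus", "B")],
        edges=[("l1", "r1", 0.9), ("l1", "r2", 0.8), ("l2", "r1", 0.8), ("l2", "r2", 0.6)],
    )
    m = max_weight_matching(g)
    assert {(l, r) for l, r, _ in m.pairs} == {("l1", "r2"), ("l2", "r1")}
    assert m.total_weight == pytest.approx(1.6)


def test_single_edge_graph():
    g = BipartiteNameGraph(left=[_rec("l1", "Aus")], right=[_rec("r1", "Aus", "B")],
                           edges=[("l1", "r1", 0.7)])
    m = max_weight_matching(g)
    assert m.pairs == [("l1", "r1", 0.7)]


def test_empty_graph_and_one_sided_input():
    assert max_weight_matching(
        BipartiteNameGraph(left=[], right=[], edges=[])).pairs == []
    m = map_names_to_taxa([_rec(1, "Aus Smith")], [])
    assert m.pairs == [] and m.unmatched_left == ["1"]


def test_matching_validity_invariants(examples):
    m = map_names_to_taxa(examples.ion_nystactes, examples.gbif_nystactes)
    lefts = [l for l, _, _ in m.pairs]
    rights = [r for _, r, _ in m.pairs]
    assert len(lefts) == len(set(lefts)) and len(rights) == len(set(rights))
    assert sorted(lefts + m.unmatched_left) == sorted(
        r.record_id for r in examples.ion_nystactes)
    assert sorted(rights + m.unmatched_right) == sorted(
        r.record_id for r in examples.gbif_nystactes)


def _random_instance(rng, n_left, n_right, p=0.6):
    edges = []
    for i in range(n_left):
        for j in range(n_right):
            if rng.random() < p:
                edges.append((f"l{i}", f"r{j}", round(rng.uniform(0.5, 1.0), 3)))
    left = [_rec(f"l{i}", "Aus") for i in range(n_left)]
    right = [_rec(f"r{j}", "Aus", "B") for j in range(n_right)]
    return BipartiteNameGraph(left=left, right=right, edges=edges)


@pytest.mark.parametrize("seed", range(20))
def test_optimality_matches_exhaustive_enumeration(seed):
    rng = random.Random(seed)
    g = _random_instance(rng, rng.randint(1, 6), rng.randint(1, 6))
    m = max_weight_matching(g)
    assert m.total_weight == pytest.approx(brute_force_matching(g.edges))


@pytest.mark.parametrize("seed", range(10))
def test_agrees_with_networkx_max_weight_matching(seed):
    rng = random.Random(100 + seed)
    g = _random_instance(rng, rng.randint(1, 5), rng.randint(1, 5))
    nxg = nx.Graph()
    nxg.add_nodes_from([l.record_id for l in g.left] + ["R" + r.record_id for r in g.right])
    for l, r, w in g.edges:
        nxg.add_edge(l, "R" + r, weight=w)
    expected = sum(nxg[u][v]["weight"] for u, v in nx.max_weight_matching(nxg))
    assert max_weight_matching(g).total_weight == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(10))
def test_total_weight_at_least_greedy(seed):
    rng = random.Random(7 + seed)
    g = _random_instance(rng, 5, 5)
    used_l, used_r, greedy = set(), set(), 0.0
    for l, r, w in sorted(g.edges, key=lambda e: -e[2]):
        if l not in used_l and r not in used_r:
            used_l.add(l)
            used_r.add(r)
            greedy += w
    assert max_weight_matching(g).total_weight >= greedy - 1e-9


def test_symmetry_of_sides(examples):
    fwd = map_names_to_taxa(examples.ion_nystactes, examples.gbif_nystactes)
    rev = map_names_to_taxa(examples.gbif_nystactes, examples.ion_nystactes)
    assert {(l, r) for l, r, _ in fwd.pairs} == {(r, l) for l, r, _ in rev.pairs}
    assert fwd.total_weight == pytest.approx(rev.total_weight)


def test_blocking_by_canonical():
    left = [_rec(1, "Aus Smith"), _rec(2, "Bus Smith")]
    right = [_rec(3, "Aus Smith", "B"), _rec(4, "Cus Smith", "B")]
    m = map_names_to_taxa(left, right)
    assert [(l, r) for l, r, _ in m.pairs] == [("1", "3")]
    assert m.unmatched_left == ["2"] and m.unmatched_right == ["4"]


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        map_names_to_taxa([_rec(1, "Aus Smith"), _rec(1, "Aus Gray")], [])


def test_deterministic_tie_breaking():
    # two optimal matchings of equal weight; the lexicographically smallest
    # sorted pair list must come back, run after run
    g = BipartiteNameGraph(
        left=[_rec("l1", "Aus"), _rec("l2", "Aus")],
        right=[_rec("r1", "Aus", "B"), _rec("r2", "Aus", "B")],
        edges=[("l1", "r1", 0.7), ("l1", "r2", 0.7), ("l2", "r1", 0.7), ("l2", "r2", 0.7)],
    )
    for _ in range(3):
        m = max_weight_matching(g)
        assert [(l, r) for l, r, _ in m.pairs] == [("l1", "r1"), ("l2", "r2")]
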