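"""Authorship clustering: graph construction, components, authorless merge."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxonrec.clustering import build_author_graph, cluster_all, cluster_names
from taxonrec.namemodel import NameRecord, parse_name

from conftest import transitive_closure_clusters


def _group(*names, canonical="Nystactes"):
    return [
        NameRecord(record_id=f"r{i}", name_string=f"{canonical} {n}".strip(), source="T")
        for i, n in enumerate(names)
    ]


def test_identical_fingerprints_get_an_edge():
    g = build_author_graph(_group("Gloger 1827", "Gloger, 1827"), 0.8)
    assert len(g.edges) == 1
    assert g.edges[0][2] == 1.0


def test_distinct_authors_get_no_edges():
    g = build_author_graph(_group("Bohlke", "Gloger 1827", "Kaup 1829"), 0.8)
    assert g.edges == []
    assert len(g.nodes) == 3


def test_singleton_group():
    g = build_author_graph(_group("Kaup 1829"), 0.8)
    assert (len(g.nodes), len(g.edges)) == (1, 0)


def test_authorless_records_excluded_from_graph():
    g = build_author_graph(_group("", "Kaup 1829"), 0.8)
    assert len(g.nodes) == 1


def test_edges_respect_threshold_invariant():
    g = build_author_graph(_group("Gloger 1827", "Gloger, 1827", "Glogar 1827"), 0.8)
    assert all(s >= 0.8 for _, _, s in g.edges)
    assert all(u != v for u, v, _ in g.edges)


def test_ion_nystactes_three_clusters(examples):
    clusters = cluster_all(examples.ion_nystactes).clusters
    assert len(clusters) == 3
    by_members = {
        frozenset(n.split(":")[-1] for n in c.member_ids): c for c in clusters
    }
    # bare "Nystactes" attaches to Bohlke's cluster (all authored clusters are
    # singletons; the tie-break picks the lexicographically smallest authorship)
    bare_and_bohlke = frozenset({"2787598", "2735131"})
    assert bare_and_bohlke in by_members
    assert by_members[bare_and_bohlke].attachment == "ambiguous"
    assert frozenset({"4888093"}) in by_members
    assert frozenset({"4888094"}) in by_members


def test_pairwise_authorless_merge():
    clusters = cluster_names(_group("", "Kaup 1829"), 0.8)
    assert len(clusters) == 1
    assert len(clusters[0]) == 2
    assert clusters[0].attachment == "merged"


def test_all_authorless_form_one_cluster():
    # three bare homonym entries, no author anywhere: nothing to separate them
    recs = [NameRecord(record_id=f"r{i}", name_string="Nystactes", source="T") for i in range(3)]
    clusters = cluster_names(recs, 0.8)
    assert len(clusters) == 1 and len(clusters[0]) == 3


def test_high_threshold_only_identical_fingerprints_cocluster():
    group = _group("Gloger 1827", "Gloger, 1827", "Gloger 1828")
    clusters = cluster_names(group, 1.0)
    sizes = sorted(len(c) for c in clusters)
    assert sizes == [1, 2]


def test_rhacophorus_variants_match_oracle(examples):
    group = examples.rhacophorus_variants
    authored = {
        r.record_id: parse_name(r.name_string).authorship
        for r in group
        if parse_name(r.name_string).authorship
    }
    expected = set(transitive_closure_clusters(authored, 0.8))
    clusters = cluster_names(group, 0.8)
    # drop the authorless record before comparing with the authored-only oracle
    bare = {r.record_id for r in group if not parse_name(r.name_string).authorship}
    got = {frozenset(c.member_ids - bare) for c in clusters}
    assert got == expected


def test_partition_and_conservation(examples):
    records = examples.ion_nystactes + examples.rhacophorus_variants
    result = cluster_all(records)
    all_ids = [m for c in result.clusters for m in c.member_ids]
    assert len(all_ids) == len(set(all_ids)) == len(records)


NAMES = ["Gloger", "Gloger 1827", "Gloger, 1827", "Glogar 1827", "Kaup 1829",
         "Kaup, 1829", "Bohlke", "Böhlke 1957", "Bohlke, 1957", "Smith 1900",
         "Smith & Gray 1900", "Gray 1900"]


@given(st.lists(st.sampled_from(NAMES), min_size=1, max_size=12, unique=True),
       st.sampled_from([0.6, 0.8, 0.9]))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_components_match_transitive_closure_oracle(authorships, threshold):
    group = _group(*authorships)
    authored = {r.record_id: parse_name(r.name_string).authorship for r in group}
    expected = set(transitive_closure_clusters(authored, threshold))
    got = {frozenset(c.member_ids) for c in cluster_names(group, threshold)}
    assert got == expected


@given(st.lists(st.sampled_from(NAMES), min_size=2, max_size=10, unique=True))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_raising_threshold_only_refines(authorships):
    group = _group(*authorships)
    lo = {frozenset(c.member_ids) for c in cluster_names(group, 0.6)}
    hi = {frozenset(c.member_ids) for c in cluster_names(group, 0.9)}
    for h in hi:
        assert any(h <= l for l in lo)  # every high-threshold cluster sits inside one low-threshold cluster


def test_fingerprint_identical_always_cocluster():
    for t in (0.5, 0.8, 1.0):
        clusters = cluster_names(_group("Kaup 1829", "Kaup, 1829", "Kaup,  1829."), t)
        assert len(clusters) == 1


def test_cluster_ids_reproducible(examples):
    a = cluster_all(examples.ion_nystactes).clusters
    b = cluster_all(list(reversed(examples.ion_nystactes))).clusters
    assert [c.cluster_id for c in a] == [c.cluster_id for c in b]


def test_empty_and_single():
    assert cluster_all([]).clusters == []
    one = cluster_all(_group("Kaup 1829")).clusters
    assert len(one) == 1 and len(one[0]) == 1


def test_bad_threshold_rejected():
    with pytest.raises(ValueError):
        build_author_graph(_group("Kaup 1829"), 0.0)
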