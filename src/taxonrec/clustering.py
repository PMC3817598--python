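"""Cluster authorship variants of a canonical name into name clusters.

Within each group of records sharing one canonical name, a graph is built
whose nodes are the authored records and whose edges join pairs whose
authorship fingerprints have LCS similarity at or above a threshold
(default 0.8; identical strings score 1.0).  The connected components of
that graph are the name clusters: "Gloger 1827" and "Gloger, 1827" fall in
one cluster, the homonymous "Kaup 1829" in another.

Authorless records ("Nystactes" with no author at all) carry no signal for
the similarity graph.  They are merged into an authored cluster by rule:
with exactly one authored cluster the merge is unambiguous; with several,
the record attaches to the largest cluster (ties broken by the
lexicographically smallest representative authorship) and the cluster is
flagged ``attachment="ambiguous"`` so downstream users can see the call was
a convention, not evidence.  With no authored cluster at all, the
authorless records form one cluster together.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .namemodel import GroupedNames, NameRecord, group_by_canonical, parse_name
from .textnorm import similarity

__all__ = [
    "DEFAULT_THRESHOLD",
    "AuthorGraph",
    "NameCluster",
    "build_author_graph",
    "cluster_names",
    "cluster_all",
    "ClusteringResult",
]

DEFAULT_THRESHOLD = 0.8


@dataclass
class AuthorGraph:
    """Similarity graph over the authored records of one canonical group.

    Every edge carries the pair's similarity score, and only pairs with
    score >= ``threshold`` are connected.  Authorless records are excluded;
    they are handled by the merge rule in :func:`cluster_names`.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="score")
        return g


@dataclass(frozen=True)
class NameCluster:
    """A set of records judged to be the same name.

    ``representative`` is the member with the longest authorship string
    (ties: lexicographically smallest authorship, then smallest record id).
    ``attachment`` records how authorless members joined: "none" (no
    authorless member), "merged" (single authored cluster, forced), or
    "ambiguous" (several authored clusters existed; largest-cluster rule).
    """

    cluster_id: str
    canonical: str
    member_ids: frozenset[str]
    representative: str
    attachment: str = "none"

    def __len__(self) -> int:
        return len(self.member_ids)


def build_author_graph(
    group: Sequence[NameRecord], threshold: float = DEFAULT_THRESHOLD
) -> AuthorGraph:
    """Build the authorship-similarity graph for one canonical group.

    An edge joins two authored records iff the LCS similarity of their
    authorship fingerprints is >= ``threshold``.  No self-edges, no
    duplicates; authorless records do not appear.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    authored = [
        (rec, parse_name(rec.name_string).authorship)
        for rec in group
        if parse_name(rec.name_string).authorship
    ]
    nodes = [rec.record_id for rec, _ in authored]
    edges: list[tuple[str, str, float]] = []
    for i in range(len(authored)):
        for j in range(i + 1, len(authored)):
            s = similarity(authored[i][1], authored[j][1]).score
            if s >= threshold:
                edges.append((authored[i][0].record_id, authored[j][0].record_id, s))
    return AuthorGraph(nodes=nodes, edges=edges, threshold=threshold)


def _make_cluster_id(canonical: str, member_ids: Iterable[str]) -> str:
    # content-derived so identical input always yields identical ids
    h = hashlib.sha1()
    h.update(canonical.encode("utf-8"))
    for mid in sorted(member_ids):
        h.update(b"\x00")
        h.update(mid.encode("utf-8"))
    return h.hexdigest()[:12]


def _representative(members: Sequence[NameRecord]) -> str:
    def key(rec: NameRecord) -> tuple[int, str, str]:
        auth = parse_name(rec.name_string).authorship
        return (-len(auth), auth, rec.record_id)

    return min(members, key=key).record_id


def cluster_names(
    group: Sequence[NameRecord], threshold: float = DEFAULT_THRESHOLD
) -> list[NameCluster]:
    """Cluster one canonical group: graph components + authorless merge.

    Returns a partition of ``group`` (every record in exactly one cluster),
    ordered by cluster id.
    """
    if not group:
        return []
    canonical = parse_name(group[0].name_string).canonical
    by_id = {rec.record_id: rec for rec in group}
    graph = build_author_graph(group, threshold)
    g = graph.to_networkx()
    components: list[set[str]] = [set(c) for c in nx.connected_components(g)]
    authorless = [rec for rec in group if not parse_name(rec.name_string).authorship]

    attachment = "none"
    if authorless:
        if components:
            attachment = "merged" if len(components) == 1 else "ambiguous"
            # attach every authorless record to the largest authored cluster;
            # ties: cluster whose representative authorship is lexicographically smallest
            def comp_key(c: set[str]) -> tuple[int, str]:
                rep = _representative([by_id[m] for m in c])
                return (-len(c), parse_name(by_id[rep].name_string).authorship)

            target = min(components, key=comp_key)
            target.update(rec.record_id for rec in authorless)
        else:
            components = [{rec.record_id for rec in authorless}]
            attachment = "merged"

    clusters = []
    for comp in components:
        members = [by_id[m] for m in comp]
        has_authorless = any(not parse_name(m.name_string).authorship for m in members)
        clusters.append(
            NameCluster(
                cluster_id=_make_cluster_id(canonical, comp),
                canonical=canonical,
                member_ids=frozenset(comp),
                representative=_representative(members),
                attachment=attachment if has_authorless else "none",
            )
        )
    return sorted(clusters, key=lambda c: c.cluster_id)


@dataclass
class ClusteringResult:
    """All clusters plus the records that could not be parsed."""

    clusters: list[NameCluster]
    rejects: list[tuple[NameRecord, str]] = field(default_factory=list)


def cluster_all(
    records: Iterable[NameRecord], threshold: float = DEFAULT_THRESHOLD
) -> ClusteringResult:
    """Group records by canonical name and cluster each group.

    Output is deterministically ordered by (canonical, cluster_id);
    unparseable records are reported, never silently dropped.
    """
    grouped: GroupedNames = group_by_canonical(records)
    clusters: list[NameCluster] = []
    for canonical in sorted(grouped.groups):
        clusters.extend(cluster_names(grouped.groups[canonical], threshold))
    clusters.sort(key=lambda c: (c.canonical, c.cluster_id))
    return ClusteringResult(clusters=clusters, rejects=grouped.rejects)
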