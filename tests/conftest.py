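"""Shared fixtures and independent oracles.

The oracles here deliberately take the dumb-but-obviously-correct route —
exhaustive recursion, full enumeration, transitive closure over a score
matrix — so the production dynamic programme / assignment solver / graph
components are checked against something that shares none of their code.
"""

from __future__ import annotations

from itertools import combinations

import pytest

from taxonrec.datasets import worked_examples
from taxonrec.textnorm import similarity


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


# ---------------------------------------------------------------- oracles


def lcs_recursive(a: str, b: str) -> int:
    """Exhaustive recursive LCS, memoized; independent of the DP rows."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def brute_force_matching(edges: list[tuple[str, str, float]]) -> float:
    """Maximum total weight over ALL matchings, by enumeration over subsets."""
    best = 0.0
    n = len(edges)
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            lefts = [edges[i][0] for i in combo]
            rights = [edges[i][1] for i in combo]
            if len(set(lefts)) != r or len(set(rights)) != r:
                continue
            best = max(best, sum(edges[i][2] for i in combo))
    return best


def transitive_closure_clusters(
    authorships: dict[str, str], threshold: float
) -> list[frozenset[str]]:
    """Cluster authored ids by repeated merging over the pairwise score
    matrix until fixpoint — no graph library involved."""
    clusters = [{k} for k in authorships]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    similarity(authorships[u], authorships[v]).score >= threshold
                    for u in clusters[i]
                    for v in clusters[j]
                ):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c) for c in clusters]
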