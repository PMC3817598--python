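"""Normalize variant and abbreviated journal titles to a registry entry.

A century of citation practice has produced dozens of spellings for most
journals — "Bull Zool Nomen", "Bull. Zool. Nom.", "Bull. Zool. Nomencl."
all mean the *Bulletin of Zoological Nomenclature* (ISSN 0007-5167).
Resolution goes through a registry of canonical titles with ISSNs (OCLC
numbers as fallback identifiers) and known variants, trying in order:

1. exact fingerprint match on the canonical title (score 1.0);
2. exact fingerprint match on a listed variant (score 1.0);
3. abbreviation matching: each query token, stripped of trailing periods,
   must be a prefix of the corresponding canonical-title token, skipping
   connective stopwords (of/the/and/de/der/und); the score is the fraction
   of canonical content tokens the query covers.

Prefix matching, not LCS, because that is how journal abbreviations are
actually formed — LCS over whole titles rewards unrelated journals that
share common words.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .textnorm import fingerprint

__all__ = [
    "JournalEntry",
    "JournalMatch",
    "validate_issn",
    "match_journal",
    "load_registry",
]

_STOPWORDS = {"of", "the", "and", "de", "der", "und"}


def validate_issn(issn: str) -> bool:
    """True iff ``issn`` is NNNN-NNNC with a valid mod-11 check digit.

    The check digit weights the first seven digits 8..2; the total plus the
    check digit (X = 10) must be divisible by 11.

    >>> validate_issn("0007-5167")
    True
    """
    if len(issn) != 9 or issn[4] != "-":
        return False
    digits = issn[:4] + issn[5:]
    if not digits[:7].isdigit() or digits[7] not in "0123456789X":
        return False
    total = sum(int(d) * w for d, w in zip(digits[:7], range(8, 1, -1)))
    check = 10 if digits[7] == "X" else int(digits[7])
    return (total + check) % 11 == 0


@dataclass(frozen=True)
class JournalEntry:
    """One registry row: canonical title, identifiers, known variant titles."""

    canonical_title: str
    issn: str | None = None
    oclc: str | None = None
    variants: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.issn is not None and not validate_issn(self.issn):
            raise ValueError(f"invalid ISSN {self.issn!r} for {self.canonical_title!r}")


@dataclass(frozen=True)
class JournalMatch:
    """Resolution outcome; ``entry`` is None iff ``method`` is "none"."""

    query: str
    entry: JournalEntry | None
    method: str  # exact | variant | abbreviation | none
    score: float


def _content_tokens(title: str) -> list[str]:
    return [t for t in fingerprint(title).value.split() if t not in _STOPWORDS]


def _abbrev_score(query: str, canonical_title: str) -> float | None:
    """Token-coverage score if ``query`` abbreviates ``canonical_title``, else None.

    Query tokens (trailing periods already gone via fingerprinting) must
    each be a prefix of the positionally corresponding canonical content
    token; score = matched / total canonical content tokens.
    """
    q = _content_tokens(query)
    c = _content_tokens(canonical_title)
    if not q or not c or len(q) > len(c):
        return None
    for qt, ct in zip(q, c):
        if not ct.startswith(qt):
            return None
    return len(q) / len(c)


def match_journal(query: str, registry: Sequence[JournalEntry]) -> JournalMatch:
    """Resolve a (possibly abbreviated) journal title against a registry.

    Deterministic and independent of registry row order: candidates at
    equal score are tie-broken by canonical title.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    entries = sorted(registry, key=lambda e: e.canonical_title)
    qfp = fingerprint(query).value

    for entry in entries:
        if fingerprint(entry.canonical_title).value == qfp:
            return JournalMatch(query, entry, "exact", 1.0)
    for entry in entries:
        if any(fingerprint(v).value == qfp for v in entry.variants):
            return JournalMatch(query, entry, "variant", 1.0)

    best: tuple[float, str, JournalEntry] | None = None
    for entry in entries:
        s = _abbrev_score(query, entry.canonical_title)
        if s is not None and (best is None or s > best[0]):
            best = (s, entry.canonical_title, entry)
    if best is not None:
        return JournalMatch(query, best[2], "abbreviation", best[0])
    return JournalMatch(query, None, "none", 0.0)


def load_registry(path: str | Path) -> list[JournalEntry]:
    """Read a registry CSV with columns canonical_title, issn, oclc, variants
    (variants pipe-separated; issn/oclc may be blank)."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"canonical_title"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"registry missing required column: {sorted(missing)[0]}")
        for row in reader:
            variants = frozenset(
                v.strip() for v in (row.get("variants") or "").split("|") if v.strip()
            )
            entries.append(
                JournalEntry(
                    canonical_title=row["canonical_title"].strip(),
                    issn=(row.get("issn") or "").strip() or None,
                    oclc=(row.get("oclc") or "").strip() or None,
                    variants=variants,
                )
            )
    titles = [e.canonical_title for e in entries]
    if len(titles) != len(set(titles)):
        raise ValueError("duplicate canonical_title in registry")
    return entries
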