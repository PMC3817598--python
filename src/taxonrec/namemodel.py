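"""Record types and the canonical/authorship split for zoological names.

A zoological name string such as ``Homo sapiens Linnaeus`` is the canonical
name (``Homo sapiens``) plus an authorship string (``Linnaeus``, possibly
with a year, possibly parenthesized to mark a recombination).  Nomenclators
never store these parts separately in their dumps, and no formal grammar
exists for the split, so :func:`parse_name` applies a documented,
deterministic heuristic with an explicit reject path: the canonical part is
the leading run of Latin name words (genus, optional parenthesized subgenus,
up to two lowercase epithets) and the authorship is everything after it.

Strings this package does not attempt to parse (botanical rank markers like
"var.", hybrid signs, strings with no leading capitalized word) raise
:class:`NameParseError` and are routed to reject lists by the callers rather
than silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

from .textnorm import Fingerprint, fingerprint

__all__ = [
    "NameRecord",
    "ParsedName",
    "NameParseError",
    "GroupedNames",
    "parse_name",
    "group_by_canonical",
]

YEAR_MIN, YEAR_MAX = 1750, 2100

# Genus / subgenus: capitalized Latin word, accents allowed ("Günther").
_GENUS = re.compile(r"^[A-ZÀ-Þ][a-zà-ÿ'-]+$")
# Species / subspecies epithet: all-lowercase Latin word.
_EPITHET = re.compile(r"^[a-zà-ÿ][a-zà-ÿ'-]*$")
_SUBGENUS = re.compile(r"^\(([A-ZÀ-Þ][a-zà-ÿ'-]+)\)$")
# Surname particles: lowercase, but open an authorship ("van Hasselt"), not an epithet.
_PARTICLES = {"de", "van", "von", "der", "den", "du", "la", "le", "di"}
# Infraspecific rank markers and hybrid signs we deliberately do not parse.
_REJECT_TOKENS = {"var.", "subsp.", "ssp.", "f.", "forma", "×", "x"}


class NameParseError(ValueError):
    """Raised for a name string the heuristic cannot split."""


@dataclass(frozen=True)
class NameRecord:
    """One name string from one source database.

    ``record_id`` is whatever the source uses — an LSID like
    ``urn:lsid:organismnames.com:name:2787598`` or a bare numeric key.
    ``published_in`` carries the raw citation string when the dump has one.
    """

    record_id: str
    name_string: str
    source: str = ""
    published_in: str | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.name_string or not self.name_string.strip():
            raise ValueError("name_string must be non-empty")


@dataclass(frozen=True)
class ParsedName:
    """Canonical name + authorship split of a name string.

    ``in_parentheses`` flags a parenthesized (recombined) authorship; the
    parentheses are kept verbatim in ``authorship`` but vanish from the
    fingerprint, where they count as punctuation.
    """

    canonical: str
    authorship: str
    year: int | None = None
    in_parentheses: bool = False
    authorship_fingerprint: Fingerprint = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.authorship_fingerprint is None:
            object.__setattr__(self, "authorship_fingerprint", fingerprint(self.authorship))
        if not self.canonical:
            raise ValueError("canonical must be non-empty")
        if any(c.isdigit() for c in self.canonical):
            raise ValueError(f"canonical contains digits: {self.canonical!r}")
        if self.year is not None and not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")


def _extract_year(authorship: str) -> int | None:
    m = re.search(r"\b(1[7-9]\d{2}|20\d{2})\b", authorship)
    if m:
        y = int(m.group(1))
        if YEAR_MIN <= y <= YEAR_MAX:
            return y
    return None


@lru_cache(maxsize=16384)
def parse_name(name_string: str) -> ParsedName:
    """Split a full name string into canonical name and authorship.

    The canonical part is the longest leading run of: a capitalized genus
    word, an optional single parenthesized capitalized subgenus, then up to
    two all-lowercase epithets.  Authorship starts at the first token that
    breaks this pattern — a capitalized surname, ``(``, a 4-digit year, a
    word with an internal capital ("McCoy") or period ("L.").  The year is
    the first 4-digit token in the authorship, if any.

    >>> p = parse_name("Nystactes Gloger 1827")
    >>> p.canonical, p.authorship, p.year
    ('Nystactes', 'Gloger 1827', 1827)

    Raises :class:`NameParseError` for strings with no leading capitalized
    Latin word, or containing rank markers / hybrid signs.
    """
    tokens = name_string.split()
    if not tokens:
        raise NameParseError("empty name string")
    for t in tokens:
        if t.lower() in _REJECT_TOKENS:
            raise NameParseError(f"unsupported name construct {t!r} in {name_string!r}")
    if not _GENUS.match(tokens[0]):
        raise NameParseError(f"no leading capitalized Latin word in {name_string!r}")

    canonical = [tokens[0]]
    i = 1
    # optional subgenus: single parenthesized capitalized word, no digits
    if i < len(tokens) and _SUBGENUS.match(tokens[i]):
        canonical.append(tokens[i])
        i += 1
    # up to two lowercase epithets (species, subspecies)
    n_epithets = 0
    while i < len(tokens) and n_epithets < 2 and _EPITHET.match(tokens[i]):
        # "van" in "Rana van Hasselt" is a surname particle, not an epithet
        if tokens[i] in _PARTICLES and i + 1 < len(tokens) and _GENUS.match(tokens[i + 1]):
            break
        canonical.append(tokens[i])
        i += 1
        n_epithets += 1

    authorship = " ".join(tokens[i:])
    in_parens = authorship.startswith("(") and authorship.endswith(")")
    return ParsedName(
        canonical=" ".join(canonical),
        authorship=authorship,
        year=_extract_year(authorship),
        in_parentheses=in_parens,
    )


@dataclass
class GroupedNames:
    """Partition of records by exact canonical name, plus the reject list."""

    groups: dict[str, list[NameRecord]]
    rejects: list[tuple[NameRecord, str]]

    def n_accepted(self) -> int:
        return sum(len(g) for g in self.groups.values())


def group_by_canonical(records: Iterable[NameRecord]) -> GroupedNames:
    """Partition ``records`` by the exact canonical component of their name.

    Unparseable records land on ``rejects`` with the parse error message;
    every parseable record appears in exactly one group.
    """
    groups: dict[str, list[NameRecord]] = {}
    rejects: list[tuple[NameRecord, str]] = []
    for rec in records:
        try:
            parsed = parse_name(rec.name_string)
        except NameParseError as exc:
            rejects.append((rec, str(exc)))
            continue
        groups.setdefault(parsed.canonical, []).append(rec)
    return GroupedNames(groups=groups, rejects=rejects)
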