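"""Parse taxonomic "published in" citation strings into structured parts.

Nomenclators attach free-text citation strings to names, e.g.::

    Description of a new species of Pinnotheres, and redescription of
    P. novaezelandiae (Brachyura: Pinnotheridae). New Zealand Journal of
    Zoology, 10(2) 1983: 151-162. 158 (Zoological Record Volume 120)

The structure is conventional — title, journal, volume(issue) year: pages,
an optional single "cited page" (the page on which the name itself appears)
and an optional trailing parenthetical note — but never formally specified,
so parsing is a bank of ordered regular expressions: the first pattern that
matches wins, and a string no pattern matches comes back as a structured
failure, never an exception.  The bank is data (ids + patterns), so new
patterns appended at the end cannot change the result for strings already
matched by earlier ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

__all__ = [
    "ParsedCitation",
    "CitationParseFailure",
    "CitationPattern",
    "PATTERN_BANK",
    "parse_citation",
    "to_openurl",
]

YEAR_MIN, YEAR_MAX = 1750, 2100

# page-range dashes: hyphen, en-dash, em-dash all accepted, en-dash canonical
_DASH = r"[-–—]"


@dataclass(frozen=True)
class ParsedCitation:
    """Bibliographic components of a successfully parsed citation string."""

    title: str
    journal: str
    volume: str
    year: int
    start_page: str
    issue: str | None = None
    end_page: str | None = None
    cited_page: str | None = None
    note: str | None = None
    matched_pattern: str = ""

    def __post_init__(self) -> None:
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}]")
        if (
            self.end_page is not None
            and self.start_page.isdigit()
            and self.end_page.isdigit()
            and int(self.start_page) > int(self.end_page)
        ):
            raise ValueError(f"page range reversed: {self.start_page}>{self.end_page}")


@dataclass(frozen=True)
class CitationParseFailure:
    """No pattern matched (or the match failed validation); carries the raw text."""

    raw: str
    status: str = "unparsed"


@dataclass(frozen=True)
class CitationPattern:
    """One entry of the ordered regex bank."""

    pattern_id: str
    regex: re.Pattern
    description: str


def _p(pattern_id: str, pattern: str, description: str) -> CitationPattern:
    return CitationPattern(pattern_id, re.compile(pattern), description)


# Ordered: first match wins.  Appending new patterns at the end cannot
# change the outcome for strings matched by earlier ones.
PATTERN_BANK: list[CitationPattern] = [
    _p(
        "article-full",
        r"^(?P<title>.+?)\.\s+"
        r"(?P<journal>[^,.]+),?\s+"
        r"(?P<volume>\d+[A-Za-z]?)\s*(?:\((?P<issue>[^)]+)\))?\s+"
        r"(?P<year>\d{4})\s*:\s*"
        r"(?P<start_page>\d+)(?:" + _DASH + r"(?P<end_page>\d+))?\.?"
        r"(?:\s+(?P<cited_page>\d+))?"
        r"(?:\s*\((?P<note>[^()]*)\))?\s*$",
        "Title. Journal, Volume(Issue) Year: Start-End. CitedPage (Note) — "
        "journal written out in full (no internal periods or commas)",
    ),
    _p(
        "article-abbrev-journal",
        r"^(?P<title>.+?)\.\s+"
        r"(?P<journal>(?:[A-Z][A-Za-z]*\.?\s+)*[A-Z][A-Za-z]*\.?),?\s+"
        r"(?P<volume>\d+[A-Za-z]?)\s*(?:\((?P<issue>[^)]+)\))?\s+"
        r"(?P<year>\d{4})\s*:\s*"
        r"(?P<start_page>\d+)(?:" + _DASH + r"(?P<end_page>\d+))?\.?"
        r"(?:\s+(?P<cited_page>\d+))?"
        r"(?:\s*\((?P<note>[^()]*)\))?\s*$",
        "Same shape with an abbreviated journal (capitalized dotted tokens)",
    ),
    _p(
        "journal-only",
        r"^(?P<journal>[^,.]+),?\s+"
        r"(?P<volume>\d+[A-Za-z]?)\s*(?:\((?P<issue>[^)]+)\))?\s+"
        r"(?P<year>\d{4})\s*:\s*"
        r"(?P<start_page>\d+)(?:" + _DASH + r"(?P<end_page>\d+))?\.?"
        r"(?:\s+(?P<cited_page>\d+))?"
        r"(?:\s*\((?P<note>[^()]*)\))?\s*$",
        "No article title: Journal, Volume(Issue) Year: Pages",
    ),
]


def parse_citation(raw: str) -> Union[ParsedCitation, CitationParseFailure]:
    """Parse a citation string against the ordered pattern bank.

    Returns a :class:`ParsedCitation` for the first pattern that matches and
    validates (year range, page order), otherwise a
    :class:`CitationParseFailure` carrying the raw string.  Only an empty
    input is an error.
    """
    if not raw or not raw.strip():
        raise ValueError("citation string must be non-empty")
    text = raw.strip()
    for entry in PATTERN_BANK:
        m = entry.regex.match(text)
        if not m:
            continue
        g = m.groupdict()
        try:
            return ParsedCitation(
                title=(g.get("title") or "").strip(),
                journal=g["journal"].strip(),
                volume=g["volume"],
                issue=g.get("issue"),
                year=int(g["year"]),
                start_page=g["start_page"],
                end_page=g.get("end_page"),
                cited_page=g.get("cited_page"),
                note=g.get("note"),
                matched_pattern=entry.pattern_id,
            )
        except ValueError:
            continue  # matched the shape but failed validation; try next pattern
    return CitationParseFailure(raw=text)


# ParsedCitation field -> OpenURL 1.0 key (journal article format)
_OPENURL_KEYS = {
    "title": "rft.atitle",
    "journal": "rft.jtitle",
    "volume": "rft.volume",
    "issue": "rft.issue",
    "year": "rft.date",
    "start_page": "rft.spage",
    "end_page": "rft.epage",
    # no standard OpenURL key exists for these; carried as extension keys
    "cited_page": "rft_dat.cited_page",
    "note": "rft_dat.note",
}


def to_openurl(parsed: ParsedCitation) -> dict[str, str]:
    """Render a parsed citation as OpenURL 1.0 key/value pairs.

    Lossless for populated bibliographic fields: each appears under exactly
    one key; empty/absent fields produce no key.  ``matched_pattern`` is
    parser provenance, not bibliography, and is not emitted.
    """
    out: dict[str, str] = {}
    for fld, key in _OPENURL_KEYS.items():
        value = getattr(parsed, fld)
        if value is None or value == "":
            continue
        out[key] = str(value)
    return out
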