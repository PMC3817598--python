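"""Worked examples shipped as typed records.

These are the published database records this package's methods were
designed around, verbatim with their identifiers:

* the four ION (Index of Organism Names) records for the genus *Nystactes*
  — a triple homonym (a fish, a bird, a bat) plus a bare authorless entry —
  and the three GBIF taxa carrying the same name with different
  punctuation and year conventions;
* a "published in" citation string for *Pinnotheres atrinicola* together
  with the DOI it is known to resolve to (kept as expected-identifier
  metadata; no lookup is performed here);
* the *Bulletin of Zoological Nomenclature* abbreviation variants and a
  small journal registry around them.

:func:`rhacophorus_variants` is a synthetic stand-in: a constructed list of
*Rhacophorus* authorship variants exercising the same accent / punctuation
/ year / misspelling variation, with cluster structure verified by the
in-repo oracle, not taken from any published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .journals import JournalEntry
from .namemodel import NameRecord

__all__ = [
    "ion_nystactes",
    "gbif_nystactes",
    "pinnotheres_citation",
    "bulletin_variants",
    "journal_registry",
    "rhacophorus_variants",
    "worked_examples",
    "WorkedExamples",
]


def ion_nystactes() -> list[NameRecord]:
    """The four ION records for the genus name *Nystactes*."""
    rows = [
        ("urn:lsid:organismnames.com:name:2787598", "Nystactes"),
        ("urn:lsid:organismnames.com:name:2735131", "Nystactes Bohlke"),
        ("urn:lsid:organismnames.com:name:4888093", "Nystactes Gloger 1827"),
        ("urn:lsid:organismnames.com:name:4888094", "Nystactes Kaup 1829"),
    ]
    return [NameRecord(record_id=i, name_string=n, source="ION") for i, n in rows]


def gbif_nystactes() -> list[NameRecord]:
    """The three GBIF taxa named *Nystactes* (ids are GBIF species ids)."""
    rows = [
        ("2403398", "Nystactes Bohlke, 1957"),
        ("2475109", "Nystactes Gloger, 1827"),
        ("3239722", "Nystactes Kaup, 1829"),
    ]
    return [NameRecord(record_id=i, name_string=n, source="GBIF") for i, n in rows]


#: citation string attached to *Pinnotheres atrinicola*
#: (urn:lsid:organismnames.com:name:371873)
PINNOTHERES_CITATION = (
    "Description of a new species of Pinnotheres, and redescription of "
    "P. novaezelandiae (Brachyura: Pinnotheridae). New Zealand Journal of "
    "Zoology, 10(2) 1983: 151–162. 158 (Zoological Record Volume 120)"
)

#: the DOI this citation is known to resolve to (expected-identifier
#: metadata for tests; this package performs no lookups)
PINNOTHERES_DOI = "10.1080/03014223.1983.10423904"


def pinnotheres_citation() -> str:
    return PINNOTHERES_CITATION


#: recorded abbreviation variants of the Bulletin of Zoological Nomenclature
BULLETIN_VARIANTS = ["Bull Zool Nomen", "Bull Zool Nom.", "Bull. Zool. Nomencl."]


def bulletin_variants() -> list[str]:
    return list(BULLETIN_VARIANTS)


def journal_registry() -> list[JournalEntry]:
    """A small registry: the Bulletin entry plus distractor journals."""
    return [
        JournalEntry(
            canonical_title="Bulletin of Zoological Nomenclature",
            issn="0007-5167",
            variants=frozenset(BULLETIN_VARIANTS),
        ),
        JournalEntry(
            canonical_title="Proceedings of the Entomological Society of Washington",
            issn="0013-8797",
        ),
        JournalEntry(
            canonical_title="New Zealand Journal of Zoology",
            issn="0301-4223",
        ),
        JournalEntry(
            canonical_title="Bulletin of the Museum of Comparative Zoology",
            oclc="1537774",
        ),
    ]


def rhacophorus_variants() -> list[NameRecord]:
    """Synthetic *Rhacophorus* authorship variants (constructed, not from
    any published source): two true names — Kuhl & Van Hasselt's frog genus
    under several spellings, and a fictitious homonym — plus a bare entry."""
    rows = [
        ("syn:rh:1", "Rhacophorus Kuhl 1822"),
        ("syn:rh:2", "Rhacophorus Kuhl, 1822"),
        ("syn:rh:3", "Rhacophorus Kuhl and Hasselt 1822"),
        ("syn:rh:4", "Rhacophorus Kuhl & Hasselt, 1822"),
        ("syn:rh:5", "Rhacophorus Gistel 1848"),
        ("syn:rh:6", "Rhacophorus"),
    ]
    return [NameRecord(record_id=i, name_string=n, source="SYN") for i, n in rows]


@dataclass(frozen=True)
class WorkedExamples:
    """Bundle of all shipped examples."""

    ion_nystactes: list[NameRecord] = field(default_factory=ion_nystactes)
    gbif_nystactes: list[NameRecord] = field(default_factory=gbif_nystactes)
    pinnotheres_citation: str = PINNOTHERES_CITATION
    pinnotheres_doi: str = PINNOTHERES_DOI
    bulletin_variants: tuple[str, ...] = tuple(BULLETIN_VARIANTS)
    journal_registry: list[JournalEntry] = field(default_factory=journal_registry)
    rhacophorus_variants: list[NameRecord] = field(default_factory=rhacophorus_variants)


def worked_examples() -> WorkedExamples:
    """All shipped examples as one typed bundle."""
    return WorkedExamples()
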