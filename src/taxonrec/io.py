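"""Readers, writers, and JSON-lines document export.

Name tables arrive as TSV/CSV (header row required; columns ``record_id``
and ``name_string``, optional ``source`` and ``published_in``) or as
JSON-lines with the same keys.  Malformed rows are collected in a reject
report with line numbers, never dropped silently; a missing required
column is a schema error naming the column.

Export bundles each name cluster into one self-contained JSON document —
the cluster, its member records, any parsed citations for those members,
and any cross-database matching pairs that touch them — one document per
line, keys sorted, so identical input yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

from .citations import CitationParseFailure, ParsedCitation
from .clustering import NameCluster
from .mapping import Matching
from .namemodel import NameRecord

__all__ = [
    "SchemaError",
    "ConsistencyError",
    "RejectedRow",
    "ReadResult",
    "read_name_table",
    "write_name_table",
    "export_documents",
]

REQUIRED_COLUMNS = ("record_id", "name_string")
OPTIONAL_COLUMNS = ("source", "published_in")


class SchemaError(ValueError):
    """Input lacks a required column."""


class ConsistencyError(ValueError):
    """A document references an id not defined within it."""


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    raw: str


@dataclass
class ReadResult:
    records: list[NameRecord]
    rejects: list[RejectedRow] = field(default_factory=list)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".tsv": "tsv", ".csv": "csv", ".jsonl": "jsonl", ".ndjson": "jsonl"}.get(
        suffix, "tsv"
    )


def _row_to_record(row: dict, line_number: int, rejects: list[RejectedRow]) -> NameRecord | None:
    rid = (row.get("record_id") or "").strip()
    name = (row.get("name_string") or "").strip()
    if not rid or not name:
        missing = "record_id" if not rid else "name_string"
        rejects.append(RejectedRow(line_number, f"blank {missing}", json.dumps(row, ensure_ascii=False)))
        return None
    return NameRecord(
        record_id=rid,
        name_string=name,
        source=(row.get("source") or "").strip(),
        published_in=(row.get("published_in") or "").strip() or None,
    )


def read_name_table(
    path: str | Path, format: str | None = None, encoding: str = "utf-8"
) -> ReadResult:
    """Read name records from a delimited or JSON-lines file.

    ``format`` is one of tsv/csv/jsonl, inferred from the extension when
    omitted.  Raises :class:`SchemaError` if a required column is absent;
    malformed rows go to ``rejects`` with their line numbers.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    records: list[NameRecord] = []
    rejects: list[RejectedRow] = []

    if fmt == "jsonl":
        with open(path, encoding=encoding) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    rejects.append(RejectedRow(lineno, f"bad JSON: {exc.msg}", line))
                    continue
                missing = [c for c in REQUIRED_COLUMNS if c not in row]
                if missing:
                    raise SchemaError(f"missing required column: {missing[0]}")
                rec = _row_to_record(row, lineno, rejects)
                if rec:
                    records.append(rec)
        return ReadResult(records, rejects)

    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    import csv as _csv

    delim = "\t" if fmt == "tsv" else ","
    with open(path, newline="", encoding=encoding) as fh:
        reader = _csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column: {col}")
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            rec = _row_to_record(row, lineno, rejects)
            if rec:
                records.append(rec)
    return ReadResult(records, rejects)


def write_name_table(
    records: Iterable[NameRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records in any of the three readable formats (round-trips)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    records = list(records)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(dataclasses.asdict(rec), ensure_ascii=False, sort_keys=True))
                fh.write("\n")
        return
    import csv as _csv

    delim = "\t" if fmt == "tsv" else ","
    cols = list(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.DictWriter(fh, fieldnames=cols, delimiter=delim)
        writer.writeheader()
        for rec in records:
            row = dataclasses.asdict(rec)
            row["published_in"] = row["published_in"] or ""
            writer.writerow(row)


def _citation_to_dict(c: Union[ParsedCitation, CitationParseFailure]) -> dict:
    d = dataclasses.asdict(c)
    d["status"] = "parsed" if isinstance(c, ParsedCitation) else "unparsed"
    return d


def export_documents(
    clusters: Sequence[NameCluster],
    records: Sequence[NameRecord],
    citations: dict[str, Union[ParsedCitation, CitationParseFailure]] | None = None,
    matching: Matching | None = None,
    stream: IO[str] | None = None,
) -> list[str]:
    """Render one self-contained JSON document per cluster.

    Each document embeds the cluster, its member records, the parsed
    citations keyed by member id, and the matching pairs touching members.
    Documents are emitted sorted by (canonical, cluster_id) with sorted
    keys: identical input gives byte-identical output.  A cluster member
    with no record, or a citation/matching id not among the members, raises
    :class:`ConsistencyError`.  Returns the lines (and writes them to
    ``stream`` if given).
    """
    by_id = {rec.record_id: rec for rec in records}
    citations = citations or {}
    pairs = matching.pairs if matching else []
    lines: list[str] = []
    for cluster in sorted(clusters, key=lambda c: (c.canonical, c.cluster_id)):
        members = sorted(cluster.member_ids)
        for mid in members:
            if mid not in by_id:
                raise ConsistencyError(f"cluster {cluster.cluster_id} references unknown id {mid!r}")
        doc_citations = {}
        for mid, cit in citations.items():
            if mid in cluster.member_ids:
                doc_citations[mid] = _citation_to_dict(cit)
        links = [
            {"left_id": l, "right_id": r, "weight": w}
            for l, r, w in pairs
            if l in cluster.member_ids or r in cluster.member_ids
        ]
        # keep the document self-contained: embed link partners too
        partner_ids = sorted(
            {x for link in links for x in (link["left_id"], link["right_id"])}
            - cluster.member_ids
        )
        for pid in partner_ids:
            if pid not in by_id:
                raise ConsistencyError(
                    f"cluster {cluster.cluster_id} links to unknown id {pid!r}"
                )
        doc = {
            "cluster_id": cluster.cluster_id,
            "canonical": cluster.canonical,
            "attachment": cluster.attachment,
            "representative": cluster.representative,
            "names": [dataclasses.asdict(by_id[mid]) for mid in members],
            "linked_records": [dataclasses.asdict(by_id[pid]) for pid in partner_ids],
            "citations": doc_citations,
            "taxon_links": links,
        }
        lines.append(json.dumps(doc, ensure_ascii=False, sort_keys=True))
    if stream is not None:
        for line in lines:
            stream.write(line + "\n")
    return lines
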