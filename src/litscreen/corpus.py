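"""Bibliographic corpus I/O, eligibility filtering and reading-list reports.

Records carry a title/abstract pair, light bibliographic metadata and an
optional gold relevance label assigned by manual screening.  Supported
on-disk formats are delimited text (CSV/TSV with a configurable column map)
and a common RIS dialect (TY/ER framing; TI, AB, PY, LA, KW, ID tags).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
UNLABELED = "unlabeled"
_LABELS = {RELEVANT, IRRELEVANT, UNLABELED}

#: default CSV/TSV column names -> record fields
DEFAULT_COLUMN_MAP = {
    "doc_id": "doc_id",
    "title": "title",
    "abstract": "abstract",
    "year": "year",
    "language": "language",
    "mesh_terms": "mesh_terms",
    "label": "label",
}

_LABEL_ALIASES = {
    "relevant": RELEVANT, "1": RELEVANT, "true": RELEVANT, "yes": RELEVANT,
    "irrelevant": IRRELEVANT, "0": IRRELEVANT, "false": IRRELEVANT, "no": IRRELEVANT,
    "unlabeled": UNLABELED, "unlabelled": UNLABELED, "": UNLABELED,
}


@dataclass
class DocumentRecord:
    """One bibliographic record with optional gold relevance label."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    language: str | None = None
    mesh_terms: list[str] = field(default_factory=list)
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(
                f"label must be one of {sorted(_LABELS)}, got {self.label!r}"
            )

    @property
    def label01(self) -> int:
        """Gold label as 0/1; raises on unlabeled records."""
        if self.label == UNLABELED:
            raise ValueError(f"record {self.doc_id!r} is unlabeled")
        return 1 if self.label == RELEVANT else 0


@dataclass
class EligibilityRules:
    """Record-level inclusion rules applied before any modelling.

    Defaults mirror a screening protocol restricted to English-language
    records with a non-empty abstract published 2006-2017.  Records with
    missing language (or year) pass the corresponding rule by default.
    """

    require_abstract: bool = True
    year_range: tuple[int, int] | None = (2006, 2017)
    languages: frozenset[str] = frozenset({"en", "eng", "english"})
    missing_language_passes: bool = True
    missing_year_passes: bool = True

    #: fixed attribution order: a record is counted under its FIRST failing rule
    RULE_ORDER = ("abstract", "year", "language")

    def failing_rule(self, record: DocumentRecord) -> str | None:
        if self.require_abstract and not record.abstract.strip():
            return "abstract"
        if self.year_range is not None:
            if record.year is None:
                if not self.missing_year_passes:
                    return "year"
            elif not (self.year_range[0] <= record.year <= self.year_range[1]):
                return "year"
        if self.languages is not None:
            if record.language is None or not record.language.strip():
                if not self.missing_language_passes:
                    return "language"
            elif record.language.strip().lower() not in self.languages:
                return "language"
        return None


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    counts_excluded_by_rule: dict[str, int]

    def __str__(self) -> str:
        lines = [f"input records:    {self.n_input}",
                 f"retained records: {self.n_retained}"]
        for rule, n in self.counts_excluded_by_rule.items():
            lines.append(f"excluded by {rule!r}: {n}")
        return "\n".join(lines)


def _parse_label(raw: str) -> str:
    key = raw.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized label {raw!r}")
    return _LABEL_ALIASES[key]


def _parse_year(raw: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    # RIS PY fields are often "2012/03//"
    head = raw.split("/")[0].strip()
    return int(head)


def _check_unique_ids(records: Sequence[DocumentRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.doc_id in seen:
            raise ValueError(f"duplicate doc_id {rec.doc_id!r} in corpus")
        seen.add(rec.doc_id)


def _read_delimited(path: Path, sep: str, column_map: Mapping[str, str]) -> list[DocumentRecord]:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map["doc_id"] not in frame.columns:
        raise ValueError(f"missing id column {column_map['doc_id']!r} in {path}")
    records = []
    for _, row in frame.iterrows():
        def get(fld: str) -> str:
            col = column_map.get(fld)
            return str(row[col]) if col in frame.columns else ""

        mesh_raw = get("mesh_terms")
        records.append(DocumentRecord(
            doc_id=str(row[column_map["doc_id"]]),
            title=get("title"),
            abstract=get("abstract"),
            year=_parse_year(get("year")),
            language=get("language").strip() or None,
            mesh_terms=[m.strip() for m in mesh_raw.split(";") if m.strip()],
            label=_parse_label(get("label")),
        ))
    return records


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  ?- ?(.*)$")


def _read_ris(path: Path) -> list[DocumentRecord]:
    records: list[DocumentRecord] = []
    current: dict[str, list[str]] | None = None
    last_tag: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            match = _RIS_TAG.match(line)
            if match is None:
                # continuation of the previous tag's value
                if current is not None and last_tag and line.strip():
                    current[last_tag][-1] += " " + line.strip()
                continue
            tag, value = match.group(1), match.group(2).strip()
            if tag == "TY":
                current, last_tag = {"TY": [value]}, tag
            elif current is None:
                continue
            elif tag == "ER":
                records.append(_ris_to_record(current, len(records)))
                current, last_tag = None, None
            else:
                current.setdefault(tag, []).append(value)
                last_tag = tag
    return records


def _ris_to_record(fields: dict[str, list[str]], index: int) -> DocumentRecord:
    def first(tag: str) -> str:
        return fields.get(tag, [""])[0]

    doc_id = first("ID") or first("AN") or f"ris-{index + 1:04d}"
    return DocumentRecord(
        doc_id=doc_id,
        title=first("TI") or first("T1"),
        abstract=first("AB") or first("N2"),
        year=_parse_year(first("PY")),
        language=first("LA").strip() or None,
        mesh_terms=[kw for kw in fields.get("KW", []) if kw],
        label=_parse_label(first("LB")),
    )


def read_corpus(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[DocumentRecord]:
    """Read a corpus file into records.

    ``format`` is one of ``csv``, ``tsv``, ``ris``; inferred from the file
    extension when omitted.  Raises on unknown formats and duplicate ids.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if format == "csv":
        records = _read_delimited(path, ",", cmap)
    elif format == "tsv":
        records = _read_delimited(path, "\t", cmap)
    elif format == "ris":
        records = _read_ris(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    _check_unique_ids(records)
    return records


def write_corpus(records: Iterable[DocumentRecord], path: str | Path) -> None:
    """Write records as CSV in the default column layout (round-trips read_corpus)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_COLUMN_MAP))
        for rec in records:
            writer.writerow([
                rec.doc_id, rec.title, rec.abstract,
                "" if rec.year is None else rec.year,
                rec.language or "",
                ";".join(rec.mesh_terms),
                "" if rec.label == UNLABELED else rec.label,
            ])


def apply_eligibility_filters(
    records: Sequence[DocumentRecord],
    rules: EligibilityRules | None = None,
) -> tuple[list[DocumentRecord], FilterReport]:
    """Drop ineligible records; tally exclusions by first failing rule."""
    rules = rules or EligibilityRules()
    retained: list[DocumentRecord] = []
    counts = {rule: 0 for rule in rules.RULE_ORDER}
    for rec in records:
        failing = rules.failing_rule(rec)
        if failing is None:
            retained.append(rec)
        else:
            counts[failing] += 1
    report = FilterReport(
        n_input=len(records),
        n_retained=len(retained),
        counts_excluded_by_rule=counts,
    )
    assert report.n_input == report.n_retained + sum(counts.values())
    return retained, report


def write_ranked_list(
    records: Sequence[DocumentRecord],
    scores: Sequence[float],
    path: str | Path,
) -> None:
    """Write the prioritized reading list: highest predicted relevance first.

    Ties are broken by doc_id ascending so output is reproducible.
    """
    if len(records) != len(scores):
        raise ValueError(
            f"{len(records)} records but {len(scores)} scores"
        )
    order = sorted(range(len(records)),
                   key=lambda i: (-float(scores[i]), records[i].doc_id))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["doc_id", "score", "label"])
        for i in order:
            rec = records[i]
            writer.writerow([
                rec.doc_id, repr(float(scores[i])),
                "" if rec.label == UNLABELED else rec.label,
            ])


def disagreement_report(
    records: Sequence[DocumentRecord],
    scores: Sequence[float],
    k: int,
) -> list[DocumentRecord]:
    """Top-k records whose predicted probability most contradicts the gold label.

    These are candidates for a second round of human review: high scores on
    records labeled irrelevant (possible screening misses) and low scores on
    records labeled relevant (possible over-inclusion).
    """
    if len(records) != len(scores):
        raise ValueError(f"{len(records)} records but {len(scores)} scores")
    if k < 0:
        raise ValueError("k must be >= 0")
    discrepancies = [abs(float(s) - rec.label01) for rec, s in zip(records, scores)]
    order = sorted(range(len(records)),
                   key=lambda i: (-discrepancies[i], records[i].doc_id))
    return [records[i] for i in order[:k]]


def labels01(records: Sequence[DocumentRecord]):
    """Gold labels of a fully labeled corpus as a 0/1 list."""
    return [rec.label01 for rec in records]
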