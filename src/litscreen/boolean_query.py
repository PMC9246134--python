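"""Deterministic keyword-guided screening: FSW AND (HIV OR Violence).

Matching happens on raw surface tokens (lowercased, punctuation-stripped)
of title+abstract, without stop-word removal, lemmatization or stemming.
MeSH terms match a record's controlled-vocabulary headings; text-word (TW)
terms match as consecutive token phrases, with an optional trailing
wildcard giving prefix truncation on the last pattern word ("violen*"
matches both "violence" and "violent").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus import DocumentRecord

MESH = "mesh"
TEXT = "text"

CATEGORY_NAMES = ("FSW", "HIV", "Violence")


@dataclass(frozen=True)
class QueryTerm:
    pattern: str        # lowercase, possibly multi-word
    wildcard: bool      # prefix match on the last word
    field: str          # "mesh" or "text"

    def __post_init__(self) -> None:
        if not self.pattern or self.pattern != self.pattern.strip().lower():
            raise ValueError(f"pattern must be non-empty lowercase, got {self.pattern!r}")
        if self.field not in (MESH, TEXT):
            raise ValueError(f"field must be mesh or text, got {self.field!r}")


@dataclass
class CategoryQuery:
    name: str
    terms: list[QueryTerm]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"category {self.name!r} has no terms")


def _parse_pattern(raw: str, field: str) -> QueryTerm:
    raw = raw.strip().lower()
    wildcard = raw.endswith("*")
    return QueryTerm(pattern=raw.rstrip("*").strip(), wildcard=wildcard, field=field)


def load_query_config(path: str | Path | None = None) -> dict[str, CategoryQuery]:
    """Load the three-category query config (packaged screening query by default)."""
    if path is None:
        path = resources.files("litscreen.data").joinpath("queries.yml")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    queries = {}
    for name, block in raw.items():
        terms = [_parse_pattern(p, MESH) for p in block.get("mesh", [])]
        terms += [_parse_pattern(p, TEXT) for p in block.get("text", [])]
        queries[name] = CategoryQuery(name=name, terms=terms)
    return queries


_NON_LETTER = re.compile(r"[^a-z]+")


def _surface_tokens(text: str) -> list[str]:
    """Raw matching tokens: lowercase, split on any non-letter run.

    Splitting on punctuation (not just whitespace) lets phrases like
    "HIV/AIDS" match the terms "hiv" and "aids", mirroring how database
    text-word queries tokenize.  No stop-word, lemma or stem processing.
    """
    return [tok for tok in _NON_LETTER.split(text.lower()) if tok]


def _phrase_match(tokens: Sequence[str], words: Sequence[str], wildcard: bool) -> bool:
    n = len(words)
    if n == 0 or len(tokens) < n:
        return False
    for start in range(len(tokens) - n + 1):
        window = tokens[start:start + n]
        head_ok = all(window[i] == words[i] for i in range(n - 1))
        if not head_ok:
            continue
        last = window[n - 1]
        if last.startswith(words[-1]) if wildcard else last == words[-1]:
            return True
    return False


def match_term(
    record: DocumentRecord,
    term: QueryTerm,
    mesh_fallback_to_text: bool = True,
) -> bool:
    """Does one query term hit one record?

    MeSH terms compare case-insensitively against the record's headings
    (prefix compare under wildcard).  When the record carries no MeSH
    headings at all — the usual case outside an indexed database export —
    MeSH terms degrade to text matching unless ``mesh_fallback_to_text``
    is disabled.
    """
    if term.field == MESH:
        if record.mesh_terms:
            for heading in record.mesh_terms:
                h = " ".join(heading.lower().split())
                if h.startswith(term.pattern) if term.wildcard else h == term.pattern:
                    return True
            return False
        if not mesh_fallback_to_text:
            return False
        term = QueryTerm(pattern=term.pattern, wildcard=term.wildcard, field=TEXT)
    tokens = _surface_tokens(f"{record.title} {record.abstract}")
    return _phrase_match(tokens, term.pattern.split(), term.wildcard)


def classify_boolean(
    record: DocumentRecord,
    queries: Mapping[str, CategoryQuery] | None = None,
    mesh_fallback_to_text: bool = True,
) -> bool:
    """Evaluate FSW AND (HIV OR Violence); a category hits if any term hits."""
    if queries is None:
        queries = load_query_config()
    missing = [c for c in CATEGORY_NAMES if c not in queries]
    if missing:
        raise ValueError(f"missing query categories: {missing}")

    def category_hits(name: str) -> bool:
        return any(
            match_term(record, term, mesh_fallback_to_text)
            for term in queries[name].terms
        )

    return category_hits("FSW") and (category_hits("HIV") or category_hits("Violence"))


def classify_corpus(
    records: Sequence[DocumentRecord],
    queries: Mapping[str, CategoryQuery] | None = None,
    mesh_fallback_to_text: bool = True,
) -> np.ndarray:
    """Vectorized hard 0/1 baseline labels for a record list."""
    if queries is None:
        queries = load_query_config()
    return np.array(
        [classify_boolean(rec, queries, mesh_fallback_to_text) for rec in records],
        dtype=bool,
    )


def baseline_operating_point(
    predictions: np.ndarray, labels: Sequence[int]
) -> dict[str, float]:
    """The baseline's single point for ROC/PR overlays.

    Returns FPR/TPR (ROC coordinates) and recall/precision (PR coordinates)
    of the deterministic classification.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=bool)
    tp = int(np.sum(p & (y == 1)))
    fp = int(np.sum(p & (y == 0)))
    fn = int(np.sum(~p & (y == 1)))
    tn = int(np.sum(~p & (y == 0)))
    return {
        "tpr": tp / (tp + fn) if tp + fn else 0.0,
        "fpr": fp / (fp + tn) if fp + tn else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
    }
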