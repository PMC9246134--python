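"""Text normalization, bag-of-words encoding and TF-IDF weighting.

The pipeline is: whitespace tokenization of the concatenated title+abstract,
character stripping (keep ASCII letters only; tokens with non-ASCII letters
are dropped as a cheap non-English proxy), stop-word removal, table-driven
lemmatization, Porter stemming, then a sparse document-term count matrix
(DTM) and the TF-IDF encoding

    tfidf(i, d) = tf(i, d) * ln(N / df(i)),

with tf the raw within-document count by default (a relative-frequency mode
is available) and df(i) the number of fitting documents containing token i.
No smoothing is applied: a token present in every document gets weight 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import DocumentRecord
from .porter import porter_stem

logger = logging.getLogger(__name__)

RAW_COUNT = "raw_count"
RELATIVE_FREQUENCY = "relative_frequency"

#: minimum token length after character stripping
MIN_TOKEN_LENGTH = 2


def _packaged(name: str) -> Path:
    return resources.files("litscreen.data").joinpath(name)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one token per line); packaged list by default."""
    with open(path or _packaged("stopwords.txt"), encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def load_lemma_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a two-column variant<TAB>lemma table; packaged list by default."""
    table: dict[str, str] = {}
    with open(path or _packaged("lemmas.tsv"), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed lemma table row {lineno}: {line!r}")
            table[parts[0]] = parts[1]
    return table


def _clean_token(raw: str, min_length: int = MIN_TOKEN_LENGTH) -> str | None:
    """Strip punctuation/digits; drop tokens containing non-ASCII letters."""
    if any(ch.isalpha() and not ch.isascii() for ch in raw):
        return None
    letters = "".join(ch for ch in raw if ch.isalpha())
    return letters if len(letters) >= min_length else None


def normalize_and_tokenize(
    title: str,
    abstract: str,
    stopwords: Iterable[str] | None = None,
) -> list[str]:
    """Lowercase, whitespace-split and strip the combined title+abstract.

    Stop words are removed here, before lemmatization and stemming.
    """
    stopset = frozenset(stopwords) if stopwords is not None else frozenset()
    tokens = []
    for raw in f"{title} {abstract}".lower().split():
        tok = _clean_token(raw)
        if tok is not None and tok not in stopset:
            tokens.append(tok)
    return tokens


def lemmatize(tokens: Sequence[str], lemma_table: Mapping[str, str]) -> list[str]:
    """Replace each token by its lemma where the table has one."""
    return [lemma_table.get(tok, tok) for tok in tokens]


@dataclass
class TokenizedDocument:
    doc_id: str
    tokens: list[str]


def tokenize_records(
    records: Sequence[DocumentRecord],
    stopwords: Iterable[str] | None = None,
    lemma_table: Mapping[str, str] | None = None,
    stem: bool = True,
) -> list[TokenizedDocument]:
    """Full normalization of records: tokenize, de-stop, lemmatize, stem."""
    if stopwords is None:
        stopwords = load_stopwords()
    if lemma_table is None:
        lemma_table = load_lemma_table()
    docs = []
    for rec in records:
        toks = normalize_and_tokenize(rec.title, rec.abstract, stopwords)
        toks = lemmatize(toks, lemma_table)
        if stem:
            toks = [porter_stem(t) for t in toks]
        docs.append(TokenizedDocument(doc_id=rec.doc_id, tokens=toks))
    return docs


@dataclass
class DocumentTermMatrix:
    """Sparse documents x tokens count matrix with an explicit vocabulary."""

    doc_ids: list[str]
    vocabulary: list[str]
    counts: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_rows(self, indices: Sequence[int]) -> "DocumentTermMatrix":
        """Row-subset view used for cross-validation splits."""
        idx = np.asarray(indices, dtype=int)
        return DocumentTermMatrix(
            doc_ids=[self.doc_ids[i] for i in idx],
            vocabulary=self.vocabulary,
            counts=sp.csr_matrix(self.counts[idx]),
        )

    def save(self, counts_path: str | Path, sidecar_path: str | Path) -> None:
        """Export as MatrixMarket sparse text plus a doc-id/vocabulary sidecar."""
        from scipy.io import mmwrite

        mmwrite(str(counts_path), self.counts.tocoo(), field="integer")
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.doc_ids)} {len(self.vocabulary)}\n")
            for doc_id in self.doc_ids:
                fh.write(f"doc\t{doc_id}\n")
            for token in self.vocabulary:
                fh.write(f"token\t{token}\n")

    @classmethod
    def load(cls, counts_path: str | Path, sidecar_path: str | Path) -> "DocumentTermMatrix":
        from scipy.io import mmread

        counts = sp.csr_matrix(mmread(str(counts_path)))
        doc_ids, vocabulary = [], []
        with open(sidecar_path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                kind, value = line.rstrip("\n").split("\t", 1)
                (doc_ids if kind == "doc" else vocabulary).append(value)
        return cls(doc_ids=doc_ids, vocabulary=vocabulary, counts=counts)


def build_dtm(docs: Sequence[TokenizedDocument]) -> DocumentTermMatrix:
    """Count tokens per document; vocabulary is the sorted union of tokens.

    Documents that became empty during preprocessing are kept as all-zero
    rows (logged) so document ids stay aligned across pipeline stages.
    """
    if not docs:
        raise ValueError("cannot build a DTM from an empty document list")
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
    vocabulary = sorted({tok for doc in docs for tok in doc.tokens})
    index = {tok: j for j, tok in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    n_empty = 0
    for i, doc in enumerate(docs):
        if not doc.tokens:
            n_empty += 1
            continue
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index[tok]
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if n_empty:
        logger.info("%d document(s) empty after preprocessing; kept as zero rows", n_empty)
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocabulary)), dtype=np.int64
    )
    return DocumentTermMatrix(
        doc_ids=[d.doc_id for d in docs], vocabulary=vocabulary, counts=counts_mat
    )


@dataclass
class TfidfModel:
    """Fitted IDF weights: idf(i) = ln(N / df(i)) over the fitting corpus."""

    vocabulary: list[str]
    df: np.ndarray
    n_docs: int
    idf: np.ndarray
    tf_mode: str = RAW_COUNT
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {tok: j for j, tok in enumerate(self.vocabulary)}


def fit_tfidf(dtm: DocumentTermMatrix, tf_mode: str = RAW_COUNT) -> TfidfModel:
    """Fit document frequencies and IDF weights on a count matrix.

    Tokens absent from every fitting document (possible after row
    subsetting) are dropped from the fitted vocabulary, so df >= 1 holds
    for every retained token.
    """
    if tf_mode not in (RAW_COUNT, RELATIVE_FREQUENCY):
        raise ValueError(f"unknown tf_mode {tf_mode!r}")
    n_docs, n_tokens = dtm.shape
    if n_docs < 1 or n_tokens < 1:
        raise ValueError("cannot fit TF-IDF on an empty matrix")
    df = np.asarray((dtm.counts > 0).sum(axis=0)).ravel()
    keep = df > 0
    vocabulary = [tok for tok, k in zip(dtm.vocabulary, keep) if k]
    df = df[keep].astype(np.int64)
    idf = np.log(n_docs / df)
    return TfidfModel(vocabulary=vocabulary, df=df, n_docs=n_docs, idf=idf, tf_mode=tf_mode)


def transform_tfidf(model: TfidfModel, dtm: DocumentTermMatrix) -> sp.csr_matrix:
    """Apply fitted IDF weights to a count matrix.

    Output columns follow ``model.vocabulary``; tokens of ``dtm`` unseen at
    fit time are dropped (with a log message).  Under relative-frequency
    mode tf is the count divided by the document's total token count
    (all-zero rows stay all-zero).
    """
    positions = [model._index.get(tok, -1) for tok in dtm.vocabulary]
    dropped = sum(1 for p in positions if p < 0)
    if dropped:
        logger.info("%d token(s) absent from the fitted vocabulary dropped", dropped)
    keep_cols = [j for j, p in enumerate(positions) if p >= 0]
    target_cols = [positions[j] for j in keep_cols]
    counts = sp.csr_matrix(dtm.counts[:, keep_cols], dtype=np.float64)
    # scatter kept columns into the model's column order
    projector = sp.csr_matrix(
        (np.ones(len(keep_cols)), (np.arange(len(keep_cols)), target_cols)),
        shape=(len(keep_cols), len(model.vocabulary)),
    )
    aligned = sp.csr_matrix(counts @ projector)
    if model.tf_mode == RELATIVE_FREQUENCY:
        row_totals = np.asarray(dtm.counts.sum(axis=1)).ravel().astype(np.float64)
        scale = np.divide(1.0, row_totals, out=np.zeros_like(row_totals),
                          where=row_totals > 0)
        aligned = sp.csr_matrix(sp.diags(scale) @ aligned)
    weighted = sp.csr_matrix(aligned @ sp.diags(model.idf))
    return weighted
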