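"""Token screening by unpooled (Welch) two-sample t-statistics.

Each token's TF-IDF column is split by gold label and scored with

    t = (mean_rel - mean_irr) / sqrt(s_rel^2 / n_rel + s_irr^2 / n_irr),

using unbiased sample variances.  Tokens are ranked by |t| (descending,
lexicographic tie-break) and the top N become additional classifier
features.  The statistic is used purely for ranking — no p-values, no
testing at a level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

DEFAULT_TOP_N = (20, 50, 100, 250, 500)


def welch_t(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Signed Welch statistic for two samples (each of size >= 2).

    Degenerate zero-variance cases: equal means give 0 (uninformative);
    unequal means give a signed infinity that outranks every finite value.
    """
    a = np.asarray(x1, dtype=np.float64)
    b = np.asarray(x2, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    diff = a.mean() - b.mean()
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0.0:
        if diff == 0.0:
            return 0.0
        return np.inf if diff > 0 else -np.inf
    return float(diff / denom)


@dataclass
class ScreeningResult:
    """Per-token Welch statistics and the top-N selection."""

    tokens: list[str]
    t_stats: np.ndarray          # signed, aligned with tokens
    abs_rank: np.ndarray         # 1-based rank by |t| (1 = largest)
    selected: list[str]          # top-N tokens in rank order
    n_selected: int

    def to_csv(self, path: str | Path) -> None:
        selected_set = set(self.selected)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["token", "t", "abs_rank", "selected"])
            for tok, t, rank in zip(self.tokens, self.t_stats, self.abs_rank):
                writer.writerow([tok, repr(float(t)), int(rank), int(tok in selected_set)])


def _column_welch(
    tfidf: sp.spmatrix | np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Vectorized per-column Welch t over a (sparse) matrix, zeros included."""
    X = sp.csr_matrix(tfidf, dtype=np.float64)
    rel = labels == 1
    irr = ~rel
    n1, n2 = int(rel.sum()), int(irr.sum())
    X1, X2 = X[rel], X[irr]
    s1 = np.asarray(X1.sum(axis=0)).ravel()
    s2 = np.asarray(X2.sum(axis=0)).ravel()
    q1 = np.asarray(X1.multiply(X1).sum(axis=0)).ravel()
    q2 = np.asarray(X2.multiply(X2).sum(axis=0)).ravel()
    m1, m2 = s1 / n1, s2 / n2
    # unbiased variances; clip tiny negative round-off
    v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(q2 - n2 * m2**2, 0.0) / (n2 - 1)
    diff = m1 - m2
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_denom = denom == 0.0
    t[zero_denom & (diff == 0.0)] = 0.0
    t[zero_denom & (diff > 0.0)] = np.inf
    t[zero_denom & (diff < 0.0)] = -np.inf
    return t


def screen_top_tokens(
    tfidf: sp.spmatrix | np.ndarray,
    vocabulary: Sequence[str],
    labels: Sequence[int],
    n: int,
) -> ScreeningResult:
    """Rank all tokens by |Welch t| between classes and select the top ``n``.

    ``labels`` is 0/1 with 1 = relevant; both classes need >= 2 documents.
    Ties in |t| (including the all-zero-column t = 0 floor) break
    lexicographically by token so the selection is reproducible.
    """
    y = np.asarray(labels, dtype=int)
    tokens = list(vocabulary)
    if n > len(tokens):
        raise ValueError(f"n={n} exceeds vocabulary size {len(tokens)}")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least 2 documents for screening")
    t = _column_welch(tfidf, y)
    abs_t = np.abs(t)
    order = sorted(range(len(tokens)), key=lambda j: (-abs_t[j], tokens[j]))
    abs_rank = np.empty(len(tokens), dtype=np.int64)
    for rank, j in enumerate(order, start=1):
        abs_rank[j] = rank
    selected = [tokens[j] for j in order[:n]]
    return ScreeningResult(
        tokens=tokens, t_stats=t, abs_rank=abs_rank, selected=selected, n_selected=n
    )
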