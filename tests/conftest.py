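import numpy as np
import pytest

import litscreen as ls


@pytest.fixture(scope="session")
def tiny_records():
    return ls.tiny_corpus()


@pytest.fixture(scope="session")
def tiny_dtm(tiny_records):
    return ls.build_dtm(ls.tokenize_records(tiny_records))


@pytest.fixture(scope="session")
def separable_corpus():
    """Strong-signal synthetic corpus, moderate size for pipeline tests."""
    records, manifest = ls.generate(ls.separable_config(seed=101, n_docs=500))
    dtm = ls.build_dtm(ls.tokenize_records(records))
    return records, manifest, dtm


@pytest.fixture(scope="session")
def null_corpus():
    """Label-randomized synthetic corpus: features carry no class signal."""
    records, manifest = ls.generate(ls.null_config(seed=102, n_docs=500))
    dtm = ls.build_dtm(ls.tokenize_records(records))
    return records, manifest, dtm


def tfidf_oracle(counts: np.ndarray) -> np.ndarray:
    """Brute-force double-loop TF-IDF: tf * ln(N / df) entrywise."""
    n_docs, n_tokens = counts.shape
    out = np.zeros((n_docs, n_tokens))
    for i in range(n_tokens):
        df = int(np.sum(counts[:, i] > 0))
        if df == 0:
            continue
        idf = np.log(n_docs / df)
        for d in range(n_docs):
            out[d, i] = counts[d, i] * idf
    return out


def auc_pairs_oracle(scores, labels) -> float:
    """Mann-Whitney concordant-pair AUC with ties counted 0.5 (O(n^2))."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def wss_scan_oracle(scores, labels, recall) -> float:
    """Exhaustive WSS@R: scan every cutoff, keep the largest reaching R."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    best = None
    for cutoff in sorted(set(scores), reverse=True):
        pred = scores >= cutoff
        if np.sum(pred & (labels == 1)) / n_pos >= recall:
            best = int(pred.sum())
            break
    return recall - best / scores.size


def average_precision_oracle(scores, labels) -> float:
    """Step-integral AUC-PR by direct summation over descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    prev_recall = 0.0
    total = 0.0
    for cutoff in sorted(set(scores), reverse=True):
        pred = scores >= cutoff
        tp = int(np.sum(pred & (labels == 1)))
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        total += (recall - prev_recall) * precision
        prev_recall = recall
    return total
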