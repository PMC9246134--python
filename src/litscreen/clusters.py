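"""Semantic token clusters and the document-cluster TF-IDF features.

Vocabulary tokens (post-stemming) are routed into named clusters by
exact-or-prefix patterns; per-document cluster counts are the summed counts
of the member tokens, and the cluster-level TF-IDF is computed with the
same formula as the token-level encoding (document frequency counted at
the cluster level).  The packaged default defines the 15 clusters used for
the screening task; their membership lists are an editable reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

from .preprocess import (
    RAW_COUNT,
    DocumentTermMatrix,
    TfidfModel,
    fit_tfidf,
    transform_tfidf,
)

DEFAULT_CLUSTER_NAMES = (
    "hiv", "fsw", "violence", "offense", "abuse", "torture", "rape",
    "victim", "assault", "harass", "extort", "homicide", "coercion",
    "ipv", "exploit",
)


@dataclass
class ClusterDefinition:
    """One named cluster with exact/prefix member patterns (trailing ``*``)."""

    name: str
    member_patterns: list[str]

    def matches(self, token: str) -> bool:
        for pattern in self.member_patterns:
            if pattern.endswith("*"):
                if token.startswith(pattern[:-1]):
                    return True
            elif token == pattern:
                return True
        return False


def load_cluster_config(path: str | Path | None = None) -> list[ClusterDefinition]:
    """Load cluster definitions (packaged 15-cluster default), order-preserving."""
    if path is None:
        path = resources.files("litscreen.data").joinpath("clusters.yml")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    clusters = [ClusterDefinition(name=n, member_patterns=list(p)) for n, p in raw.items()]
    names = [c.name for c in clusters]
    if len(set(names)) != len(names):
        raise ValueError("cluster names must be unique")
    return clusters


def assign_tokens(
    vocabulary: Sequence[str], clusters: Sequence[ClusterDefinition]
) -> dict[str, str]:
    """Map each vocabulary token to the FIRST cluster whose pattern matches.

    Unmatched tokens are simply absent from the returned map.
    """
    assignment: dict[str, str] = {}
    for token in vocabulary:
        for cluster in clusters:
            if cluster.matches(token):
                assignment[token] = cluster.name
                break
    return assignment


def build_cluster_matrix(
    dtm: DocumentTermMatrix,
    assignment: Mapping[str, str],
    clusters: Sequence[ClusterDefinition],
) -> DocumentTermMatrix:
    """Collapse token counts into per-cluster counts (declared cluster order).

    Entry (d, c) is the summed count over d's tokens assigned to cluster c;
    unassigned tokens contribute nowhere, so column sums conserve exactly
    the assigned-token mass.
    """
    names = [c.name for c in clusters]
    col_of = {name: j for j, name in enumerate(names)}
    rows, cols, vals = [], [], []
    for j, token in enumerate(dtm.vocabulary):
        cluster = assignment.get(token)
        if cluster is not None and cluster in col_of:
            rows.append(j)
            cols.append(col_of[cluster])
            vals.append(1)
    collapse = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(dtm.vocabulary), len(names)), dtype=np.int64
    )
    counts = sp.csr_matrix(dtm.counts @ collapse)
    return DocumentTermMatrix(doc_ids=list(dtm.doc_ids), vocabulary=names, counts=counts)


def cluster_tfidf(
    cluster_dtm: DocumentTermMatrix, tf_mode: str = RAW_COUNT
) -> tuple[TfidfModel, sp.csr_matrix, list[str]]:
    """Fit and apply TF-IDF at the cluster level.

    Returns the fitted model, the D x n_clusters weight matrix with columns
    in the cluster matrix's declared order (clusters absent from every
    document become all-zero columns), and the column names.
    """
    model = fit_tfidf(cluster_dtm, tf_mode=tf_mode)
    weights = transform_tfidf(model, cluster_dtm)
    # re-expand to all declared clusters so the feature layout is stable
    names = list(cluster_dtm.vocabulary)
    full = sp.lil_matrix((cluster_dtm.shape[0], len(names)), dtype=np.float64)
    fitted_col = {tok: j for j, tok in enumerate(model.vocabulary)}
    for j, name in enumerate(names):
        if name in fitted_col:
            full[:, j] = weights[:, fitted_col[name]]
    return model, sp.csr_matrix(full), names
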