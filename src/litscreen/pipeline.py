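"""End-to-end relevance pipeline: TF-IDF -> clusters + top tokens -> forest.

``RelevancePipeline`` owns every fitted component (token IDF, cluster IDF,
token screening, forest) and re-fits all of them from the training rows it
is given, so cross-validation with ``evaluate.kfold_cv`` is leakage-free
by construction.  A "global" screening mode — selecting top tokens once on
the full labeled corpus before any splitting, as a study might have done —
is available behind an explicit flag for comparison; it leaks label
information into test folds and is not the default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import forest
from .clusters import (
    ClusterDefinition,
    assign_tokens,
    build_cluster_matrix,
    cluster_tfidf,
    load_cluster_config,
)
from .preprocess import (
    RAW_COUNT,
    DocumentTermMatrix,
    fit_tfidf,
    transform_tfidf,
)
from .screening import screen_top_tokens

FOLD_SAFE = "fold_safe"
GLOBAL = "global"


class RelevancePipeline:
    """Clusters + top-N screened tokens + class-balanced forest.

    Parameters
    ----------
    top_n
        Number of screened tokens appended to the cluster features
        (0 reproduces the clusters-only model).
    n_trees, seed
        Forest size and RNG seed (deterministic given both).
    tf_mode
        TF convention for both token- and cluster-level TF-IDF.
    clusters
        Cluster definitions; packaged 15-cluster default when omitted.
    screening_mode
        ``"fold_safe"`` (default) screens inside ``fit``;  ``"global"``
        requires ``set_fixed_tokens`` to have been called with a
        pre-computed selection.
    exclude_cluster_tokens
        Drop tokens already matched by a cluster from top-N eligibility.
    """

    def __init__(
        self,
        top_n: int = 250,
        n_trees: int = forest.DEFAULT_N_TREES,
        tf_mode: str = RAW_COUNT,
        clusters: Sequence[ClusterDefinition] | None = None,
        screening_mode: str = FOLD_SAFE,
        exclude_cluster_tokens: bool = False,
        seed: int = 0,
    ) -> None:
        if screening_mode not in (FOLD_SAFE, GLOBAL):
            raise ValueError(f"unknown screening_mode {screening_mode!r}")
        self.top_n = top_n
        self.n_trees = n_trees
        self.tf_mode = tf_mode
        self.clusters = list(clusters) if clusters is not None else load_cluster_config()
        self.screening_mode = screening_mode
        self.exclude_cluster_tokens = exclude_cluster_tokens
        self.seed = seed
        self.fixed_tokens: list[str] | None = None

    def set_fixed_tokens(self, tokens: Sequence[str]) -> None:
        """Pin the screened-token list (used by the global screening mode)."""
        self.fixed_tokens = list(tokens)

    # -- feature construction -------------------------------------------------

    def _cluster_features(self, dtm: DocumentTermMatrix, fit: bool) -> forest.FeatureMatrix:
        cdtm = build_cluster_matrix(dtm, self.assignment_, self.clusters)
        if fit:
            self.cluster_model_, weights, names = cluster_tfidf(cdtm, self.tf_mode)
            self.cluster_names_ = names
        else:
            weights = transform_tfidf(self.cluster_model_, cdtm)
            # transform keeps the fitted vocabulary; re-expand to declared order
            fitted = {t: j for j, t in enumerate(self.cluster_model_.vocabulary)}
            full = np.zeros((dtm.shape[0], len(self.cluster_names_)))
            dense = np.asarray(weights.todense())
            for j, name in enumerate(self.cluster_names_):
                if name in fitted:
                    full[:, j] = dense[:, fitted[name]]
            return forest.FeatureMatrix(
                doc_ids=list(dtm.doc_ids),
                feature_names=list(self.cluster_names_),
                values=full,
            )
        return forest.FeatureMatrix(
            doc_ids=list(dtm.doc_ids),
            feature_names=list(self.cluster_names_),
            values=np.asarray(weights.todense()),
        )

    def _token_features(self, dtm: DocumentTermMatrix) -> forest.FeatureMatrix | None:
        if not self.selected_tokens_:
            return None
        tfidf = transform_tfidf(self.token_model_, dtm)
        col = {t: j for j, t in enumerate(self.token_model_.vocabulary)}
        dense = np.asarray(tfidf.todense())
        values = np.zeros((dtm.shape[0], len(self.selected_tokens_)))
        for j, tok in enumerate(self.selected_tokens_):
            if tok in col:
                values[:, j] = dense[:, col[tok]]
        return forest.FeatureMatrix(
            doc_ids=list(dtm.doc_ids),
            feature_names=list(self.selected_tokens_),
            values=values,
        )

    def _features(self, dtm: DocumentTermMatrix, fit: bool) -> forest.FeatureMatrix:
        return forest.assemble_features(
            self._cluster_features(dtm, fit=fit), self._token_features(dtm)
        )

    # -- fit / predict ---------------------------------------------------------

    def fit(self, dtm: DocumentTermMatrix, labels: Sequence[int]) -> "RelevancePipeline":
        y = np.asarray(labels, dtype=int)
        self.token_model_ = fit_tfidf(dtm, tf_mode=self.tf_mode)
        self.assignment_ = assign_tokens(dtm.vocabulary, self.clusters)
        if self.top_n == 0:
            self.selected_tokens_: list[str] = []
        elif self.screening_mode == GLOBAL:
            if self.fixed_tokens is None:
                raise ValueError(
                    "global screening mode needs set_fixed_tokens() before fit"
                )
            self.selected_tokens_ = list(self.fixed_tokens)
        else:
            tfidf = transform_tfidf(self.token_model_, dtm)
            vocab = self.token_model_.vocabulary
            if self.exclude_cluster_tokens:
                eligible = [j for j, t in enumerate(vocab) if t not in self.assignment_]
                tfidf = tfidf[:, eligible]
                vocab = [vocab[j] for j in eligible]
            n = min(self.top_n, len(vocab))
            self.screening_ = screen_top_tokens(tfidf, vocab, y, n)
            self.selected_tokens_ = list(self.screening_.selected)
        features = self._features(dtm, fit=True)
        self.model_ = forest.train(features, y, n_trees=self.n_trees, seed=self.seed)
        return self

    def predict_proba(self, dtm: DocumentTermMatrix) -> np.ndarray:
        features = self._features(dtm, fit=False)
        return forest.predict_proba(self.model_, features)


def global_screening_tokens(
    dtm: DocumentTermMatrix,
    labels: Sequence[int],
    top_n: int,
    tf_mode: str = RAW_COUNT,
) -> list[str]:
    """Top-N token selection on the FULL labeled corpus (leaky; comparison only)."""
    model = fit_tfidf(dtm, tf_mode=tf_mode)
    tfidf = transform_tfidf(model, dtm)
    result = screen_top_tokens(
        tfidf, model.vocabulary, labels, min(top_n, len(model.vocabulary))
    )
    return list(result.selected)
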