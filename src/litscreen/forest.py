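"""Class-balanced random-forest vote classifier.

With roughly one relevant document per ten irrelevant ones, a forest grown
on the raw data drifts toward the majority class.  Each tree here is
instead grown on a balanced bootstrap: the minority class is resampled
with replacement to its own size and the majority class is down-sampled
(with replacement) to that same size, with fresh randomness per tree.  The
predicted probability of relevance is the fraction of trees voting
"relevant" — a hard-vote proportion, not an averaged leaf probability.

Tree induction itself is delegated to sklearn's ``DecisionTreeClassifier``
(per-split candidate features = floor(sqrt(p))); the sampling scheme and
vote aggregation are what this module adds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

DEFAULT_N_TREES = 500


@dataclass
class FeatureMatrix:
    """Documents x features: cluster columns first, then screened tokens."""

    doc_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.doc_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.doc_ids)} docs x {len(self.feature_names)} features"
            )


def assemble_features(
    cluster_features: FeatureMatrix, token_features: FeatureMatrix | None
) -> FeatureMatrix:
    """Concatenate cluster features with (optional) top-token features.

    Rows must align by doc_id; ``token_features=None`` yields the
    clusters-only design (the "refined clusters" model).
    """
    if token_features is None:
        return cluster_features
    if cluster_features.doc_ids != token_features.doc_ids:
        raise ValueError("cluster and token feature rows are not aligned by doc_id")
    return FeatureMatrix(
        doc_ids=list(cluster_features.doc_ids),
        feature_names=cluster_features.feature_names + token_features.feature_names,
        values=np.hstack([cluster_features.values, token_features.values]),
    )


@dataclass
class TrainedModel:
    backend: str
    n_trees: int
    per_tree_sampling: str
    feature_names: list[str]
    seed: int
    trees: list = field(default_factory=list, repr=False)
    estimator: object = None


def _balanced_bootstrap(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Indices of one balanced bootstrap: each class resampled to minority size."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n_min = min(idx_pos.size, idx_neg.size)
    take_pos = rng.choice(idx_pos, size=n_min, replace=True)
    take_neg = rng.choice(idx_neg, size=n_min, replace=True)
    return np.concatenate([take_pos, take_neg])


def train(
    features: FeatureMatrix,
    labels: Sequence[int],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    backend: Callable | None = None,
) -> TrainedModel:
    """Fit the vote classifier.

    ``backend`` may supply any sklearn-style estimator factory (fit /
    predict_proba) as a pluggable alternative; the balanced-forest default
    is the supported, tested path.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != len(features.doc_ids):
        raise ValueError("labels are not aligned to feature rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if backend is not None:
        est = backend()
        est.fit(features.values, y)
        return TrainedModel(
            backend="plugin", n_trees=0, per_tree_sampling="backend-defined",
            feature_names=list(features.feature_names), seed=seed, estimator=est,
        )
    rng = np.random.default_rng(seed)
    max_feat = max(1, int(np.floor(np.sqrt(features.values.shape[1]))))
    trees = []
    for _ in range(n_trees):
        idx = _balanced_bootstrap(rng, y)
        tree = DecisionTreeClassifier(
            max_features=max_feat,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(features.values[idx], y[idx])
        trees.append(tree)
    return TrainedModel(
        backend="random_forest",
        n_trees=n_trees,
        per_tree_sampling="balanced bootstrap: both classes resampled to minority size",
        feature_names=list(features.feature_names),
        seed=seed,
        trees=trees,
    )


def predict_proba(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Probability of relevance per document = fraction of trees voting 1."""
    if features.feature_names != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    X = features.values
    if model.backend == "plugin":
        return np.asarray(model.estimator.predict_proba(X))[:, 1]
    votes = np.zeros(X.shape[0], dtype=np.float64)
    for tree in model.trees:
        votes += tree.predict(X) == 1
    return votes / model.n_trees


def classify(probabilities: Sequence[float], cutoff: float = 0.5) -> np.ndarray:
    """Hard labels under the >= cutoff convention (ties count as relevant)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    return np.asarray(probabilities, dtype=float) >= cutoff


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the fitted state (binary blob) with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "format_version": 1,
        "backend": model.backend,
        "n_trees": model.n_trees,
        "per_tree_sampling": model.per_tree_sampling,
        "feature_names": model.feature_names,
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
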