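"""Classifier evaluation: ROC/PR curves, cross-validation, WSS and workload.

All curve operations use the ">= cutoff" prediction convention and sweep
thresholds over the unique scores in descending order (plus a +inf
sentinel so the ROC curve starts at (0, 0)).  AUC-ROC is the trapezoidal
integral; AUC-PR uses the step-interpolated (average-precision) integral,
since linear interpolation in PR space is optimistic.

The work-saved-over-sampling metric at target recall R is

    WSS@R = R - P/N,

where the score cutoff is the largest one reaching recall >= R, P is the
number of documents flagged at that cutoff and N the corpus size: the
fraction of reading avoided relative to screening documents in random
order.  The formula uses the target recall R, not the (possibly slightly
higher) recall achieved at the chosen cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

DEFAULT_WSS_RECALLS = (0.80, 0.95)


@dataclass
class CurvePoints:
    kind: str                 # "roc" or "pr"
    thresholds: np.ndarray    # descending
    x: np.ndarray             # FPR (roc) or recall (pr)
    y: np.ndarray             # TPR (roc) or precision (pr)
    auc: float


@dataclass
class EvalSummary:
    """Cross-validation output: pooled out-of-fold curves plus per-fold curves."""

    per_fold: list[dict[str, CurvePoints]]
    pooled: dict[str, CurvePoints]
    auc_roc: float
    auc_pr: float
    wss: dict[float, float]
    n_folds: int
    seed: int
    pooled_scores: np.ndarray = field(default=None, repr=False)
    pooled_labels: np.ndarray = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "wss": {str(k): v for k, v in self.wss.items()},
            "per_fold_auc_roc": [f["roc"].auc for f in self.per_fold],
            "per_fold_auc_pr": [f["pr"].auc for f in self.per_fold],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def curves_to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kind", "threshold", "x", "y"])
            for kind in ("roc", "pr"):
                curve = self.pooled[kind]
                for t, x, y in zip(curve.thresholds, curve.x, curve.y):
                    writer.writerow([kind, repr(float(t)), repr(float(x)), repr(float(y))])


@dataclass
class WorkloadSummary:
    n_total: int
    n_relevant: int
    recall: float
    precision: float
    n_flagged: int
    reduction_pct: float


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError(f"scores shape {s.shape} != labels shape {y.shape}")
    return s, y


def confusion_at(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) under the >= cutoff rule."""
    s, y = _validate(scores, labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP counts at each unique descending threshold."""
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    cum_tp = np.cumsum(y_sorted == 1)
    cum_fp = np.cumsum(y_sorted == 0)
    # number of documents with score >= t for each threshold
    counts = np.searchsorted(-s_sorted, -thresholds, side="right")
    tp = np.where(counts > 0, cum_tp[counts - 1], 0)
    fp = np.where(counts > 0, cum_fp[counts - 1], 0)
    return thresholds, tp, fp


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> CurvePoints:
    """ROC curve over descending unique thresholds; AUC by trapezoid rule."""
    s, y = _validate(scores, labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    thresholds, tp, fp = _sweep(s, y)
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(kind="roc", thresholds=thresholds, x=fpr, y=tpr, auc=auc)


def pr_points(scores: Sequence[float], labels: Sequence[int]) -> CurvePoints:
    """PR curve; AUC-PR is the average-precision step integral."""
    s, y = _validate(scores, labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("PR needs at least one positive")
    thresholds, tp, fp = _sweep(s, y)
    flagged = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(flagged > 0, tp / np.maximum(flagged, 1), 1.0)
    recall = tp / n_pos
    auc = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return CurvePoints(kind="pr", thresholds=thresholds, x=recall, y=precision, auc=auc)


def wss_at(scores: Sequence[float], labels: Sequence[int], recall: float) -> float:
    """Work saved over sampling at target recall ``recall`` (Eq above)."""
    if not 0.0 < recall <= 1.0:
        raise ValueError("target recall must lie in (0, 1]")
    s, y = _validate(scores, labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("WSS needs at least one positive")
    thresholds, tp, fp = _sweep(s, y)
    achieved = tp / n_pos
    reaching = np.flatnonzero(achieved >= recall)
    first = reaching[0]  # largest threshold reaching the target recall
    flagged = int(tp[first] + fp[first])
    return float(recall - flagged / s.size)


def invert_wss(wss: float, recall: float) -> tuple[float, float]:
    """From a reported WSS@R, recover (flagged fraction P/N, fraction not read)."""
    flagged_fraction = recall - wss
    return flagged_fraction, 1.0 - flagged_fraction


def n_training_documents(n_total: int, proportion: float) -> int:
    """Nearest-integer training-set size for a labeling proportion."""
    return int(round(proportion * n_total))


def workload(
    n_total: int, n_relevant: int, recall: float, precision: float
) -> WorkloadSummary:
    """Reading-workload arithmetic at an operating point.

    Flagging recall*n_relevant true positives at the given precision means
    reading n_flagged = recall*n_relevant/precision documents instead of
    n_total, a reduction of 100*(1 - n_flagged/n_total) percent.
    """
    if n_total <= 0 or n_relevant <= 0:
        raise ValueError("counts must be positive")
    if not (0.0 < recall <= 1.0) or not (0.0 < precision <= 1.0):
        raise ValueError("recall and precision must lie in (0, 1]")
    n_flagged = int(round(recall * n_relevant / precision))
    return WorkloadSummary(
        n_total=n_total,
        n_relevant=n_relevant,
        recall=recall,
        precision=precision,
        n_flagged=n_flagged,
        reduction_pct=100.0 * (1.0 - n_flagged / n_total),
    )


def _curves(scores: np.ndarray, labels: np.ndarray) -> dict[str, CurvePoints]:
    return {"roc": roc_points(scores, labels), "pr": pr_points(scores, labels)}


def kfold_cv(
    make_pipeline: Callable[[], "object"],
    data,
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    wss_recalls: Sequence[float] = DEFAULT_WSS_RECALLS,
) -> EvalSummary:
    """Stratified k-fold cross-validation of a fit/predict pipeline.

    ``make_pipeline()`` must return a fresh object with
    ``fit(train_data, train_labels)`` and ``predict_proba(test_data)``;
    ``data`` must support ``subset_rows(indices)`` (as DocumentTermMatrix
    does).  The whole pipeline — IDF fitting, token screening, training —
    is re-run inside each fold on that fold's training rows only.  Pooled
    out-of-fold scores give the headline curves; per-fold curves are kept.
    """
    y = np.asarray(labels, dtype=int)
    if k > min((y == 1).sum(), (y == 0).sum()):
        raise ValueError("k exceeds the minority class size")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_scores = np.empty_like(y, dtype=np.float64)
    per_fold = []
    for train_idx, test_idx in splitter.split(np.zeros(y.size), y):
        pipeline = make_pipeline()
        pipeline.fit(data.subset_rows(train_idx), y[train_idx])
        fold_scores = np.asarray(pipeline.predict_proba(data.subset_rows(test_idx)))
        pooled_scores[test_idx] = fold_scores
        if len(np.unique(y[test_idx])) == 2:
            per_fold.append(_curves(fold_scores, y[test_idx]))
    pooled = _curves(pooled_scores, y)
    wss = {float(r): wss_at(pooled_scores, y, r) for r in wss_recalls}
    return EvalSummary(
        per_fold=per_fold,
        pooled=pooled,
        auc_roc=pooled["roc"].auc,
        auc_pr=pooled["pr"].auc,
        wss=wss,
        n_folds=k,
        seed=seed,
        pooled_scores=pooled_scores,
        pooled_labels=y,
    )


@dataclass
class LearningCurveResult:
    proportions: list[float]
    auc_roc: np.ndarray   # proportions x replicates
    auc_pr: np.ndarray

    @property
    def mean_auc_roc(self) -> np.ndarray:
        return self.auc_roc.mean(axis=1)

    @property
    def mean_auc_pr(self) -> np.ndarray:
        return self.auc_pr.mean(axis=1)

    @property
    def std_auc_roc(self) -> np.ndarray:
        return self.auc_roc.std(axis=1)


def learning_curve(
    make_pipeline: Callable[[], "object"],
    data,
    labels: Sequence[int],
    proportions: Sequence[float] = (0.01, 0.02, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80),
    n_replicates: int = 3,
    seed: int = 0,
) -> LearningCurveResult:
    """Training-size sensitivity: AUCs on held-out data vs labeled fraction.

    For each proportion p and replicate, a stratified sample of p of the
    corpus trains the pipeline and the remaining (1-p) is scored.
    Proportions too small to contain both classes raise.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    props = list(proportions)
    auc_roc = np.empty((len(props), n_replicates))
    auc_pr = np.empty((len(props), n_replicates))
    for i, p in enumerate(props):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie in (0, 1)")
        for r in range(n_replicates):
            split_seed = int(rng.integers(0, 2**31 - 1))
            train_idx, test_idx = train_test_split(
                np.arange(y.size), train_size=p, stratify=y, random_state=split_seed
            )
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError(f"proportion {p} too small to contain both classes")
            pipeline = make_pipeline()
            pipeline.fit(data.subset_rows(train_idx), y[train_idx])
            scores = np.asarray(pipeline.predict_proba(data.subset_rows(test_idx)))
            auc_roc[i, r] = roc_points(scores, y[test_idx]).auc
            auc_pr[i, r] = pr_points(scores, y[test_idx]).auc
    return LearningCurveResult(proportions=props, auc_roc=auc_roc, auc_pr=auc_pr)
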