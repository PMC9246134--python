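"""Curves, AUCs, WSS@R, cross-validation and workload arithmetic."""

import numpy as np
import pytest
import sklearn.metrics

import litscreen as ls

from conftest import auc_pairs_oracle, average_precision_oracle, wss_scan_oracle


def _random_scores(seed, n=60):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    labels = (rng.random(n) < 0.3).astype(int)
    labels[:2] = [0, 1]
    return scores, labels


class TestConfusion:
    def test_basic_counts(self):
        assert ls.confusion_at([0.9, 0.1], [1, 0], 0.5) == (1, 0, 1, 0)

    def test_cutoff_zero_flags_everything(self):
        tp, fp, tn, fn = ls.confusion_at([0.2, 0.8], [0, 1], 0.0)
        assert (tn, fn) == (0, 0)

    def test_conservation(self):
        scores, labels = _random_scores(0)
        tp, fp, tn, fn = ls.confusion_at(scores, labels, 0.4)
        assert tp + fp + tn + fn == len(scores)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ls.confusion_at([0.5], [1, 0], 0.5)


class TestRoc:
    def test_perfect_separation(self):
        assert ls.roc_points([.9, .8, .3, .2], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_reversed_labels(self):
        assert ls.roc_points([.9, .8, .3, .2], [0, 0, 1, 1]).auc == pytest.approx(0.0)

    def test_endpoints_and_monotonicity(self):
        scores, labels = _random_scores(1)
        curve = ls.roc_points(scores, labels)
        assert curve.x[0] == 0.0 and curve.y[0] == 0.0
        assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0
        assert np.all(np.diff(curve.x) >= 0) and np.all(np.diff(curve.y) >= 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_concordant_pair_oracle(self, seed):
        scores, labels = _random_scores(seed, n=50)
        auc = ls.roc_points(scores, labels).auc
        assert auc == pytest.approx(auc_pairs_oracle(scores, labels), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_agrees_with_sklearn(self, seed):
        scores, labels = _random_scores(seed, n=80)
        assert ls.roc_points(scores, labels).auc == pytest.approx(
            sklearn.metrics.roc_auc_score(labels, scores), abs=1e-10
        )

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            ls.roc_points([0.5, 0.7], [1, 1])


class TestPr:
    def test_perfect_ranking(self):
        assert ls.pr_points([.9, .8, .3], [1, 1, 0]).auc == pytest.approx(1.0)

    def test_constant_score_precision_is_prevalence(self):
        curve = ls.pr_points([0.5] * 10, [1, 0, 0, 0, 0, 1, 0, 0, 0, 0])
        assert curve.y[-1] == pytest.approx(0.2)
        assert curve.x[-1] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_step_integral_oracle(self, seed):
        scores, labels = _random_scores(seed)
        assert ls.pr_points(scores, labels).auc == pytest.approx(
            average_precision_oracle(scores, labels), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_agrees_with_sklearn_average_precision(self, seed):
        scores, labels = _random_scores(seed, n=80)
        assert ls.pr_points(scores, labels).auc == pytest.approx(
            sklearn.metrics.average_precision_score(labels, scores), abs=1e-10
        )

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            ls.pr_points([0.5, 0.7], [0, 0])


class TestWss:
    def test_everything_flagged_gives_r_minus_one(self):
        # constant scores: the only cutoff flags all N documents
        assert ls.wss_at([0.5] * 8, [1, 0, 0, 0, 1, 0, 0, 0], 0.8) == \
            pytest.approx(0.8 - 1.0)

    def test_perfect_classifier_r1_gives_one_minus_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        scores = labels * 0.9 + 0.05
        prevalence = labels.mean()
        assert ls.wss_at(scores, labels, 1.0) == pytest.approx(1.0 - prevalence)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("recall", [0.5, 0.8, 0.95, 1.0])
    def test_equals_exhaustive_cutoff_scan(self, seed, recall):
        scores, labels = _random_scores(seed, n=40)
        assert ls.wss_at(scores, labels, recall) == pytest.approx(
            wss_scan_oracle(scores, labels, recall), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds(self, seed):
        scores, labels = _random_scores(seed)
        for recall in (0.3, 0.8, 1.0):
            wss = ls.wss_at(scores, labels, recall)
            assert recall - 1.0 - 1e-12 <= wss <= recall + 1e-12

    def test_invalid_recall(self):
        with pytest.raises(ValueError):
            ls.wss_at([0.5, 0.6], [1, 0], 0.0)


class TestWorkload:
    def test_worked_example_arithmetic(self):
        summary = ls.workload(10000, 1000, recall=0.8, precision=0.4)
        assert summary.n_flagged == 2000
        assert summary.reduction_pct == pytest.approx(80.0)

    def test_perfect_precision_and_recall(self):
        assert ls.workload(100, 10, 1.0, 1.0).n_flagged == 10

    def test_equal_recall_precision_flags_n_relevant(self):
        assert ls.workload(100, 10, 0.5, 0.5).n_flagged == 10

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ls.workload(100, 10, 0.5, 0.0)


def test_invert_wss_reading_fraction():
    flagged, unread = ls.invert_wss(0.55, 0.80)
    assert flagged == pytest.approx(0.25)
    assert unread == pytest.approx(0.75)


def test_n_training_documents_rounds_to_nearest():
    assert ls.n_training_documents(10718, 0.20) == 2144
    assert ls.n_training_documents(10718, 0.01) == 107


class TestKfoldCv:
    def _summary(self, corpus, seed=3, **kw):
        records, _, dtm = corpus
        labels = ls.labels01(records)
        make = lambda: ls.RelevancePipeline(top_n=20, n_trees=60, seed=seed)
        return ls.kfold_cv(make, dtm, labels, k=5, seed=seed, **kw)

    def test_pooled_scores_cover_corpus(self, separable_corpus):
        records, _, _ = separable_corpus
        summary = self._summary(separable_corpus)
        assert summary.pooled_scores.shape == (len(records),)
        assert summary.n_folds == 5
        assert len(summary.per_fold) == 5

    def test_high_auc_on_separable_corpus(self, separable_corpus):
        assert self._summary(separable_corpus).auc_roc >= 0.95

    def test_deterministic_under_fixed_seed(self, separable_corpus):
        s1 = self._summary(separable_corpus)
        s2 = self._summary(separable_corpus)
        np.testing.assert_array_equal(s1.pooled_scores, s2.pooled_scores)
        assert s1.auc_roc == s2.auc_roc and s1.wss == s2.wss

    def test_stratified_fold_sizes_balanced(self, separable_corpus):
        records, _, dtm = separable_corpus
        y = np.asarray(ls.labels01(records))
        from sklearn.model_selection import StratifiedKFold

        sizes = [len(test) for _, test in
                 StratifiedKFold(5, shuffle=True, random_state=3).split(y, y)]
        assert max(sizes) - min(sizes) <= 1

    def test_k_exceeding_minority_raises(self, separable_corpus):
        records, _, dtm = separable_corpus
        y = np.asarray(ls.labels01(records))
        with pytest.raises(ValueError):
            ls.kfold_cv(lambda: ls.RelevancePipeline(), dtm, y, k=int(y.sum()) + 1)

    def test_export_json_and_curves(self, separable_corpus, tmp_path):
        summary = self._summary(separable_corpus)
        summary.to_json(tmp_path / "s.json")
        summary.curves_to_csv(tmp_path / "c.csv")
        assert (tmp_path / "s.json").stat().st_size > 0
        assert (tmp_path / "c.csv").read_text().startswith("kind,threshold,x,y")


class TestLearningCurve:
    def test_smoke_and_weak_monotonicity(self, separable_corpus):
        records, _, dtm = separable_corpus
        labels = ls.labels01(records)
        make = lambda: ls.RelevancePipeline(top_n=20, n_trees=60, seed=0)
        curve = ls.learning_curve(make, dtm, labels,
                                  proportions=[0.1, 0.5], n_replicates=3, seed=5)
        assert curve.auc_roc.shape == (2, 3)
        assert np.all(np.isfinite(curve.auc_roc))
        # more training data should not hurt much on separable data
        assert curve.mean_auc_roc[1] >= curve.mean_auc_roc[0] - 0.05

    def test_too_small_fraction_raises(self, separable_corpus):
        records, _, dtm = separable_corpus
        labels = ls.labels01(records)
        make = lambda: ls.RelevancePipeline(top_n=5, n_trees=10)
        with pytest.raises(ValueError):
            ls.learning_curve(make, dtm, labels, proportions=[0.002],
                              n_replicates=1, seed=0)
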