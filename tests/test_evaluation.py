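import numpy as np
import pandas as pd
import pytest

from imspeech.evaluation import (assert_no_leakage, confusion,
                                 evaluate_features, extract_dataset_features,
                                 holm_adjust, paired_t_test, repeated_kfold,
                                 run_pipeline)
from imspeech.io import ConfigurationError, RunConfig, Trial

from conftest import cluster_features


def make_trials(n_per_class, n_classes=6, participant=0):
    trials = []
    tid = 0
    for c in range(n_classes):
        for _ in range(n_per_class):
            trials.append(Trial(recording=None, label=c, participant=participant,
                                session=0, trial_id=tid))
            tid += 1
    return trials


def cluster_table(n_per_class=10, n_segments=2, dim=24, spread=0.3, seed=0):
    """Feature table of separable clusters with several segments per trial."""
    X, y = cluster_features(n_per_class=n_per_class, dim=dim, spread=spread,
                            seed=seed)
    rows = []
    names = [f"f{i}" for i in range(dim)]
    rng = np.random.default_rng(seed + 1)
    for tid, (x, label) in enumerate(zip(X, y)):
        for s in range(n_segments):
            row = dict(zip(names, x + 0.05 * rng.standard_normal(dim)))
            row.update(label=label, participant=0, trial=tid, segment=s)
            rows.append(row)
    return pd.DataFrame(rows)


class TestRepeatedKFold:
    def test_counts_and_sizes(self):
        trials = make_trials(n_per_class=10, n_classes=10)
        assignments = repeated_kfold(trials, k=10, repeats=10, seed=0)
        assert len(assignments) == 100
        for a in assignments:
            assert len(a.test_trials) == 10
            assert len(a.train_trials) == 90

    def test_no_train_test_overlap(self):
        trials = make_trials(n_per_class=5)
        assignments = repeated_kfold(trials, k=5, repeats=3, seed=1)
        assert_no_leakage(assignments)
        for a in assignments:
            assert not (a.train_trials & a.test_trials)

    def test_every_trial_tested_once_per_repeat(self):
        trials = make_trials(n_per_class=5)
        keys = {(t.participant, t.trial_id) for t in trials}
        assignments = repeated_kfold(trials, k=5, repeats=3, seed=2)
        for r in range(3):
            tested = [key for a in assignments if a.repeat == r
                      for key in a.test_trials]
            assert len(tested) == len(keys)
            assert set(tested) == keys

    def test_stratified_within_class(self):
        trials = make_trials(n_per_class=10)
        for a in repeated_kfold(trials, k=5, repeats=1, seed=0):
            test_labels = [t.label for t in trials
                           if (t.participant, t.trial_id) in a.test_trials]
            assert np.all(np.bincount(test_labels, minlength=6) == 2)

    def test_k_exceeding_trials_rejected(self):
        with pytest.raises(ConfigurationError):
            repeated_kfold(make_trials(1), k=10, repeats=1, seed=0)


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 5, 0])
        counts, norm = confusion(y, y, 6)
        assert np.trace(counts) == 7
        assert counts.sum() == 7
        assert np.allclose(norm[np.array(y)].diagonal(), 1.0)

    def test_hand_counted_example(self):
        counts, norm = confusion([0, 0, 1], [0, 1, 1], 2)
        assert counts.tolist() == [[1, 1], [0, 1]]
        assert norm.tolist() == [[0.5, 0.5], [0.0, 1.0]]

    def test_nonempty_rows_sum_to_one(self, rng):
        t = rng.integers(0, 6, 100)
        p = rng.integers(0, 6, 100)
        counts, norm = confusion(t, p, 6)
        assert counts.sum() == 100
        assert np.allclose(norm.sum(axis=1), 1.0)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ConfigurationError):
            confusion([0, 6], [0, 0], 6)


class TestPairedTTest:
    def test_matches_textbook_formula(self, rng):
        a = rng.uniform(0.5, 0.9, 20)
        b = rng.uniform(0.5, 0.9, 20)
        res = paired_t_test(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert not res.degenerate
        assert 0 <= res.p <= 1

    def test_identical_vectors_degenerate(self):
        res = paired_t_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert res.degenerate
        assert np.isnan(res.p)

    def test_constant_difference_degenerate(self):
        res = paired_t_test([0.7, 0.8, 0.9], [0.6, 0.7, 0.8])
        assert res.degenerate
        assert res.mean_difference == pytest.approx(0.1)

    def test_holm_adjustment_monotone(self):
        raw = {"a": 0.01, "b": 0.04, "c": 0.3}
        adj = holm_adjust(raw)
        assert adj["a"] == pytest.approx(0.03)
        assert all(adj[k] >= raw[k] for k in raw)


class TestEvaluateFeatures:
    def test_segments_follow_their_trial(self):
        """With two near-identical segments per trial, trial-level folds keep
        both on the same side; accuracy bookkeeping stays exact."""
        df = cluster_table(n_per_class=5, n_segments=3)
        cfg = RunConfig(classifier="lda", k=3, repeats=2, seed=0)
        report = evaluate_features(df, cfg, 6)
        assert report.confusion_counts.sum() == 2 * len(df)  # repeats x segments
        assert report.mean_accuracy == pytest.approx(
            report.fold_accuracies.mean())

    def test_separable_clusters_high_accuracy(self):
        df = cluster_table(n_per_class=8, n_segments=2)
        cfg = RunConfig(classifier="lda", k=4, repeats=1, seed=0)
        report = evaluate_features(df, cfg, 6)
        assert report.mean_accuracy >= 0.9
        assert report.trial_vote_accuracy >= 0.9

    def test_fold_accuracy_grid_shape(self):
        df = cluster_table(n_per_class=5, n_segments=2)
        cfg = RunConfig(classifier="knn", k=5, repeats=3, seed=1)
        report = evaluate_features(df, cfg, 6)
        assert report.fold_accuracies.shape == (3, 5)

    def test_label_shuffled_near_chance(self):
        df = cluster_table(n_per_class=10, n_segments=1, seed=3)
        rng = np.random.default_rng(5)
        df["label"] = rng.permutation(df["label"].to_numpy())
        cfg = RunConfig(classifier="lda", k=5, repeats=2, seed=2)
        report = evaluate_features(df, cfg, 6)
        p = 1.0 / 6.0
        sd = np.sqrt(p * (1 - p) / report.confusion_counts.sum())
        assert abs(report.pooled_accuracy - p) <= 3 * sd + 0.02

    def test_deterministic_under_seed(self):
        df = cluster_table(n_per_class=5, n_segments=2)
        cfg = RunConfig(classifier="lda", k=3, repeats=1, seed=4)
        a = evaluate_features(df, cfg, 6)
        b = evaluate_features(df, cfg, 6)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.confusion_counts, b.confusion_counts)


class TestPipeline:
    def test_wpd_pipeline_end_to_end(self, tiny_dataset):
        """Full chain on a 2-class dataset via the fast wavelet route: the
        classes differ in band content and are separable."""
        cfg = RunConfig(method="wpd", classifier="lda", k=2, repeats=1,
                        window=1.0, step=0.5, seed=0)
        report = run_pipeline(tiny_dataset, cfg)
        assert report.mean_accuracy >= 0.75
        assert report.confusion_counts.sum() == 8  # 8 trials x 1 segment
        assert 0 in report.per_participant

    def test_feature_table_lineage(self, tiny_dataset):
        cfg = RunConfig(method="wpd", window=0.5, step=0.25, seed=0)
        df = extract_dataset_features(tiny_dataset, cfg)
        assert len(df) == 8 * 3  # 8 trials, 3 half-second segments each
        assert set(df["segment"]) == {0, 1, 2}
        # 3 channels x 8 nodes x 6 stats + 4 lineage columns
        assert df.shape[1] == 3 * 8 * 6 + 4
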