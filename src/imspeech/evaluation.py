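"""Trial-level repeated k-fold evaluation, sub-band analysis, paired tests.

The cross-validation contract: folds are drawn over *trials* (stratified by
class within participant) before windowed segmentation, so all segments of a
trial inherit the trial's train/test assignment and no segment leaks across
the split.  Segmentation, decomposition and feature extraction are per-trial
local operations with no cross-trial statistics, so they are computed once
and cached; only standardization and classifier training see fold-specific
data (training-fold statistics only).  Models are fitted per participant.

Accuracy is reported at segment level (the classification unit); a
trial-level majority-vote accuracy is reported alongside.  Paired t-tests
between classifiers are two-sided on fold-wise accuracy differences; raw
p-values are reported, with Holm-adjusted values labelled as an extension.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import preprocessing
from .classifiers import (CNNClassifier, MRFNetworkSpec, SRFBranchSpec,
                          classical_classifiers)
from .emd import na_memd
from .features import segment_features, standardize
from .io import ConfigurationError, RunConfig, Trial, features_to_frame
from .synthetic import LabelledDataset
from .wavelet import wpd_features

logger = logging.getLogger("imspeech")

TrialKey = tuple[int, int]  # (participant, trial_id)


@dataclass
class FoldAssignment:
    repeat: int
    fold: int
    train_trials: frozenset[TrialKey]
    test_trials: frozenset[TrialKey]


@dataclass
class PairedTestResult:
    """Two-sided paired t-test on fold-wise accuracy differences.

    ``degenerate`` marks zero-variance differences, where the statistic is
    undefined and no numeric p-value is reported.
    """

    t: float
    p: float
    mean_difference: float
    degenerate: bool


@dataclass
class EvaluationReport:
    fold_accuracies: np.ndarray  # (repeats, k), segment-level
    mean_accuracy: float
    sd_accuracy: float
    confusion_counts: np.ndarray
    confusion_normalized: np.ndarray
    pooled_accuracy: float
    trial_vote_accuracy: float
    per_participant: dict[int, tuple[float, float]] = field(default_factory=dict)
    per_band: pd.DataFrame | None = None
    paired_tests: dict[str, PairedTestResult] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "pooled_accuracy": self.pooled_accuracy,
            "trial_vote_accuracy": self.trial_vote_accuracy,
            "per_participant": {str(k): list(v) for k, v in self.per_participant.items()},
            "paired_tests": {k: dataclasses.asdict(v) for k, v in self.paired_tests.items()},
        }
        if self.per_band is not None:
            obj["per_band"] = self.per_band.to_dict(orient="records")
        Path(path).write_text(json.dumps(obj, indent=2))


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

def repeated_kfold(trials: list[Trial], k: int, repeats: int,
                   seed: int = 0) -> list[FoldAssignment]:
    """Repeated stratified k-fold over trials (never over segments).

    Stratification is by class within participant, which keeps folds
    class-balanced even at desk scale.  Every trial lands in exactly one test
    fold per repeat.
    """
    if k > len(trials):
        raise ConfigurationError(f"k={k} exceeds {len(trials)} trials")
    keys = [(t.participant, t.trial_id) for t in trials]
    if len(set(keys)) != len(keys):
        raise ConfigurationError("duplicate trial ids")
    strata = np.array([f"{t.participant}:{t.label}" for t in trials])
    ss = np.random.SeedSequence(seed)
    out: list[FoldAssignment] = []
    for r, child in enumerate(ss.spawn(repeats)):
        rs = int(child.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(trials)), strata)):
            out.append(
                FoldAssignment(
                    repeat=r,
                    fold=f,
                    train_trials=frozenset(keys[i] for i in tr),
                    test_trials=frozenset(keys[i] for i in te),
                )
            )
    return out


def assert_no_leakage(assignments: list[FoldAssignment]) -> None:
    for a in assignments:
        overlap = a.train_trials & a.test_trials
        if overlap:
            raise AssertionError(f"trial leakage in repeat {a.repeat} fold {a.fold}: {overlap}")


# ---------------------------------------------------------------------------
# feature extraction over a dataset
# ---------------------------------------------------------------------------

def _segment_seed(config: RunConfig, participant: int, trial_id: int,
                  segment: int) -> int:
    return (config.seed * 1_000_003 + participant * 10_007
            + trial_id * 101 + segment) % (2 ** 31)


def extract_dataset_features(dataset: LabelledDataset, config: RunConfig,
                             apply_filters: bool = True) -> pd.DataFrame:
    """Preprocess, segment, decompose, and featurize every trial.

    Returns the feature table (one row per segment) with lineage columns.
    Deterministic: the noise channels of NA-MEMD are seeded per segment from
    the run seed and the segment's lineage.
    """
    trials = dataset.trials
    if apply_filters:
        processed = []
        for t in trials:
            rec = preprocessing.preprocess_recording(
                t.recording, target_rate=config.target_rate,
                hp_cutoff=config.highpass_cutoff, notch_band=config.notch_band,
                notch_order=config.notch_order,
            )
            processed.append(Trial(rec, t.label, t.participant, t.session, t.trial_id))
        trials = preprocessing.reject_noisy_trials(processed, config.amplitude_threshold)
    vectors = []
    for t in trials:
        for seg in preprocessing.segment_trial(t, config.window, config.step):
            if config.method == "namemd":
                imfset = na_memd(
                    seg.data, q=config.q,
                    noise_power_fraction=config.noise_power_fraction,
                    n_directions=config.n_directions, max_imfs=config.max_imfs,
                    seed=_segment_seed(config, t.participant, t.trial_id,
                                       seg.segment_index),
                    stop_constants=config.sift_thresholds,
                    max_sift_iterations=config.max_sift_iterations,
                    source_rate=seg.sampling_rate,
                )
                vectors.append(segment_features(seg, imfset, config.use_bands))
            elif config.method == "wpd":
                vectors.append(wpd_features(seg, config.wpd_level, config.wavelet))
            else:
                raise ConfigurationError(f"unknown method {config.method!r}")
    return features_to_frame(vectors)


# ---------------------------------------------------------------------------
# classifier harness
# ---------------------------------------------------------------------------

_CLASSICAL = {"svmlin": "svm_lin", "svm_lin": "svm_lin",
              "svmrbf": "svm_rbf", "svm_rbf": "svm_rbf",
              "lda": "lda", "knn": "knn"}


def make_classifier(config: RunConfig, input_length: int, n_classes: int,
                    seed: int):
    """Instantiate the configured classifier for one fold."""
    name = config.classifier
    if name == "mrf":
        spec = MRFNetworkSpec(
            branches=[SRFBranchSpec(first_kernel=kk, second_kernel=config.second_kernel,
                                    filters=config.filters, pool=config.pool,
                                    fc_units=config.fc_units)
                      for kk in config.branch_kernels],
            n_classes=n_classes, input_length=input_length,
            relu_before_pool=config.relu_before_pool,
        )
        return CNNClassifier(spec, seed=seed)
    if name.startswith("srf"):
        idx = int(name[3:]) - 1
        if not 0 <= idx < len(config.branch_kernels):
            raise ConfigurationError(f"no branch {name!r}")
        spec = MRFNetworkSpec(
            branches=[SRFBranchSpec(first_kernel=config.branch_kernels[idx],
                                    second_kernel=config.second_kernel,
                                    filters=config.filters, pool=config.pool,
                                    fc_units=config.fc_units)],
            n_classes=n_classes, input_length=input_length,
            relu_before_pool=config.relu_before_pool,
        )
        return CNNClassifier(spec, seed=seed)
    if name in _CLASSICAL:
        return classical_classifiers(_CLASSICAL[name],
                                     knn_neighbors=config.knn_neighbors, seed=seed)
    raise ConfigurationError(f"unknown classifier {name!r}")


def _fit_predict(clf, Xtr, ytr, Xte, config: RunConfig) -> np.ndarray:
    if isinstance(clf, CNNClassifier):
        clf.fit(Xtr, ytr, lr=config.learning_rate, iterations=config.iterations,
                batch_size=config.batch_size)
        return clf.predict(Xte)[0]
    clf.fit(Xtr, ytr)
    return np.asarray(clf.predict(Xte))


# ---------------------------------------------------------------------------
# confusion and tests
# ---------------------------------------------------------------------------

def confusion(true: np.ndarray, pred: np.ndarray,
              n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts[i, j] = #(true i, predicted j), plus the row-normalized form."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ConfigurationError("label vectors differ in length")
    if true.size and (min(true.min(), pred.min()) < 0
                      or max(true.max(), pred.max()) >= n_classes):
        raise ConfigurationError(f"label outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (true, pred), 1)
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, normalized


def paired_t_test(acc_a: np.ndarray, acc_b: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test on fold-paired accuracy differences."""
    a = np.asarray(acc_a, dtype=float).ravel()
    b = np.asarray(acc_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ConfigurationError("need two equal-length vectors of >= 2 folds")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult(t=float("nan"), p=float("nan"),
                                mean_difference=float(d.mean()), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p),
                            mean_difference=float(d.mean()), degenerate=False)


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment (reported as an extension; the primary
    report carries raw p-values)."""
    from statsmodels.stats.multitest import multipletests

    keys = [k for k, v in pvalues.items() if np.isfinite(v)]
    if not keys:
        return {}
    _, adj, _, _ = multipletests([pvalues[k] for k in keys], method="holm")
    return dict(zip(keys, adj.tolist()))


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def evaluate_features(df: pd.DataFrame, config: RunConfig, n_classes: int,
                      feature_columns: list[str] | None = None) -> EvaluationReport:
    """Repeated k-fold CV of the configured classifier on a feature table.

    Folds are drawn over trials per participant; segments follow their trial.
    """
    lineage_cols = {"label", "participant", "trial", "segment"}
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c not in lineage_cols]
    participants = sorted(df["participant"].unique())
    all_fold_accs: list[float] = []
    per_participant: dict[int, tuple[float, float]] = {}
    counts_total = np.zeros((n_classes, n_classes), dtype=int)
    vote_correct = vote_total = 0

    for p in participants:
        sub = df[df["participant"] == p]
        trial_rows = sub.drop_duplicates("trial")
        pseudo_trials = [
            Trial(recording=None, label=int(r.label), participant=p,
                  session=0, trial_id=int(r.trial))
            for r in trial_rows.itertuples()
        ]
        assignments = repeated_kfold(pseudo_trials, config.k, config.repeats,
                                     seed=config.seed + p)
        assert_no_leakage(assignments)
        keys = list(zip(sub["participant"].astype(int), sub["trial"].astype(int)))
        X = sub[feature_columns].to_numpy(dtype=float)
        y = sub["label"].to_numpy(dtype=int)
        trial_ids = sub["trial"].to_numpy(dtype=int)
        p_accs = []
        for a in assignments:
            te_mask = np.array([key in a.test_trials for key in keys])
            tr_mask = ~te_mask
            Xtr, Xte = X[tr_mask], X[te_mask]
            if config.standardize:
                Xtr, Xte, _ = standardize(Xtr, Xte)
            clf_seed = (config.seed * 7919 + p * 613 + a.repeat * 101
                        + a.fold) % (2 ** 31)
            clf = make_classifier(config, len(feature_columns), n_classes, clf_seed)
            pred = _fit_predict(clf, Xtr, y[tr_mask], Xte, config)
            y_te = y[te_mask]
            acc = float(np.mean(pred == y_te))
            p_accs.append(acc)
            c, _ = confusion(y_te, pred, n_classes)
            counts_total += c
            # trial-level majority vote over each test trial's segments
            tid_te = trial_ids[te_mask]
            for tid in np.unique(tid_te):
                m = tid_te == tid
                votes = np.bincount(pred[m], minlength=n_classes)
                vote_total += 1
                vote_correct += int(votes.argmax() == y_te[m][0])
        per_participant[p] = (float(np.mean(p_accs)), float(np.std(p_accs, ddof=1)))
        all_fold_accs.extend(p_accs)

    fold_arr = np.array(all_fold_accs)
    total = counts_total.sum()
    row_sums = counts_total.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts_total / row_sums, 0.0)
    return EvaluationReport(
        # rows are repeats (stacked over participants), columns are folds
        fold_accuracies=fold_arr.reshape(-1, config.k) if fold_arr.size else fold_arr,
        mean_accuracy=float(fold_arr.mean()),
        sd_accuracy=float(fold_arr.std(ddof=1)) if fold_arr.size > 1 else 0.0,
        confusion_counts=counts_total,
        confusion_normalized=normalized,
        pooled_accuracy=float(np.trace(counts_total) / total) if total else float("nan"),
        trial_vote_accuracy=float(vote_correct / vote_total) if vote_total else float("nan"),
        per_participant=per_participant,
    )


def run_pipeline(dataset: LabelledDataset, config: RunConfig,
                 apply_filters: bool = True) -> EvaluationReport:
    """The full chain: preprocess, decompose, featurize, cross-validate."""
    df = extract_dataset_features(dataset, config, apply_filters=apply_filters)
    n_classes = dataset.ground_truth.n_classes
    return evaluate_features(df, config, n_classes)


def per_band_accuracy(dataset: LabelledDataset, config: RunConfig,
                      bands: tuple[int, ...] | None = None,
                      apply_filters: bool = True,
                      features: pd.DataFrame | None = None) -> pd.DataFrame:
    """CV accuracy restricted to each single sub-band, and to all bands.

    Returns a table with one row per band (plus ``"all"``) per participant.
    """
    if bands is None:
        bands = config.use_bands
    df = (features if features is not None
          else extract_dataset_features(dataset, config, apply_filters=apply_filters))
    n_classes = dataset.ground_truth.n_classes
    rows = []
    for band in list(bands) + ["all"]:
        if band == "all":
            cols = None
        else:
            cols = [c for c in df.columns if f"_band{band}_" in c]
            if not cols:
                raise ConfigurationError(f"no feature columns for band {band}")
        report = evaluate_features(df, config, n_classes, feature_columns=cols)
        for p, (m, s) in report.per_participant.items():
            rows.append({"band": band, "participant": p,
                         "mean_accuracy": m, "sd_accuracy": s})
        rows.append({"band": band, "participant": "all",
                     "mean_accuracy": report.mean_accuracy,
                     "sd_accuracy": report.sd_accuracy})
    return pd.DataFrame(rows)
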