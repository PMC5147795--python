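"""Repeated stratified cross-validation with internal feature selection.

The evaluation protocol: the cohort is split into ``folds`` stratified
subsets; each fold in turn is held out as a test sample while feature
selection (SVM-RFE, uniform random subsets, or none) and classifier
training run on the remaining folds only; after one pass every subject
has been tested exactly once.  The whole procedure is repeated
``repetitions`` times with fresh random splits, and accuracy /
sensitivity / specificity are reported as mean +/- SD over repetitions
as a function of the number of selected features.

Chance performance is estimated by Y-randomization: half of each class
in the training fold swaps labels while the test fold keeps its true
labels.  Curves are compared with the variance-corrected resampled
t-test for repeated cross-validation (the correction inflates the
variance by the train/test overlap term ``test_fraction / (1 -
test_fraction)``).

The classifier is a linear soft-margin SVM (libsvm's SMO solver);
features are z-scored with training-fold statistics only, so no
information from the test fold can leak into selection or scaling.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "TrainerConfig",
    "ProtocolConfig",
    "FoldRecord",
    "ProtocolResult",
    "rfe_rank",
    "select_random_features",
    "y_randomize_training",
    "classification_metrics",
    "corrected_resampled_ttest",
    "run_protocol",
    "compare_results",
    "DEFAULT_GRID",
]

POSITIVE = "HR"
NEGATIVE = "LR"
DEFAULT_GRID = (4, 8, 16, 32, 48, 64, 96, 128, 168)

RESULT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TrainerConfig:
    """Linear SVM settings: soft-margin cost and training-fold z-scoring."""

    svm_cost: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Repeated-CV settings.

    ``fs_method``: ``"rfe"`` ranks features by SVM-RFE inside each
    training fold; ``"random"`` draws a fresh uniform subset per fold and
    subset size; ``"none"`` takes features in schema order (so the full
    grid value equals a plain SVM).  ``n_features_grid`` is the list of
    subset sizes evaluated.
    """

    folds: int = 10
    repetitions: int = 100
    fs_method: str = "rfe"
    n_features_grid: tuple[int, ...] = DEFAULT_GRID
    y_randomize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.fs_method not in ("rfe", "random", "none"):
            raise ValueError(f"unknown fs_method: {self.fs_method!r}")
        object.__setattr__(self, "n_features_grid", tuple(int(n) for n in self.n_features_grid))
        if any(n < 1 for n in self.n_features_grid):
            raise ValueError("grid sizes must be >= 1")


def _make_svm(trainer: TrainerConfig) -> SVC:
    return SVC(kernel="linear", C=trainer.svm_cost)


def _check_classes(labels: np.ndarray, minimum: int = 2) -> None:
    values, counts = np.unique(labels, return_counts=True)
    if len(values) != 2 or counts.min() < minimum:
        raise ValueError(
            f"need two classes with at least {minimum} members each, "
            f"got {dict(zip(values.tolist(), counts.tolist()))}"
        )


def rfe_rank(
    X: np.ndarray, labels: np.ndarray, trainer: TrainerConfig = TrainerConfig()
) -> np.ndarray:
    """Full SVM-RFE feature ranking, best to worst.

    Iteratively fits a linear SVM on the surviving features, squares the
    weight vector, and removes the single lowest-weight feature until
    none remain; the ranking is the reverse elimination order.  Weight
    ties are broken deterministically by removing the feature with the
    larger column index first.

    ``X`` is used as given; standardize beforehand if the features are
    on different scales.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one feature")
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        clf = _make_svm(trainer).fit(X[:, surviving], labels)
        w2 = np.ravel(clf.coef_) ** 2
        lowest = w2.min()
        worst = max(surviving[j] for j in range(len(surviving)) if w2[j] == lowest)
        eliminated.append(worst)
        surviving.remove(worst)
    eliminated.append(surviving[0])
    return np.array(eliminated[::-1], dtype=int)


def select_random_features(
    n: int, n_features: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform feature subset without replacement (sorted indices)."""
    if not 1 <= n <= n_features:
        raise ValueError(f"need 1 <= n <= {n_features}, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.sort(rng.choice(n_features, size=n, replace=False))


def y_randomize_training(
    labels: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Let half of each class in a training fold swap places.

    Flips the labels of ``floor(n_c / 2)`` randomly chosen members of
    each class ``c``; feature rows are untouched and test labels are
    never randomized.
    """
    labels = np.asarray(labels).copy()
    _check_classes(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = np.unique(labels)
    other = {classes[0]: classes[1], classes[1]: classes[0]}
    flips = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        flips.append(rng.choice(members, size=len(members) // 2, replace=False))
    for c, idx in zip(classes, flips):
        labels[idx] = other[c]
    return labels


def classification_metrics(
    truth: np.ndarray, predicted: np.ndarray, positive: str = POSITIVE
) -> dict[str, float | None]:
    """Accuracy, sensitivity and specificity in percent.

    The high-risk class is positive: sensitivity is the share of HR
    subjects identified, specificity the share of LR subjects excluded.
    Undefined ratios (no members of a class) are reported as None.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) == 0 or len(truth) != len(predicted):
        raise ValueError("need equal-length, non-empty truth and prediction arrays")
    pos = truth == positive
    correct = truth == predicted
    return {
        "accuracy": 100.0 * float(correct.mean()),
        "sensitivity": 100.0 * float(correct[pos].mean()) if pos.any() else None,
        "specificity": 100.0 * float(correct[~pos].mean()) if (~pos).any() else None,
    }


def corrected_resampled_ttest(
    diffs: np.ndarray, test_fraction: float
) -> tuple[float, float]:
    """Variance-corrected paired t-test for repeated cross-validation.

    ``t = mean(d) / sqrt((1/k + r/(1-r)) * var(d))`` with sample variance,
    ``r`` the test fraction and ``k - 1`` degrees of freedom; returns the
    two-sided p value.  Zero variance yields t = 0/p = 1 for zero mean
    and +/-inf / p = 0 otherwise.
    """
    diffs = np.asarray(diffs, dtype=float)
    k = len(diffs)
    if k < 2:
        raise ValueError("need at least 2 resampled differences")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    mean = diffs.mean()
    var = diffs.var(ddof=1)
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / math.sqrt((1.0 / k + test_fraction / (1.0 - test_fraction)) * var)
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 1))
    return float(t), p


@dataclass
class FoldRecord:
    """Everything one training fold produced."""

    repetition: int
    fold: int
    test_idx: np.ndarray
    selected: dict[int, np.ndarray]  # subset size -> feature indices
    predictions: dict[int, np.ndarray]  # subset size -> predicted labels


@dataclass
class ProtocolResult:
    """Full record of one repeated-CV run."""

    protocol: ProtocolConfig
    trainer: TrainerConfig
    feature_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray
    fold_records: list[FoldRecord]
    rep_scores: dict[int, pd.DataFrame] = field(repr=False)  # n -> (reps x 3 metrics)
    fold_accuracy: dict[int, np.ndarray] = field(repr=False)  # n -> (reps, folds)

    def curve(self) -> pd.DataFrame:
        """Mean +/- SD (over repetitions) of the three metrics per subset size."""
        rows = {}
        for n, df in self.rep_scores.items():
            row = {}
            for m in ("accuracy", "sensitivity", "specificity"):
                row[f"{m}_mean"] = float(df[m].mean())
                row[f"{m}_sd"] = float(df[m].std(ddof=1)) if len(df) > 1 else 0.0
            rows[n] = row
        out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        out.index.name = "n_features"
        return out

    @property
    def best_n(self) -> int:
        """Subset size with the highest mean accuracy (ties -> smallest n)."""
        curve = self.curve()
        return int(curve["accuracy_mean"].idxmax())

    def to_dict(self) -> dict:
        return {
            "schema_version": RESULT_SCHEMA_VERSION,
            "protocol": asdict(self.protocol),
            "trainer": asdict(self.trainer),
            "feature_ids": self.feature_ids,
            "subject_ids": self.subject_ids,
            "labels": self.labels.tolist(),
            "curve": {
                str(n): {k: v for k, v in row.items()}
                for n, row in self.curve().to_dict(orient="index").items()
            },
            "rep_scores": {
                str(n): df.to_dict(orient="list") for n, df in self.rep_scores.items()
            },
            "fold_accuracy": {
                str(n): arr.tolist() for n, arr in self.fold_accuracy.items()
            },
            "fold_records": [
                {
                    "repetition": fr.repetition,
                    "fold": fr.fold,
                    "test_idx": fr.test_idx.tolist(),
                    "selected": {str(n): v.tolist() for n, v in fr.selected.items()},
                    "predictions": {str(n): v.tolist() for n, v in fr.predictions.items()},
                }
                for fr in self.fold_records
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolResult":
        protocol = ProtocolConfig(**d["protocol"])
        trainer = TrainerConfig(**d["trainer"])
        fold_records = [
            FoldRecord(
                repetition=fr["repetition"],
                fold=fr["fold"],
                test_idx=np.array(fr["test_idx"], dtype=int),
                selected={int(n): np.array(v, dtype=int) for n, v in fr["selected"].items()},
                predictions={int(n): np.array(v) for n, v in fr["predictions"].items()},
            )
            for fr in d["fold_records"]
        ]
        return cls(
            protocol=protocol,
            trainer=trainer,
            feature_ids=list(d["feature_ids"]),
            subject_ids=list(d["subject_ids"]),
            labels=np.array(d["labels"]),
            fold_records=fold_records,
            rep_scores={int(n): pd.DataFrame(v) for n, v in d["rep_scores"].items()},
            fold_accuracy={int(n): np.array(v) for n, v in d["fold_accuracy"].items()},
        )

    @classmethod
    def from_json(cls, path: str) -> "ProtocolResult":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def run_protocol(
    feature_matrix: np.ndarray | pd.DataFrame,
    labels: np.ndarray | None = None,
    protocol: ProtocolConfig = ProtocolConfig(),
    trainer: TrainerConfig = TrainerConfig(),
    feature_ids: list[str] | None = None,
    subject_ids: list[str] | None = None,
) -> ProtocolResult:
    """Run the full repeated-CV protocol and collect every fold's output.

    ``feature_matrix`` may be the DataFrame from
    :func:`gazescreen.features.cohort_feature_table` (its ``label``
    column then supplies ``labels``) or a plain (subjects x features)
    array with a separate label vector.  All feature selection and
    standardization happen strictly inside each training fold.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        df = feature_matrix
        if labels is None:
            if "label" not in df.columns:
                raise ValueError("DataFrame input needs a 'label' column or explicit labels")
            labels = df["label"].to_numpy()
        subject_ids = subject_ids or [str(s) for s in df.index]
        value_cols = [c for c in df.columns if c != "label"]
        feature_ids = feature_ids or [str(c) for c in value_cols]
        X = df[value_cols].to_numpy(float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        if labels is None:
            raise ValueError("labels are required with array input")
        labels = np.asarray(labels)
    n_subjects, n_features = X.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_features)]
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n_subjects)]
    if len(labels) != n_subjects:
        raise ValueError("labels length must match the number of subjects")
    _check_classes(labels, minimum=protocol.folds)
    grid = tuple(n for n in protocol.n_features_grid if n <= n_features)
    if not grid:
        raise ValueError("no grid size fits the feature dimension")

    root = np.random.SeedSequence(protocol.seed)
    rep_seqs = root.spawn(protocol.repetitions)
    strat = (labels == POSITIVE).astype(int) if POSITIVE in labels else labels

    fold_records: list[FoldRecord] = []
    rep_rows: dict[int, list[dict]] = {n: [] for n in grid}
    fold_acc: dict[int, np.ndarray] = {
        n: np.empty((protocol.repetitions, protocol.folds)) for n in grid
    }

    for rep in range(protocol.repetitions):
        rep_seq = rep_seqs[rep]
        split_seed = int(rep_seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        fold_seqs = rep_seq.spawn(protocol.folds)
        skf = StratifiedKFold(
            n_splits=protocol.folds, shuffle=True, random_state=split_seed
        )
        rep_truth: list[np.ndarray] = []
        rep_pred: dict[int, list[np.ndarray]] = {n: [] for n in grid}
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, strat)):
            rng = np.random.default_rng(fold_seqs[fold])
            y_train = labels[train_idx]
            try:
                _check_classes(y_train)
            except ValueError as err:
                raise ValueError(
                    f"degenerate class composition in repetition {rep}, fold {fold}: {err}"
                ) from err
            if protocol.y_randomize:
                y_train = y_randomize_training(y_train, rng)
            if trainer.standardize:
                scaler = StandardScaler().fit(X[train_idx])
                X_train = scaler.transform(X[train_idx])
                X_test = scaler.transform(X[test_idx])
            else:
                X_train = X[train_idx]
                X_test = X[test_idx]

            ranking = (
                rfe_rank(X_train, y_train, trainer)
                if protocol.fs_method == "rfe"
                else None
            )
            selected: dict[int, np.ndarray] = {}
            predictions: dict[int, np.ndarray] = {}
            for n in grid:
                if ranking is not None:
                    sel = ranking[:n]
                elif protocol.fs_method == "random":
                    sel = select_random_features(n, n_features, rng)
                else:  # "none": schema order, full grid value == plain SVM
                    sel = np.arange(n)
                clf = _make_svm(trainer).fit(X_train[:, sel], y_train)
                pred = clf.predict(X_test[:, sel])
                selected[n] = np.asarray(sel, dtype=int)
                predictions[n] = pred
                fold_acc[n][rep, fold] = float((pred == labels[test_idx]).mean())
                rep_pred[n].append(pred)
            rep_truth.append(labels[test_idx])
            fold_records.append(
                FoldRecord(rep, fold, np.asarray(test_idx), selected, predictions)
            )
        truth = np.concatenate(rep_truth)
        for n in grid:
            rep_rows[n].append(
                classification_metrics(truth, np.concatenate(rep_pred[n]))
            )

    rep_scores = {n: pd.DataFrame(rows) for n, rows in rep_rows.items()}
    return ProtocolResult(
        protocol=protocol,
        trainer=trainer,
        feature_ids=list(feature_ids),
        subject_ids=list(subject_ids),
        labels=np.asarray(labels),
        fold_records=fold_records,
        rep_scores=rep_scores,
        fold_accuracy=fold_acc,
    )


def compare_results(
    result_a: ProtocolResult,
    result_b: ProtocolResult,
    n_a: int | None = None,
    n_b: int | None = None,
) -> tuple[float, float]:
    """Corrected resampled t-test between two runs' per-fold accuracies.

    Pairs the ``folds x repetitions`` fold-level accuracy differences;
    both runs must share folds, repetitions and protocol seed so their
    splits coincide.  Subset sizes default to each run's best n.
    """
    pa, pb = result_a.protocol, result_b.protocol
    if (pa.folds, pa.repetitions, pa.seed) != (pb.folds, pb.repetitions, pb.seed):
        raise ValueError("results use different resampling plans; folds are not paired")
    n_a = result_a.best_n if n_a is None else n_a
    n_b = result_b.best_n if n_b is None else n_b
    d = result_a.fold_accuracy[n_a].ravel() - result_b.fold_accuracy[n_b].ravel()
    return corrected_resampled_ttest(d, test_fraction=1.0 / pa.folds)
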