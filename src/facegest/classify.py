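"""Balanced-subsample repeated classification harness.

Each run draws a fresh class-balanced subsample, splits it 70/30 with
stratification, and fits three classifier families on byte-identical
train/test folds: a single-hidden-layer perceptron (MLP), a degree-2
polynomial-kernel support vector machine tuned over a fixed grid (SVM),
and a 500-tree random forest (RFC).  Correct classification rate (CCR),
precision, recall, and F1 are recorded per run for train and test; runs
are aggregated as mean +/- SD and the per-run pairing supports paired
t-tests between the families.

Defaults mirror the study design: 3000 instances per class for the
voiced/unvoiced task, 200 per class for the 8-context task (matched to
the rarest category, yawning), 100 runs, 70% training fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import split_columns
from .io_dlc import CONTEXTS, VOICINGS

ALGORITHMS: tuple[str, ...] = ("mlp", "svm", "rfc")
METRICS: tuple[str, ...] = ("accuracy", "precision", "recall", "f1")

#: Fixed class orders used for confusion matrices and reports.
TASK_CLASSES: dict[str, tuple[str, ...]] = {"voicing": VOICINGS, "context": CONTEXTS}


@dataclass(frozen=True)
class HarnessConfig:
    """Configuration of the repeated-subsample classification harness."""

    task: str = "voicing"  # "voicing" (2-class) or "context" (8-class)
    n_per_class: int | None = None  # default: 3000 voicing / 200 context
    n_runs: int = 100
    train_fraction: float = 0.70
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS
    # SVM tuning grid (degree-2 polynomial kernel)
    svm_gamma: tuple[float, ...] = tuple(round(0.005 * k, 3) for k in range(1, 11))
    svm_cost: tuple[float, ...] = tuple(10.0**e for e in range(-8, 1))
    svm_coef0: tuple[float, ...] = (0.1, 1.0, 10.0)
    svm_degree: int = 2
    svm_tune_folds: int = 3
    # random forest
    rf_n_trees: int = 500
    rf_mtry: int = 3
    # single-hidden-layer perceptron
    mlp_hidden: int = 5
    mlp_learning_rate: float = 0.1
    mlp_max_epochs: int = 100
    group_by_clip: bool = False  # optional clip-grouped splitting (off by default)

    def __post_init__(self) -> None:
        if self.task not in TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        if self.n_per_class is None:
            object.__setattr__(self, "n_per_class", 3000 if self.task == "voicing" else 200)

    @property
    def label_column(self) -> str:
        return "voicing" if self.task == "voicing" else "context"

    @property
    def classes(self) -> tuple[str, ...]:
        return TASK_CLASSES[self.task]


@dataclass
class RunResult:
    """Per-run metrics and test confusion matrices for each algorithm."""

    run_index: int
    class_order: tuple[str, ...]
    metrics: dict[tuple[str, str], dict[str, float]]  # (algorithm, split) -> metric -> value
    confusion: dict[str, np.ndarray]  # algorithm -> test confusion counts


@dataclass
class PairComparison:
    """Paired comparison of two algorithms' per-run test CCRs."""

    pair: tuple[str, str]
    shapiro_w: float
    shapiro_p: float
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False  # zero-variance differences: t undefined


@dataclass
class ComparisonResult:
    comparisons: list[PairComparison]
    metric: str = "accuracy"


def _run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Derive one reproducible sub-seed per run from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_runs)]


def balanced_subsample(
    table: pd.DataFrame, config: HarnessConfig, run_seed: int
) -> pd.DataFrame:
    """Draw exactly ``n_per_class`` rows per class without replacement."""
    rng = np.random.default_rng(run_seed)
    label = config.label_column
    parts = []
    for cls in config.classes:
        pool = np.flatnonzero((table[label] == cls).to_numpy())
        if len(pool) < config.n_per_class:
            raise ValueError(
                f"class {cls!r} has {len(pool)} rows, fewer than "
                f"n_per_class={config.n_per_class}"
            )
        chosen = rng.choice(pool, size=config.n_per_class, replace=False)
        parts.append(table.iloc[np.sort(chosen)])
    return pd.concat(parts, ignore_index=True)


def _binary_positive(classes: Sequence[str]) -> str:
    # voiced frames are the positive class in the 2-class task
    return "vo" if "vo" in classes else classes[0]


def _metric_block(y_true, y_pred, classes: Sequence[str]) -> dict[str, float]:
    accuracy = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    if len(classes) == 2:
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=_binary_positive(classes),
            zero_division=0,
        )
    else:
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
    return {"accuracy": accuracy, "precision": float(prec), "recall": float(rec), "f1": float(f1)}


def _fit_predict(
    algo: str,
    config: HarnessConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one family and return (train predictions, test predictions)."""
    if algo == "rfc":
        model = RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_features=min(config.rf_mtry, X_train.shape[1]),
            random_state=seed,
        )
        model.fit(X_train, y_train)
        return model.predict(X_train), model.predict(X_test)

    # scale-sensitive learners get train-fitted standardization
    scaler = StandardScaler().fit(X_train)
    Xtr, Xte = scaler.transform(X_train), scaler.transform(X_test)
    if algo == "mlp":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = MLPClassifier(
                hidden_layer_sizes=(config.mlp_hidden,),
                solver="sgd",
                learning_rate_init=config.mlp_learning_rate,
                max_iter=config.mlp_max_epochs,
                random_state=seed,
            )
            model.fit(Xtr, y_train)
    elif algo == "svm":
        grid = {
            "gamma": list(config.svm_gamma),
            "C": list(config.svm_cost),
            "coef0": list(config.svm_coef0),
        }
        search = GridSearchCV(
            SVC(kernel="poly", degree=config.svm_degree),
            grid,
            cv=config.svm_tune_folds,
            n_jobs=None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(Xtr, y_train)
        model = search.best_estimator_
    else:  # pragma: no cover
        raise ValueError(f"unknown algorithm {algo!r}")
    return model.predict(Xtr), model.predict(Xte)


def run_once(subsample: pd.DataFrame, config: HarnessConfig, run_seed: int) -> RunResult:
    """One run: a shared stratified 70/30 split, all families on the same folds."""
    feats, _ = split_columns(subsample)
    X = subsample[feats].to_numpy(dtype=float)
    y = subsample[config.label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    ss = np.random.SeedSequence(run_seed)
    split_seed, *algo_seeds = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(1 + len(ALGORITHMS))
    )
    algo_seed = dict(zip(ALGORITHMS, algo_seeds))
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=config.train_fraction, stratify=y, random_state=split_seed
    )
    metrics: dict[tuple[str, str], dict[str, float]] = {}
    confusion: dict[str, np.ndarray] = {}
    for algo in config.algorithms:
        pred_train, pred_test = _fit_predict(
            algo, config, X_train, y_train, X_test, algo_seed[algo]
        )
        metrics[(algo, "train")] = _metric_block(y_train, pred_train, config.classes)
        metrics[(algo, "test")] = _metric_block(y_test, pred_test, config.classes)
        confusion[algo] = confusion_matrix(y_test, pred_test, labels=list(config.classes))
    return RunResult(
        run_index=-1, class_order=config.classes, metrics=metrics, confusion=confusion
    )


def run_harness(table: pd.DataFrame, config: HarnessConfig) -> list[RunResult]:
    """Run the full repeated design: fresh balanced subsample + split per run."""
    results = []
    for run_index, run_seed in enumerate(_run_seeds(config.seed, config.n_runs)):
        sub = balanced_subsample(table, config, run_seed)
        result = run_once(sub, config, run_seed)
        result.run_index = run_index
        results.append(result)
    return results


def aggregate(results: Sequence[RunResult]) -> dict:
    """Mean +/- SD of every metric, plus row-normalized mean confusion (percent).

    Returns ``{"summary": DataFrame, "confusion": {algorithm: DataFrame}}``.
    The summary has one row per metric and a (algorithm, split, stat) column
    MultiIndex; confusion rows (true classes) sum to 100.
    """
    if len(results) < 2:
        raise ValueError("aggregation needs at least 2 runs")
    keys = list(results[0].metrics)
    records = {}
    for algo, split in keys:
        for metric in METRICS:
            series = np.array([r.metrics[(algo, split)][metric] for r in results])
            records[(algo, split, "mean")] = records.get((algo, split, "mean"), {})
            records[(algo, split, "mean")][metric] = series.mean()
            records[(algo, split, "sd")] = records.get((algo, split, "sd"), {})
            records[(algo, split, "sd")][metric] = series.std(ddof=1)
    summary = pd.DataFrame(records).loc[list(METRICS)]
    summary.columns.names = ("algorithm", "split", "stat")

    confusion = {}
    classes = list(results[0].class_order)
    for algo in results[0].confusion:
        stack = []
        for r in results:
            counts = r.confusion[algo].astype(float)
            stack.append(100.0 * counts / counts.sum(axis=1, keepdims=True))
        confusion[algo] = pd.DataFrame(
            np.mean(stack, axis=0), index=classes, columns=classes
        )
    return {"summary": summary, "confusion": confusion}


def compare_algorithms(
    results: Sequence[RunResult], metric: str = "accuracy", split: str = "test"
) -> ComparisonResult:
    """Shapiro-Wilk then paired t-test on per-run CCR differences, per pair.

    Pairing is valid because each run feeds byte-identical folds to every
    family.  Differences with zero variance are flagged as degenerate (the
    t statistic is undefined there).
    """
    if len(results) < 3:
        raise ValueError("paired comparison needs at least 3 runs")
    algos = [a for a in ALGORITHMS if (a, split) in results[0].metrics]
    series = {
        a: np.array([r.metrics[(a, split)][metric] for r in results]) for a in algos
    }
    comparisons = []
    for a, b in combinations(algos, 2):
        diff = series[a] - series[b]
        n = len(diff)
        if np.ptp(diff) == 0.0:
            comparisons.append(
                PairComparison(
                    pair=(a, b), shapiro_w=np.nan, shapiro_p=np.nan,
                    t_statistic=np.nan, df=n - 1, p_value=np.nan,
                    mean_difference=float(diff.mean()), degenerate=True,
                )
            )
            continue
        sw = stats.shapiro(diff)
        tt = stats.ttest_rel(series[a], series[b])
        comparisons.append(
            PairComparison(
                pair=(a, b),
                shapiro_w=float(sw.statistic),
                shapiro_p=float(sw.pvalue),
                t_statistic=float(tt.statistic),
                df=n - 1,
                p_value=float(tt.pvalue),
                mean_difference=float(diff.mean()),
            )
        )
    return ComparisonResult(comparisons=comparisons, metric=metric)
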