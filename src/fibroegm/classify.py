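"""Decision-tree characterization of the fibrotic substrate.

A labeled feature table (one row per bipolar trace) feeds three tasks:
binary fibrotic vs. non-fibrotic, five-class fibrosis density, and
four-class transmurality.  Each hold-out realization draws a stratified
70/15/15 train/validation/test split, runs greedy forward feature selection
with correlation pruning (|Pearson r| > 0.6 candidates dropped against the
already-selected set), trains an impurity-based tree on the selected
features, and scores the held-out test set.  Metrics are averaged over
realizations and reported as mean +- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, ParameterError
from .features import FEATURE_NAMES

TASKS = ("binary", "density", "transmurality")

#: Column holding the class label of each task.
TASK_COLUMNS = {
    "binary": "binary_label",
    "density": "density_class",
    "transmurality": "transmurality_class",
}

POSITIVE_BINARY = "fibrotic"
CORR_THRESHOLD = 0.6
SPLIT_FRACTIONS = (0.70, 0.15, 0.15)

TREE_PARAMS = dict(criterion="gini", min_samples_leaf=3)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple = SPLIT_FRACTIONS
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ParameterError("split fractions must sum to 1")


@dataclass
class TrainedModel:
    tree: DecisionTreeClassifier
    features: list
    task: str
    seed: int


@dataclass
class EvalReport:
    """Aggregate metrics of repeated hold-out realizations (percent)."""

    task: str
    n_realizations: int
    accuracy_mean: float
    accuracy_se: float
    sensitivity_mean: float
    sensitivity_se: float
    specificity_mean: float
    specificity_se: float
    validation_accuracy_mean: float
    confusion: np.ndarray = field(repr=False)
    classes: list = field(default_factory=list)
    selected_features: list = field(default_factory=list)  # per realization

    def summary(self) -> str:
        lines = [
            f"task: {self.task} ({self.n_realizations} hold-out realizations)",
            f"accuracy:    {self.accuracy_mean:.2f} +- {self.accuracy_se:.2f} %",
            f"sensitivity: {self.sensitivity_mean:.2f} +- {self.sensitivity_se:.2f} %",
            f"specificity: {self.specificity_mean:.2f} +- {self.specificity_se:.2f} %",
            f"validation accuracy: {self.validation_accuracy_mean:.2f} %",
            f"classes: {self.classes}",
            "summed confusion matrix (rows = truth):",
            str(self.confusion),
        ]
        return "\n".join(lines)


def assemble_dataset(
    simulated: pd.DataFrame, control_substitutes: pd.DataFrame | None
) -> pd.DataFrame:
    """Concatenate simulated rows with control-substitute rows.

    Substitutes play the role of clinically recorded non-fibrotic signals
    and must carry non-fibrotic labels throughout.
    """
    if simulated is None or len(simulated) == 0:
        raise DataError("simulated feature table is empty")
    frames = [simulated]
    if control_substitutes is not None and len(control_substitutes):
        missing = set(simulated.columns) - set(control_substitutes.columns)
        if missing:
            raise DataError(f"substitute table lacks columns {sorted(missing)}")
        bad = control_substitutes["binary_label"] != "non-fibrotic"
        if bad.any():
            raise DataError("control substitutes must be labeled non-fibrotic")
        frames.append(control_substitutes[simulated.columns])
    out = pd.concat(frames, ignore_index=True)
    _check_label_consistency(out)
    return out


def _check_label_consistency(df: pd.DataFrame) -> None:
    nonfib = df["binary_label"] == "non-fibrotic"
    if not (
        (df.loc[nonfib, "density_class"] == "none").all()
        and (df.loc[nonfib, "transmurality_class"] == "none").all()
        and (df.loc[~nonfib, "density_class"] != "none").all()
        and (df.loc[~nonfib, "transmurality_class"] != "none").all()
    ):
        raise DataError("binary/density/transmurality labels are inconsistent")


def _apportion(counts: np.ndarray, fraction: float, n_target: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_target`` samples across classes,
    proportional to class sizes, at least one per class."""
    quota = fraction * counts.astype(float)
    alloc = np.maximum(np.floor(quota).astype(int), 1)
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder, kind="stable")
    i = 0
    while alloc.sum() < n_target:
        alloc[order[i % len(alloc)]] += 1
        i += 1
    order_small = np.argsort(remainder, kind="stable")
    i = 0
    while alloc.sum() > n_target:
        j = order_small[i % len(alloc)]
        if alloc[j] > 1 and alloc[j] < counts[j]:
            alloc[j] -= 1
        i += 1
    return alloc


def split(dataset: pd.DataFrame, spec: SplitSpec, task: str = "binary"):
    """Stratified 70/15/15 partition; every class lands in every subset.

    Global subset sizes honor the fractions exactly (largest-remainder
    apportionment, leftovers to train); validation and test get at least
    one sample per class.  Classes with fewer than 3 samples are rejected.
    """
    col = TASK_COLUMNS[task]
    rng = np.random.default_rng(spec.seed)
    _, f_val, f_test = spec.fractions
    groups = list(dataset.groupby(col, sort=True))
    counts = np.array([len(g) for _, g in groups])
    if counts.min() < 3:
        bad = groups[int(np.argmin(counts))][0]
        raise DataError(f"class {bad!r} has {counts.min()} < 3 samples")
    n = counts.sum()
    n_val = _apportion(counts, f_val, int(round(f_val * n)))
    n_test = _apportion(counts, f_test, int(round(f_test * n)))
    train_idx, val_idx, test_idx = [], [], []
    for (_, group), kv, kt in zip(groups, n_val, n_test):
        perm = group.index.to_numpy()[rng.permutation(len(group))]
        val_idx.extend(perm[:kv])
        test_idx.extend(perm[kv : kv + kt])
        train_idx.extend(perm[kv + kt :])
    return (
        dataset.loc[train_idx],
        dataset.loc[val_idx],
        dataset.loc[test_idx],
    )


def _fit_tree(train: pd.DataFrame, features: list, task: str, seed: int):
    X = train[list(features)].to_numpy()
    y = train[TASK_COLUMNS[task]].to_numpy()
    tree = DecisionTreeClassifier(random_state=seed, **TREE_PARAMS)
    tree.fit(X, y)
    return tree


def _accuracy(tree, subset: pd.DataFrame, features: list, task: str) -> float:
    X = subset[list(features)].to_numpy()
    y = subset[TASK_COLUMNS[task]].to_numpy()
    return float(np.mean(tree.predict(X) == y))


def greedy_select(
    train: pd.DataFrame,
    val: pd.DataFrame,
    task: str,
    corr_threshold: float = CORR_THRESHOLD,
    candidates: tuple = FEATURE_NAMES,
    seed: int = 0,
) -> list:
    """Greedy forward feature selection with correlation pruning.

    Each round removes candidates whose |Pearson correlation| with any
    already-selected feature exceeds the threshold (computed on the training
    set), then adds the candidate that maximizes validation accuracy of a
    tree trained on the training set.  Stops when no candidate improves the
    accuracy; ties break by the canonical feature order.
    """
    selected: list = []
    best_acc = -np.inf
    corr = train[list(candidates)].corr().abs()
    while True:
        pool = [
            c
            for c in candidates
            if c not in selected
            and all(corr.loc[c, s] <= corr_threshold for s in selected)
        ]
        if not pool:
            break
        round_best = None
        for c in pool:  # canonical order -> first max wins ties
            tree = _fit_tree(train, selected + [c], task, seed)
            acc = _accuracy(tree, val, selected + [c], task)
            if round_best is None or acc > round_best[0]:
                round_best = (acc, c)
        if round_best[0] > best_acc:
            best_acc = round_best[0]
            selected.append(round_best[1])
        else:
            break
    return selected


def train_tree(
    train: pd.DataFrame, features: list, task: str, seed: int = 0
) -> TrainedModel:
    """Fit an axis-aligned impurity-based decision tree on selected features."""
    if not features:
        raise DataError("feature list is empty")
    if train[TASK_COLUMNS[task]].nunique() < 2:
        raise DataError("training set contains a single class")
    tree = _fit_tree(train, features, task, seed)
    return TrainedModel(tree=tree, features=list(features), task=task, seed=seed)


def evaluate(model: TrainedModel, test: pd.DataFrame, classes=None):
    """Confusion matrix and accuracy/sensitivity/specificity (percent).

    Binary: fibrotic is the positive class.  Multiclass: macro-averaged
    one-vs-rest sensitivity and specificity.
    """
    if len(test) == 0:
        raise DataError("test set is empty")
    col = TASK_COLUMNS[model.task]
    y = test[col].to_numpy()
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    known = set(model.tree.classes_)
    unseen = set(y) - known
    if unseen:
        raise DataError(f"test contains classes unseen in training: {sorted(unseen)}")
    pred = model.tree.predict(test[model.features].to_numpy())
    cm = confusion_matrix(y, pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum()) * 100.0

    sens_list, spec_list = [], []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens_list.append(tp / (tp + fn) if tp + fn else np.nan)
        spec_list.append(tn / (tn + fp) if tn + fp else np.nan)
    if model.task == "binary" and POSITIVE_BINARY in classes:
        i = classes.index(POSITIVE_BINARY)
        sensitivity = sens_list[i] * 100.0
        specificity = spec_list[i] * 100.0
    else:
        sensitivity = float(np.nanmean(sens_list)) * 100.0
        specificity = float(np.nanmean(spec_list)) * 100.0
    return cm, {"accuracy": acc, "sensitivity": sensitivity, "specificity": specificity}


def repeated_holdout(
    dataset: pd.DataFrame,
    task: str,
    n_realizations: int = 100,
    base_seed: int = 0,
) -> EvalReport:
    """n independent split -> select -> train -> evaluate cycles."""
    if n_realizations < 2:
        raise ParameterError("need at least 2 realizations")
    col = TASK_COLUMNS[task]
    classes = sorted(dataset[col].unique().tolist())
    accs, sens, specs, vaccs = [], [], [], []
    cm_sum = np.zeros((len(classes), len(classes)), dtype=int)
    sel_all = []
    for k in range(n_realizations):
        seed = base_seed + k
        train, val, test = split(dataset, SplitSpec(seed=seed), task)
        feats = greedy_select(train, val, task, seed=seed)
        if not feats:
            feats = [FEATURE_NAMES[0]]
        model = train_tree(train, feats, task, seed=seed)
        cm, metrics = evaluate(model, test, classes=classes)
        cm_sum += cm
        accs.append(metrics["accuracy"])
        sens.append(metrics["sensitivity"])
        specs.append(metrics["specificity"])
        vaccs.append(_accuracy(model.tree, val, feats, task) * 100.0)
        sel_all.append(feats)

    def se(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    return EvalReport(
        task=task,
        n_realizations=n_realizations,
        accuracy_mean=float(np.mean(accs)),
        accuracy_se=se(accs),
        sensitivity_mean=float(np.mean(sens)),
        sensitivity_se=se(sens),
        specificity_mean=float(np.mean(specs)),
        specificity_se=se(specs),
        validation_accuracy_mean=float(np.mean(vaccs)),
        confusion=cm_sum,
        classes=classes,
        selected_features=sel_all,
    )


def height_sweep(model: TrainedModel, test_sets: dict, classes=None):
    """Evaluate a contact-trained model on feature tables regenerated at
    increasing electrode heights.

    ``test_sets`` maps height (mm) to a feature table; heights must be
    sorted ascending starting at 0.  Returns a DataFrame (height, accuracy).
    """
    heights = list(test_sets)
    if any(h < 0 for h in heights):
        raise ParameterError("heights must be >= 0")
    if heights != sorted(heights) or heights[0] != 0:
        raise ParameterError("heights must be ascending and start at 0")
    rows = []
    for h, table in test_sets.items():
        _, metrics = evaluate(model, table, classes=classes)
        rows.append({"height_mm": h, "accuracy": metrics["accuracy"]})
    return pd.DataFrame(rows)
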