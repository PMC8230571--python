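"""Ensemble-tree classification of feature-table rows under 10-fold CV.

Bagged trees (bootstrap-aggregated deep decision trees, majority vote) and
boosted trees (sequentially reweighted shallow trees, AdaBoost SAMME) are
evaluated with k-fold cross-validation: every row is predicted exactly once,
while held out.  Missing features are imputed with column medians computed
on the training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import current_dependent_columns

__all__ = ["ClassificationTask", "ClassificationReport", "make_folds",
           "train_eval", "run_benchmark_tasks"]


@dataclass
class ClassificationTask:
    """One classification problem on a feature table.

    features : column subset (None = the current-dependent catalogue)
    label : "genotype" or "age" (derived from the group label), or an
        explicit column name in the table
    kind : "bagged" or "boosted"
    """

    features: list[str] | None = None
    label: str = "genotype"
    kind: str = "bagged"
    n_estimators: int = 100
    max_depth: int | None = None     # bagged trees: unlimited by default
    boost_depth: int = 3
    learning_rate: float = 0.1
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.kind not in ("bagged", "boosted"):
            raise ValueError("kind must be 'bagged' or 'boosted'")


@dataclass
class ClassificationReport:
    task: ClassificationTask
    predictions: pd.DataFrame        # index as table; fold, truth, predicted
    accuracy: float
    confusion: pd.DataFrame
    classes: list[str]
    seed: int
    refolded: bool = False

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.classes)

    def summary(self) -> str:
        lines = [f"classifier : {self.task.kind} trees "
                 f"({self.task.n_estimators} estimators)",
                 f"label      : {self.task.label} "
                 f"({len(self.classes)} classes: {', '.join(self.classes)})",
                 f"folds      : {self.task.folds}, seed {self.seed}",
                 f"accuracy   : {self.accuracy:.3f} "
                 f"(chance {self.chance_level:.3f})",
                 "confusion  :", self.confusion.to_string()]
        return "\n".join(lines)


def make_folds(n_rows: int, k: int, seed: int,
               labels: np.ndarray | None = None) -> np.ndarray:
    """Random fold assignment: each row held out once, sizes differ by <= 1.

    With ``labels`` given, the assignment is stratified per class (used when
    a plain split leaves a class missing from some training fold).
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_rows, dtype=int)
    if labels is None:
        perm = rng.permutation(n_rows)
        out[perm] = np.arange(n_rows) % k
        return out
    labels = np.asarray(labels)
    counter = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        out[perm] = (np.arange(idx.size) + counter) % k
        counter += idx.size
    return out


def _labels_for(table: pd.DataFrame, label: str) -> np.ndarray:
    if label in table.columns:
        return table[label].astype(str).to_numpy()
    groups = table.index.get_level_values("group_label").astype(str)
    if label == "genotype":
        return np.array([g.split("-")[0] for g in groups])
    if label == "age":
        return np.array([g.split("-")[1] for g in groups])
    raise ValueError(f"unknown label source {label!r}")


def _estimator(task: ClassificationTask, seed: int):
    if task.kind == "bagged":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=task.max_depth,
                                             random_state=seed),
            n_estimators=task.n_estimators, max_samples=1.0, bootstrap=True,
            random_state=seed)
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=task.boost_depth,
                                         random_state=seed),
        n_estimators=task.n_estimators, learning_rate=task.learning_rate,
        random_state=seed)


def train_eval(task: ClassificationTask, table: pd.DataFrame,
               labels: np.ndarray | None = None) -> ClassificationReport:
    """Cross-validated accuracy of the requested ensemble on the table.

    Accuracy counts held-out predictions only.  If the random split leaves a
    class absent from any training fold, the split is redone stratified (and
    the report flags it).
    """
    y = labels if labels is not None else _labels_for(table, task.label)
    y = np.asarray(y).astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if task.features is not None:
        cols = task.features
    else:
        cols = [c for c in current_dependent_columns() if c in table.columns]
        if not cols:  # non-catalogue table: use every numeric column
            cols = [c for c in table.columns
                    if np.issubdtype(table[c].dtype, np.number)]
    X = table[cols].to_numpy(dtype=float)
    n = X.shape[0]
    k = min(task.folds, n)

    folds = make_folds(n, k, task.seed)
    refolded = False
    for f in range(k):
        if len(set(y[folds != f])) < len(classes):
            folds = make_folds(n, k, task.seed, labels=y)
            refolded = True
            warnings.warn("class missing from a training fold; "
                          "re-split stratified")
            break

    pred = np.empty(n, dtype=object)
    for f in range(k):
        tr, te = folds != f, folds == f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X[tr], axis=0)
        med = np.where(np.isfinite(med), med, 0.0)  # all-NaN column: impute 0
        Xtr = np.where(np.isfinite(X[tr]), X[tr], med)
        Xte = np.where(np.isfinite(X[te]), X[te], med)
        est = _estimator(task, task.seed + f)
        est.fit(Xtr, y[tr])
        pred[te] = est.predict(Xte)

    acc = float(np.mean(pred == y))
    conf = pd.crosstab(pd.Series(y, name="true"),
                       pd.Series(pred.astype(str), name="predicted"),
                       dropna=False).reindex(index=classes, columns=classes,
                                             fill_value=0)
    preds = pd.DataFrame({"fold": folds, "truth": y,
                          "predicted": pred.astype(str)}, index=table.index)
    return ClassificationReport(task=task, predictions=preds, accuracy=acc,
                                confusion=conf, classes=classes,
                                seed=task.seed, refolded=refolded)


def run_benchmark_tasks(table: pd.DataFrame, kind_per_task: dict[str, str] | None = None,
                    seed: int = 0, folds: int = 10) -> pd.DataFrame:
    """The six benchmark tasks: WT/AD per age, WT/AD pooled, age from WT,
    age from AD.  Returns one row per task with accuracy and chance level.
    """
    kinds = {"WT-AD-1m": "bagged", "WT-AD-4m": "bagged",
             "WT-AD-10m": "bagged", "WT-AD-all": "bagged",
             "age-WT": "bagged", "age-AD": "boosted"}
    if kind_per_task:
        kinds.update(kind_per_task)
    groups = table.index.get_level_values("group_label").astype(str)
    ages = [g.split("-")[1] for g in groups]
    genos = [g.split("-")[0] for g in groups]

    rows = []

    def add(name, subtable, label):
        task = ClassificationTask(label=label, kind=kinds[name],
                                  folds=folds, seed=seed)
        rep = train_eval(task, subtable)
        rows.append({"task": name, "label": label, "kind": kinds[name],
                     "n_rows": len(subtable), "n_classes": len(rep.classes),
                     "chance": rep.chance_level, "accuracy": rep.accuracy})
        return rep

    for age in ("1m", "4m", "10m"):
        mask = [a == age for a in ages]
        if any(mask):
            add(f"WT-AD-{age}", table[mask], "genotype")
    add("WT-AD-all", table, "genotype")
    for geno in ("WT", "AD"):
        mask = [g == geno for g in genos]
        if any(mask):
            add(f"age-{geno}", table[mask], "age")
    return pd.DataFrame(rows)
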