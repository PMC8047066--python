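"""Repeated stratified k-fold benchmark of six classifier families.

For each binary index the cohort's 19 features are classified with
random forest (RF), gradient boosting (GB), AdaBoost over decision
stumps (ADAB), an RBF support-vector machine (SVM), k-nearest
neighbours (KNN) and a one-hidden-layer perceptron (MLP).  Evaluation
uses stratified 10-fold cross-validation repeated over 10 seeds;
out-of-fold predictions are pooled per seed, and accuracy, sensitivity,
specificity (class 1 = symptomatic as positive) and AUCROC are reported
as mean +/- SD across seeds.  Feature relevance is ranked by mean
impurity-decrease importance of the random forests fitted across the
seeds' training folds, normalised to sum to 100 %.

Hyperparameters are fixed, documented defaults (see ``make_model``);
tree splits use the information-gain (`entropy`) criterion.  Rows with
missing features are dropped listwise before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

MODEL_NAMES = ("RF", "GB", "ADAB", "SVM", "KNN", "MLP")
DEFAULT_LABELS = ("I_PV", "I_NM", "I_MS")
METRICS = ("accuracy", "sensitivity", "specificity", "aucroc")


def make_model(name: str, seed: int, **overrides):
    """Instantiate one classifier family with the documented defaults;
    keyword overrides reach the final estimator."""
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, criterion="entropy", random_state=seed, **overrides
        )
    if name == "GB":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed, **overrides)
    if name == "ADAB":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, criterion="entropy"),
            n_estimators=100,
            random_state=seed,
            **overrides,
        )
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed, **overrides))
    if name == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5, **overrides))
    if name == "MLP":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(32,),
                early_stopping=True,
                max_iter=500,
                random_state=seed,
                **overrides,
            ),
        )
    raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous ranking scores for AUCROC: decision-function values
    where available (SVM), class-1 probability otherwise (KNN uses
    neighbour-vote fractions)."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


@dataclass
class BenchResult:
    """Repeated-CV metrics of one (index, model) pair."""

    label: str
    model: str
    per_seed: pd.DataFrame  # one row per seed, columns = METRICS
    confusion: dict[int, tuple[int, int, int, int]]  # seed -> (tn, fp, fn, tp)
    n_rows: int
    n_dropped: int

    @property
    def mean(self) -> pd.Series:
        return self.per_seed.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_seed.std(ddof=1)


def _clean_xy(cohort: pd.DataFrame, label: str, features) -> tuple[np.ndarray, np.ndarray, int]:
    X = cohort.loc[:, list(features)].to_numpy(dtype=float)
    y = cohort[label].to_numpy(dtype=int)
    ok = np.isfinite(X).all(axis=1)
    return X[ok], y[ok], int((~ok).sum())


def repeated_cv(
    cohort: pd.DataFrame,
    label: str,
    model: str,
    k: int = 10,
    seeds=range(10),
    features: tuple[str, ...] = FEATURE_NAMES,
) -> BenchResult:
    """Stratified k-fold CV of one model on one index, repeated per seed.

    Out-of-fold hard predictions and continuous scores are pooled within
    each seed before computing the four metrics (percent scale for the
    first three, [0, 1] for AUCROC).
    """
    X, y, n_dropped = _clean_xy(cohort, label, features)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"label {label!r} has a single class; cannot benchmark")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class count {counts.min()} for {label!r}"
        )
    rows, confusion = [], {}
    for seed in seeds:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        pred = np.empty_like(y)
        score = np.empty(len(y), dtype=float)
        for train, test in cv.split(X, y):
            est = make_model(model, seed)
            est.fit(X[train], y[train])
            pred[test] = est.predict(X[test])
            score[test] = _scores(est, X[test])
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        confusion[seed] = (tn, fp, fn, tp)
        rows.append(
            dict(
                accuracy=100.0 * (tp + tn) / len(y),
                sensitivity=100.0 * tp / (tp + fn),
                specificity=100.0 * tn / (tn + fp),
                aucroc=float(roc_auc_score(y, score)),
            )
        )
    per_seed = pd.DataFrame(rows, index=list(seeds))
    return BenchResult(label, model, per_seed, confusion, len(y), n_dropped)


def rf_importance(
    cohort: pd.DataFrame,
    label: str,
    k: int = 10,
    seeds=range(10),
    features: tuple[str, ...] = FEATURE_NAMES,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Random-forest impurity-decrease importances, averaged over every
    forest fitted on the training folds of every seed, normalised to
    sum to 100 and ranked descending.

    Columns: feature, importance_pct, rank.
    """
    X, y, _ = _clean_xy(cohort, label, features)
    if len(np.unique(y)) < 2:
        raise ValueError(f"label {label!r} has a single class")
    acc = np.zeros(len(features))
    n_fits = 0
    for seed in seeds:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for train, _test in cv.split(X, y):
            est = make_model("RF", seed, **(model_kwargs or {}))
            est.fit(X[train], y[train])
            acc += est.feature_importances_
            n_fits += 1
    imp = 100.0 * acc / acc.sum()
    out = pd.DataFrame({"feature": list(features), "importance_pct": imp})
    out = out.sort_values("importance_pct", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class BenchmarkReport:
    """Full benchmark: metric grid, best model per index, importances."""

    metrics: pd.DataFrame  # tidy: index, model, metric means and SDs
    best_model: dict[str, str]
    importances: dict[str, pd.DataFrame]
    results: dict[tuple[str, str], BenchResult] = field(repr=False, default_factory=dict)


def benchmark_all(
    cohort: pd.DataFrame,
    labels=DEFAULT_LABELS,
    models=MODEL_NAMES,
    k: int = 10,
    seeds=range(10),
    features: tuple[str, ...] = FEATURE_NAMES,
) -> BenchmarkReport:
    """Run every (index, model) pair plus per-index RF importances."""
    rows, results, best, importances = [], {}, {}, {}
    for label in labels:
        for model in models:
            res = repeated_cv(cohort, label, model, k=k, seeds=seeds, features=features)
            results[(label, model)] = res
            rows.append(
                {
                    "index": label,
                    "model": model,
                    **{m: res.mean[m] for m in METRICS},
                    **{f"{m}_sd": res.sd[m] for m in METRICS},
                }
            )
        sub = [r for r in rows if r["index"] == label]
        best[label] = max(sub, key=lambda r: r["aucroc"])["model"]
        importances[label] = rf_importance(cohort, label, k=k, seeds=seeds, features=features)
    return BenchmarkReport(pd.DataFrame(rows), best, importances, results)
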