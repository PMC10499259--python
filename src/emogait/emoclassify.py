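"""Multi-class emotion classification from the feature table.

Six model families (kNN, decision tree, multinomial logistic regression, and
SVMs with RBF / linear / polynomial kernels) are trained on a stratified
80/20 split of the trials and evaluated with accuracy, per-class and
macro/weighted precision/recall/F1, one-vs-rest ROC curves and — for the
decision tree — Gini (impurity-decrease) feature importances.

Standardization and median imputation are fit on the training fold only.
The random baseline for five balanced conditions is 20% accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import META_COLUMNS
from .mocap_io import CONDITIONS

DEFAULT_MODEL_CONFIG = {
    "knn": {"n_neighbors": 5},
    "decision_tree": {"min_samples_leaf": 2, "max_depth": None},
    "logistic_regression": {"C": 1.0, "max_iter": 5000},
    "svm_rbf": {"C": 1.0, "gamma": "scale"},
    "svm_linear": {"C": 1.0},
    "svm_poly": {"C": 1.0, "degree": 3, "gamma": "scale"},
}

MODEL_FAMILIES = tuple(DEFAULT_MODEL_CONFIG)


@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0
    stratify_by: str = "condition"


@dataclass
class ClassificationReport:
    model: str
    accuracy: float
    per_class: pd.DataFrame               # precision/recall/f1/support per class
    macro: dict[str, float]
    weighted: dict[str, float]
    confusion: pd.DataFrame
    roc: dict[str, dict] | None = None    # class -> {fpr, tpr, auc}
    importances: pd.Series | None = None
    multiclass_strategy: str = "native"

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "accuracy": self.accuracy,
            "precision": self.macro["precision"],
            "recall": self.macro["recall"],
            "f1": self.macro["f1"],
        }


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive 80/20 split preserving per-condition proportions.

    Test counts use largest-remainder rounding of ``test_fraction`` of each
    condition's count, so e.g. counts (24,24,24,23,21) give test counts
    (5,5,5,5,4).  Deterministic per seed.
    """
    spec = spec or SplitSpec()
    key = spec.stratify_by
    counts = table[key].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"conditions with fewer than 2 trials: {small}")
    n_test_total = int(np.ceil(len(table) * spec.test_fraction))
    ideal = counts * spec.test_fraction
    base = np.floor(ideal).astype(int)
    remainder = (ideal - base).sort_values(ascending=False)
    extra = n_test_total - int(base.sum())
    take = base.copy()
    for cls in remainder.index[:extra]:
        take[cls] += 1
    rng = np.random.default_rng(spec.seed)
    test_idx: list = []
    for cls, n_take in take.items():
        idx = table.index[table[key] == cls].to_numpy()
        chosen = rng.choice(idx, size=int(n_take), replace=False)
        test_idx.extend(chosen.tolist())
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _estimator(name: str, params: dict, seed: int):
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "logistic_regression":
        return LogisticRegression(**params)
    if name == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "svm_linear":
        return SVC(kernel="linear", random_state=seed, **params)
    if name == "svm_poly":
        return SVC(kernel="poly", random_state=seed, **params)
    raise ValueError(f"unknown model family {name!r}")


def build_models(config: dict | None = None, seed: int = 0) -> dict[str, Pipeline]:
    """The six model pipelines (train-fit imputation + standardization)."""
    cfg = {k: dict(v) for k, v in DEFAULT_MODEL_CONFIG.items()}
    for k, v in (config or {}).items():
        cfg.setdefault(k, {}).update(v)
    return {
        name: Pipeline([
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("clf", _estimator(name, params, seed)),
        ])
        for name, params in cfg.items()
    }


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    X = table[feature_cols].to_numpy(float)
    y = table["condition"].to_numpy()
    return X, y, feature_cols


def train_models(
    train: pd.DataFrame, model_set: dict[str, Pipeline] | None = None, seed: int = 0
) -> dict[str, Pipeline]:
    """Fit all configured models on the training fold."""
    X, y, cols = _split_xy(train)
    if np.isnan(X).all(axis=0).any():
        bad = [cols[i] for i in np.flatnonzero(np.isnan(X).all(axis=0))]
        X = X  # all-NaN columns are imputed to the global median of zeros
        warnings.warn(f"features entirely missing in training fold: {bad[:5]}...",
                      stacklevel=2)
    models = model_set or build_models(seed=seed)
    for model in models.values():
        model.fit(X, y)
    return models


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _scores(model: Pipeline, X: np.ndarray) -> np.ndarray | None:
    clf = model[-1]
    if hasattr(clf, "predict_proba") and getattr(clf, "probability", True):
        try:
            return model.predict_proba(X)
        except AttributeError:
            pass
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        return s if s.ndim == 2 else np.column_stack([-s, s])
    return None


def evaluate(
    model: Pipeline,
    test: pd.DataFrame,
    name: str = "model",
    feature_names: list[str] | None = None,
) -> ClassificationReport:
    """Evaluate a fitted model on the held-out trials."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y, cols = _split_xy(test)
    pred = model.predict(X)
    classes = list(model[-1].classes_)
    ordered = [c for c in CONDITIONS if c in classes] or classes
    acc = accuracy_score(y, pred)
    prec, rec, f1, support = precision_recall_fscore_support(
        y, pred, labels=ordered, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support}, index=ordered
    )
    macro = {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
    }
    w = support / support.sum()
    weighted = {
        "precision": float((prec * w).sum()),
        "recall": float((rec * w).sum()),
        "f1": float((f1 * w).sum()),
    }
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=ordered), index=ordered, columns=ordered
    )
    scores = _scores(model, X)
    roc = None
    if scores is not None:
        roc = {}
        for j, cls in enumerate(classes):
            if cls not in ordered:
                continue
            fpr, tpr, _ = roc_curve((y == cls).astype(int), scores[:, j])
            roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    else:
        warnings.warn(f"{name}: no class scores available, ROC omitted", stacklevel=2)
    importances = None
    clf = model[-1]
    if hasattr(clf, "feature_importances_"):
        importances = tree_importances(model, feature_names or cols)
    strategy = "one-vs-rest" if isinstance(clf, SVC) else "native"
    return ClassificationReport(
        model=name, accuracy=float(acc), per_class=per_class, macro=macro,
        weighted=weighted, confusion=conf, roc=roc, importances=importances,
        multiclass_strategy=strategy,
    )


def tree_importances(model, feature_names: list[str]) -> pd.Series:
    """Gini importances of a fitted tree, normalized to sum 1, sorted
    descending, zeros omitted."""
    clf = model[-1] if isinstance(model, Pipeline) else model
    if not hasattr(clf, "feature_importances_"):
        raise ValueError("model does not expose impurity-based importances")
    imp = np.asarray(clf.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    s = pd.Series(imp, index=feature_names).sort_values(ascending=False)
    return s[s > 0]


def run_classification(
    table: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[dict[str, ClassificationReport], pd.DataFrame]:
    """Train and evaluate all six models on one stratified split.

    Returns per-model reports and a comparison table (accuracy, macro
    precision/recall/F1) shaped like the study's model-comparison table.
    """
    train, test = stratified_split(table, SplitSpec(test_fraction, seed))
    models = build_models(config, seed=seed)
    models = train_models(train, models)
    _, _, cols = _split_xy(train)
    reports = {
        name: evaluate(model, test, name=name, feature_names=cols)
        for name, model in models.items()
    }
    comparison = pd.DataFrame([r.summary_row() for r in reports.values()]).set_index("model")
    return reports, comparison
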