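"""Imbalance-aware classification of match underperformance and its
evaluation.

Protocol: feature rows (one per player-match and period) are split 70/30 at
the player-match level (grouped split by default, so no match leaks periods
across the boundary; ``unit='rows'`` mimics a plain row split).  The
training side is rebalanced with SMOTE -- synthetic minority rows
interpolated between minority nearest neighbours until the classes are
equal -- and a classifier (random forest, decision tree, or the Gaussian
naive-Bayes baseline) is tuned by randomized search with cross-validation,
scored by the F1 of the underperforming class.  Evaluation reports
accuracy, AUC, per-class precision/recall/F1, confusion counts, and
per-period precision curves computed on the test rows of each 5-minute
period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.metrics import f1_score, make_scorer
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "ModelReport",
    "split_train_test",
    "smote_resample",
    "train_model",
    "evaluate",
    "run_experiment",
]

#: label convention: 1 = underperforming (positive class), 0 = performing
POSITIVE = 1


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    unit: str = "player_match"  # 'player_match' (grouped) or 'rows'
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "random_forest"  # | 'decision_tree' | 'naive_bayes'
    n_search_iterations: int = 30
    cv_folds: int = 5
    seed: int = 0
    #: optional override of the hyperparameter search space
    search_space: dict | None = None

    def space(self) -> dict:
        if self.algorithm == "naive_bayes":
            return {}  # baseline model, nothing to tune
        if self.search_space is not None:
            return self.search_space
        if self.algorithm == "random_forest":
            return {
                "n_estimators": list(range(100, 501, 50)),
                "max_depth": [3, 5, 8, 12, 16, 20, None],
                "min_samples_split": list(range(2, 21)),
                "max_features": ["sqrt", "log2", None],
            }
        if self.algorithm == "decision_tree":
            return {
                "max_depth": [3, 5, 8, 12, 16, 20, None],
                "min_samples_split": list(range(2, 21)),
                "criterion": ["gini", "entropy"],
            }
        return {}


@dataclass
class ModelReport:
    algorithm: str
    variable_set: str
    threshold: float
    accuracy: float
    auc: float
    precision: dict[str, float]  # class name -> value
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: list[list[int]]  # [[tn, fp], [fn, tp]]
    per_period_precision: dict[str, dict[int, float]]  # class -> period -> precision
    best_params: dict = field(default_factory=dict)
    n_test: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def split_train_test(rows: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """70/30 split; grouped by player-match unless ``spec.unit == 'rows'``."""
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "rows":
        n = len(rows)
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        return rows.iloc[perm[:n_train]], rows.iloc[perm[n_train:]]
    groups = rows[["match_id", "player_id"]].apply(tuple, axis=1)
    uniq = pd.unique(groups)
    if len(uniq) < 10:
        raise ValueError("need at least 10 player-matches for a meaningful split")
    perm = rng.permutation(len(uniq))
    n_train = int(round(spec.train_fraction * len(uniq)))
    train_groups = set(uniq[perm[:n_train]])
    mask = groups.isin(train_groups).to_numpy()
    return rows[mask], rows[~mask]


def smote_resample(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance the classes by SMOTE interpolation on the minority class.

    Each synthetic sample lies on the segment between a random minority
    sample and one of its k nearest minority neighbours.  Raises on
    single-class input; reduces k with a warning when the minority class is
    too small.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires both classes in the training data")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = n_maj - n_min
    if n_new == 0:
        return X, y
    if n_min <= k_neighbors:
        warnings.warn(
            f"minority class has {n_min} samples <= k_neighbors={k_neighbors}; reducing k",
            stacklevel=2,
        )
        k_neighbors = max(n_min - 1, 1)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, nbr = nn.kneighbors(Xm)  # first neighbour is the point itself
    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, len(Xm), size=n_new)
    nbr_pick = nbr[base_idx, rng.integers(1, k_neighbors + 1, size=n_new)]
    lam = rng.random(size=(n_new, 1))
    X_new = Xm[base_idx] + lam * (Xm[nbr_pick] - Xm[base_idx])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=int)]),
    )


def _estimator(spec: ModelSpec, params: dict):
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "naive_bayes":
        return GaussianNB(**params)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def train_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec):
    """Randomized hyperparameter search with CV, then refit on all rows.

    Scored by cross-validated F1 of the underperforming class; returns the
    fitted estimator with the search trace attached as ``search_trace_``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    scorer = make_scorer(f1_score, pos_label=POSITIVE, zero_division=0)
    space = spec.space()
    if space:
        sampler = list(
            ParameterSampler(space, n_iter=spec.n_search_iterations, random_state=spec.seed)
        )
    else:
        sampler = [{}]
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    trace = []
    for params in sampler:
        est = _estimator(spec, params)
        scores = cross_val_score(est, X, y, scoring=scorer, cv=cv, n_jobs=1)
        trace.append({"params": params, "mean_f1": float(np.mean(scores))})
    best = max(trace, key=lambda r: r["mean_f1"])
    model = _estimator(spec, best["params"]).fit(X, y)
    model.search_trace_ = trace
    model.best_params_ = best["params"]
    return model


def _per_class(values, labels=(0, 1)) -> dict[str, float]:
    names = {0: "performing", 1: "underperforming"}
    return {names[lbl]: float(v) for lbl, v in zip(labels, values)}


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    periods: np.ndarray,
    *,
    algorithm: str = "",
    variable_set: str = "",
    threshold: float = np.nan,
) -> ModelReport:
    """Overall metrics plus per-period precision curves on the test rows.

    Per-period precision for a class is computed on the subset of test rows
    belonging to that period; periods with no test rows (or no predictions
    of the class) are omitted from the curve.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test).astype(int)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X_test)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X_test)[:, list(model.classes_).index(POSITIVE)]
    else:  # pragma: no cover
        score = y_pred
    auc = roc_auc_score(y_test, score) if len(np.unique(y_test)) > 1 else np.nan
    prec, rec, f1v, _ = precision_recall_fscore_support(
        y_test, y_pred, labels=[0, 1], zero_division=0
    )
    cm = confusion_matrix(y_test, y_pred, labels=[0, 1])

    curves: dict[str, dict[int, float]] = {"performing": {}, "underperforming": {}}
    for p in np.unique(periods):
        m = periods == p
        for cls, name in ((0, "performing"), (1, "underperforming")):
            pred_cls = y_pred[m] == cls
            if pred_cls.sum() == 0:
                continue
            curves[name][int(p)] = float(np.mean(y_test[m][pred_cls] == cls))

    return ModelReport(
        algorithm=algorithm,
        variable_set=variable_set,
        threshold=threshold,
        accuracy=float(accuracy_score(y_test, y_pred)),
        auc=float(auc),
        precision=_per_class(prec),
        recall=_per_class(rec),
        f1=_per_class(f1v),
        confusion=cm.tolist(),
        per_period_precision=curves,
        best_params=getattr(model, "best_params_", {}),
        n_test=int(len(y_test)),
    )


def _matrix(features: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = ["period"] + [c for c in features.columns if c.startswith("pct_")]
    return features[cols].to_numpy(float), cols


def run_experiment(
    features_by_set: dict[str, pd.DataFrame],
    labels_by_set: dict[str, pd.DataFrame],
    thresholds=(1.00, 0.95, 0.90),
    algorithms=("random_forest", "decision_tree", "naive_bayes"),
    split: SplitSpec | None = None,
    model_kwargs: dict | None = None,
    seed: int = 0,
) -> list[ModelReport]:
    """Full factorial run: algorithm x threshold x variable set.

    ``features_by_set`` / ``labels_by_set`` map variable-set names to the
    outputs of :func:`matchload.features_labels.build_features` and
    :func:`~matchload.features_labels.label_performance`.
    """
    split = split or SplitSpec(seed=seed)
    model_kwargs = model_kwargs or {}
    reports = []
    for vset, feats in features_by_set.items():
        labels = labels_by_set[vset]
        for thr in thresholds:
            col = f"underperf_{int(round(thr * 100))}"
            rows = feats.merge(
                labels[["match_id", "player_id", col]], on=["match_id", "player_id"]
            )
            rows = rows.rename(columns={col: "label"})
            train, test = split_train_test(rows, split)
            X_tr, _ = _matrix(train)
            X_te, _ = _matrix(test)
            y_tr = train["label"].to_numpy(int)
            y_te = test["label"].to_numpy(int)
            if len(np.unique(y_tr)) > 1:
                X_tr, y_tr = smote_resample(X_tr, y_tr, seed=seed)
            for algo in algorithms:
                spec = ModelSpec(algorithm=algo, seed=seed, **model_kwargs)
                model = train_model(X_tr, y_tr, spec)
                reports.append(
                    evaluate(
                        model,
                        X_te,
                        y_te,
                        test["period"].to_numpy(int),
                        algorithm=algo,
                        variable_set=vset,
                        threshold=thr,
                    )
                )
    return reports


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Flatten reports into a threshold x algorithm x class x metric table."""
    rows = []
    for r in reports:
        for cls in ("underperforming", "performing"):
            rows.append(
                {
                    "variable_set": r.variable_set,
                    "threshold": r.threshold,
                    "algorithm": r.algorithm,
                    "class": cls,
                    "accuracy": r.accuracy,
                    "auc": r.auc,
                    "precision": r.precision[cls],
                    "recall": r.recall[cls],
                    "f1": r.f1[cls],
                }
            )
    return pd.DataFrame(rows)


def save_reports(reports: list[ModelReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, default=float)
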