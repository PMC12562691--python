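"""Cross-validated training of the classifier suite with imbalance handling.

Classifier internals are delegated to established libraries (scikit-learn,
XGBoost, LightGBM; CatBoost when installed); this module owns everything
around them: the stratified fold plan, fold-wise standardization and MI
selection (leakage-safe default, with a ``paper_compat`` mode that fits
both globally once), the imbalance strategies (balanced class weights,
SMOTE for KNN, inverse-class-frequency sample weights for XGBoost), the
feature-free null model, and the aggregation of per-fold metrics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import evaluate as ev
from . import mi
from .features import FeatureMatrix, apply_standardization, standardize


class ModelUnavailableError(RuntimeError):
    """Raised when a wrapped classifier's library is not installed."""


@dataclass
class ModelSpec:
    """One classifier configuration.

    ``imbalance_strategy`` is one of ``class_weight_balanced``, ``smote``,
    ``inverse_freq_sample_weight``, ``auto_balanced``, ``none``.
    """

    name: str
    imbalance_strategy: str = "none"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def default_model_specs(seed: int = 0,
                        models: list[str] | None = None) -> list[ModelSpec]:
    """The seven classifiers plus the null model, with their default
    imbalance strategies."""
    registry = {
        "svm": ModelSpec("SVM", "class_weight_balanced", seed=seed),
        "knn": ModelSpec("KNN", "smote", {"n_neighbors": 5}, seed=seed),
        "dt": ModelSpec("DT", "class_weight_balanced", seed=seed),
        "rf": ModelSpec("RF", "class_weight_balanced", seed=seed),
        "lightgbm": ModelSpec("LightGBM", "class_weight_balanced", seed=seed),
        "catboost": ModelSpec("CatBoost", "auto_balanced", seed=seed),
        "xgboost": ModelSpec("XGBoost", "inverse_freq_sample_weight", seed=seed),
        "null": ModelSpec("Null", "none", seed=seed),
    }
    if models is None:
        models = list(registry)
    return [registry[m.lower()] for m in models]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    name = spec.name.lower()
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", class_weight="balanced", probability=True,
                   random_state=spec.seed, **hp)
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(class_weight="balanced",
                                      random_state=spec.seed, **hp)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(class_weight="balanced",
                                      random_state=spec.seed, n_jobs=1, **hp)
    if name == "lightgbm":
        try:
            from lightgbm import LGBMClassifier
        except ImportError as err:  # pragma: no cover
            raise ModelUnavailableError("LightGBM is not installed") from err
        return LGBMClassifier(class_weight="balanced", random_state=spec.seed,
                              verbose=-1, n_jobs=1, **hp)
    if name == "catboost":
        try:
            from catboost import CatBoostClassifier
        except ImportError as err:
            raise ModelUnavailableError("CatBoost is not installed") from err
        return CatBoostClassifier(auto_class_weights="Balanced",
                                  random_seed=spec.seed, verbose=0, **hp)
    if name == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as err:  # pragma: no cover
            raise ModelUnavailableError("XGBoost is not installed") from err
        return XGBClassifier(objective="multi:softprob", random_state=spec.seed,
                             eval_metric="mlogloss", n_jobs=1,
                             tree_method="hist", **hp)
    raise ValueError(f"unknown model {spec.name!r}")


# ---------------------------------------------------------------------------
# Imbalance handling
# ---------------------------------------------------------------------------

def balanced_class_weights(labels) -> dict:
    """``n_total / (n_classes * n_c)`` per class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    classes, counts = np.unique(labels, return_counts=True)
    total = labels.size
    return {c: float(total / (classes.size * n)) for c, n in zip(classes, counts)}


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Upsample every class to the majority count by same-class
    nearest-neighbour interpolation ``x_i + u * (x_nn - x_i)``, u in [0, 1).
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        if cnt >= majority:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has a single member; use a smaller k or exclude it")
        rows = X[y == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(rows)
        _, idx = nn.kneighbors(rows)  # column 0 is the point itself
        n_new = majority - cnt
        base = rng.integers(0, cnt, n_new)
        pick = rng.integers(1, k + 1, n_new)
        u = rng.uniform(0.0, 1.0, n_new)[:, None]
        neighbors = rows[idx[base, pick]]
        synthetic = rows[base] + u * (neighbors - rows[base])
        new_X.append(synthetic)
        new_y.append(np.full(n_new, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# Fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Stratified assignment of each segment to exactly one test fold."""

    assignments: np.ndarray
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_fold_plan(labels, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise ValueError(
                f"class {cls!r} has {cnt} segments, fewer than n_folds={n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignments[test_idx] = fold
    return FoldPlan(assignments=assignments, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def null_model_predict(labels_train, n_test: int, n_classes: int,
                       seed: int = 0) -> np.ndarray:
    """Seeded uniform-random class probabilities (flat Dirichlet) per test row."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n_classes), size=n_test)


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    name: str
    fold_metrics: list[dict]
    mean: dict
    sd: dict
    pooled_confusion: ev.ConfusionMatrix
    pooled_metrics: dict
    pooled_probs: np.ndarray
    pooled_true: np.ndarray
    fold_selected: list[list[str]]
    train_seconds: float


@dataclass
class CVReport:
    class_order: tuple[str, ...]
    results: dict[str, ModelResult]
    unavailable: dict[str, str]
    selection_k: int
    cv_mode: str


def _fold_selection(fm: FeatureMatrix, train_idx: np.ndarray, selection_k: int,
                    k_neighbors: int, seed: int):
    """Standardizer + MI selection fitted on the training rows only."""
    train_fm = FeatureMatrix(values=fm.values[train_idx], names=list(fm.names),
                             labels=fm.labels[train_idx],
                             group_ids=fm.group_ids[train_idx],
                             start_times=fm.start_times[train_idx])
    std_train, means, sds, const = standardize(train_fm)
    scores = mi.score_all(std_train, k_neighbors=k_neighbors, seed=seed)
    selection = mi.select_top_k(scores, k=selection_k)
    return selection, (means, sds, const)


def fold_feature_selections(fm: FeatureMatrix, plan: FoldPlan,
                            selection_k: int = 30, k_neighbors: int = 3,
                            seed: int = 0) -> list[list[str]]:
    """Per-fold selected feature names under the leakage-safe default."""
    out = []
    for fold in range(plan.n_folds):
        sel, _ = _fold_selection(fm, plan.train_indices(fold), selection_k,
                                 k_neighbors, seed)
        out.append(sel.selected_names)
    return out


def run_cv(fm: FeatureMatrix, specs: list[ModelSpec], plan: FoldPlan,
           selection_k: int = 30, cv_mode: str = "fold_wise",
           mi_k_neighbors: int = 3, smote_k_neighbors: int = 5) -> CVReport:
    """Train every spec under the fold plan and aggregate the metrics.

    ``cv_mode='fold_wise'`` (default) fits standardization and MI
    selection inside each training fold; ``'paper_compat'`` fits both once
    on all segments before cross-validation.
    """
    if cv_mode not in {"fold_wise", "paper_compat"}:
        raise ValueError(f"unknown cv_mode {cv_mode!r}")
    labels = np.asarray(fm.labels)
    class_order = tuple(sorted(np.unique(labels)))
    cls_index = {c: i for i, c in enumerate(class_order)}
    y_all = np.array([cls_index[c] for c in labels])

    global_ctx = None
    if cv_mode == "paper_compat":
        std_all, means, sds, const = standardize(fm)
        scores = mi.score_all(std_all, k_neighbors=mi_k_neighbors, seed=0)
        global_ctx = (mi.select_top_k(scores, k=selection_k), (means, sds, const))

    results: dict[str, ModelResult] = {}
    unavailable: dict[str, str] = {}
    for spec in specs:
        if spec.name.lower() != "null":
            try:
                _build_estimator(spec)
            except ModelUnavailableError as err:
                unavailable[spec.name] = str(err)
                continue
        t0 = time.perf_counter()
        fold_metrics: list[dict] = []
        fold_selected: list[list[str]] = []
        pooled_true, pooled_pred = [], []
        pooled_probs = []
        for fold in range(plan.n_folds):
            train_idx = plan.train_indices(fold)
            test_idx = plan.test_indices(fold)
            y_train, y_test = y_all[train_idx], y_all[test_idx]

            if spec.name.lower() == "null":
                probs = null_model_predict(labels[train_idx], test_idx.size,
                                           len(class_order),
                                           seed=spec.seed * 1000 + fold)
                selected_names: list[str] = []
            else:
                if cv_mode == "fold_wise":
                    selection, std_params = _fold_selection(
                        fm, train_idx, selection_k, mi_k_neighbors, spec.seed)
                else:
                    selection, std_params = global_ctx
                selected_names = selection.selected_names
                std_fm = apply_standardization(fm, *std_params)
                cols = [fm.names.index(n) for n in selected_names]
                X_train = std_fm.values[np.ix_(train_idx, cols)]
                X_test = std_fm.values[np.ix_(test_idx, cols)]

                fit_X, fit_y = X_train, y_train
                sample_weight = None
                if spec.imbalance_strategy == "smote":
                    fit_X, fit_y = smote_oversample(
                        X_train, y_train, k_neighbors=smote_k_neighbors,
                        seed=spec.seed * 1000 + fold)
                elif spec.imbalance_strategy == "inverse_freq_sample_weight":
                    weights = balanced_class_weights(y_train)
                    sample_weight = np.array([weights[c] for c in y_train])

                est = _build_estimator(spec)
                if sample_weight is not None:
                    est.fit(fit_X, fit_y, sample_weight=sample_weight)
                else:
                    est.fit(fit_X, fit_y)
                raw = est.predict_proba(X_test)
                probs = np.zeros((test_idx.size, len(class_order)))
                for col, cls in enumerate(est.classes_):
                    probs[:, int(cls)] = raw[:, col]
                # guard against estimators that omit an absent class
                probs /= probs.sum(axis=1, keepdims=True)

            preds = probs.argmax(axis=1)
            true_names = labels[test_idx]
            pred_names = np.array([class_order[p] for p in preds], dtype=object)
            fold_metrics.append(ev.metrics_from_predictions(
                true_names, pred_names, probs, class_order))
            fold_selected.append(selected_names)
            pooled_true.append(true_names)
            pooled_pred.append(pred_names)
            pooled_probs.append(probs)

        pooled_true = np.concatenate(pooled_true)
        pooled_pred = np.concatenate(pooled_pred)
        pooled_probs = np.vstack(pooled_probs)
        keys = fold_metrics[0].keys()
        mean = {k: float(np.mean([m[k] for m in fold_metrics])) for k in keys}
        sd = {k: float(np.std([m[k] for m in fold_metrics])) for k in keys}
        results[spec.name] = ModelResult(
            name=spec.name,
            fold_metrics=fold_metrics,
            mean=mean,
            sd=sd,
            pooled_confusion=ev.confusion(pooled_true, pooled_pred, class_order),
            pooled_metrics=ev.metrics_from_predictions(
                pooled_true, pooled_pred, pooled_probs, class_order),
            pooled_probs=pooled_probs,
            pooled_true=pooled_true,
            fold_selected=fold_selected,
            train_seconds=time.perf_counter() - t0,
        )
    return CVReport(class_order=class_order, results=results,
                    unavailable=unavailable, selection_k=selection_k,
                    cv_mode=cv_mode)
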