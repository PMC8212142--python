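"""Evaluation protocol: stratified resplitting, leakage-free scaling and
PCA, metrics, paired statistics, training-fraction sweeps and feature
importance.

All transforms (z-scoring, PCA) are fitted on the training split only and
applied to the corresponding test split, so no test-set statistic ever
enters a fitted transform.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

from .datasets import LabeledDataset
from .model import SolverSpec, TrainedIsingModel, fit as fit_ising, predict, predict_proba
from .rbm import rbm_predict, rbm_predict_proba, rbm_train

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "make_splits",
    "zscore_fit_apply",
    "pca_fit_project",
    "subsample_training",
    "compute_metrics",
    "compare_classifiers",
    "overfitting_gap",
    "feature_importance",
    "select_top_loading_features",
    "IsingClassifier",
    "RBMClassifier",
    "baseline_classifier",
    "evaluate_classifiers",
    "training_fraction_sweep",
]

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "balanced_accuracy", "auc", "f1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitPlan:
    """Stratified train/test index lists for repeated splits."""

    n_splits: int
    train_fraction: float
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    seed: int


def make_splits(
    labels: np.ndarray,
    n_splits: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Class-stratified random splits without replacement.

    Per class the train count is round-half-up(train_fraction * class
    size), clamped so both sides keep at least one member.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    rng = np.random.default_rng(seed)
    train_lists, test_lists = [], []
    for _ in range(n_splits):
        train_parts, test_parts = [], []
        for cls, size in zip(classes, counts):
            idx = np.flatnonzero(labels == cls)
            n_train = min(max(_round_half_up(train_fraction * size), 1), size - 1)
            perm = rng.permutation(idx)
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        train_lists.append(np.sort(np.concatenate(train_parts)))
        test_lists.append(np.sort(np.concatenate(test_parts)))
    return SplitPlan(n_splits, train_fraction, train_lists, test_lists, seed)


def zscore_fit_apply(
    train_x: np.ndarray, test_x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scoring fitted on train (ddof=1), applied to both splits.

    Constant training columns are mapped to zero in train and test alike.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    means = train_x.mean(axis=0)
    sds = train_x.std(axis=0, ddof=1) if train_x.shape[0] > 1 else np.zeros(train_x.shape[1])
    safe = np.where(sds == 0, 1.0, sds)
    train_z = (train_x - means) / safe
    test_z = (test_x - means) / safe
    zero_cols = sds == 0
    train_z[:, zero_cols] = 0.0
    test_z[:, zero_cols] = 0.0
    return train_z, test_z, means, sds


def pca_fit_project(
    train_z: np.ndarray, test_z: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PCA fitted on the training matrix; test rows projected with the
    training loadings.

    Components are ordered by decreasing variance; each loading column is
    sign-fixed so its largest-magnitude entry is positive.  Returns
    (train_PCs, test_PCs, loadings (M x n_components), explained_variance).
    """
    train_z = np.asarray(train_z, dtype=float)
    test_z = np.asarray(test_z, dtype=float)
    n, m = train_z.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(N_train, M)={min(n, m)}"
        )
    center = train_z.mean(axis=0)
    xc = train_z - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[:n_components].T  # (M, n_components)
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip = np.where(flip == 0, 1.0, flip)
    loadings = loadings * flip
    explained = (s[:n_components] ** 2) / max(n - 1, 1)
    train_pcs = xc @ loadings
    test_pcs = (test_z - center) @ loadings
    return train_pcs, test_pcs, loadings, explained


def subsample_training(
    train_indices: np.ndarray,
    labels: np.ndarray,
    fraction: float,
    n_replicates: int = 50,
    seed: int = 0,
) -> list[np.ndarray]:
    """Stratified sub-partitions of a fixed training set; test untouched."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    train_indices = np.asarray(train_indices, dtype=int)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    sub_labels = labels[train_indices]
    classes = np.unique(sub_labels)
    out = []
    for _ in range(n_replicates):
        parts = []
        for cls in classes:
            idx = train_indices[sub_labels == cls]
            n_take = _round_half_up(fraction * len(idx))
            if n_take < 1:
                raise ValueError(
                    f"fraction {fraction} empties class {cls} "
                    f"(class size {len(idx)})"
                )
            parts.append(rng.permutation(idx)[:n_take])
        out.append(np.sort(np.concatenate(parts)))
    return out


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_proba: np.ndarray, n_classes: int
) -> dict[str, float]:
    """Accuracy, balanced accuracy, AUC and F1 for labels in 1..K.

    Balanced accuracy averages per-class recall over classes present in
    ``y_true`` (absent classes are excluded with a warning).  For K=2 the
    AUC and F1 treat class 2 (the second listed) as positive; for K>2
    both are macro-averaged one-vs-rest.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_proba = np.atleast_2d(np.asarray(y_proba, dtype=float))
    accuracy = float(np.mean(y_true == y_pred))

    recalls = []
    for cls in range(1, n_classes + 1):
        mask = y_true == cls
        if not mask.any():
            warnings.warn(f"class {cls} absent from y_true; recall excluded")
            continue
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    balanced = float(np.mean(recalls))

    if n_classes == 2:
        auc = _safe_binary_auc(y_true == 2, y_proba[:, 1])
        f1 = float(f1_score(y_true, y_pred, pos_label=2, zero_division=0))
    else:
        aucs = []
        for cls in range(1, n_classes + 1):
            pos = y_true == cls
            if pos.all() or not pos.any():
                continue
            aucs.append(_safe_binary_auc(pos, y_proba[:, cls - 1]))
        auc = float(np.mean(aucs)) if aucs else float("nan")
        f1 = float(
            f1_score(y_true, y_pred, average="macro",
                     labels=list(range(1, n_classes + 1)), zero_division=0)
        )
    return {"accuracy": accuracy, "balanced_accuracy": balanced, "auc": auc, "f1": f1}


def _safe_binary_auc(pos: np.ndarray, score: np.ndarray) -> float:
    if pos.all() or not pos.any():
        return float("nan")
    return float(roc_auc_score(pos, score))


@dataclass
class EvaluationReport:
    """Tidy per-(classifier, split, phase, metric) table plus extras."""

    records: pd.DataFrame  # columns: classifier, split, phase, metric, value
    models: dict[str, list] = field(default_factory=dict)
    n_splits: int = 0

    def summary(self, phase: str = "test") -> pd.DataFrame:
        sub = self.records[self.records["phase"] == phase]
        grouped = sub.groupby(["classifier", "metric"])["value"]
        out = grouped.agg(["mean", "std", "count"]).reset_index()
        out["sem"] = out["std"] / np.sqrt(out["count"])
        return out[["classifier", "metric", "mean", "sem", "count"]]

    def metric_matrix(self, metric: str, phase: str = "test") -> pd.DataFrame:
        sub = self.records[
            (self.records["metric"] == metric) & (self.records["phase"] == phase)
        ]
        return sub.pivot(index="split", columns="classifier", values="value")


def compare_classifiers(
    report: EvaluationReport, metric: str = "balanced_accuracy", phase: str = "test"
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests, Bonferroni-corrected.

    The correction family is all classifier pairs within the metric;
    identical paired values give p = 1.
    """
    mat = report.metric_matrix(metric, phase)
    names = list(mat.columns)
    if len(names) < 2:
        raise ValueError("need at least two classifiers to compare")
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        x, y = mat[a].to_numpy(), mat[b].to_numpy()
        if np.allclose(x, y):
            p = 1.0
        else:
            p = float(stats.wilcoxon(x, y).pvalue)
        rows.append(
            {
                "classifier_a": a,
                "classifier_b": b,
                "metric": metric,
                "mean_a": float(np.mean(x)),
                "mean_b": float(np.mean(y)),
                "p_raw": p,
                "p_bonferroni": min(p * len(pairs), 1.0),
            }
        )
    return pd.DataFrame(rows)


def overfitting_gap(report: EvaluationReport, metric: str = "balanced_accuracy") -> pd.DataFrame:
    """Per-classifier train minus test metric, mean +/- SEM over splits."""
    train = report.metric_matrix(metric, "train")
    test = report.metric_matrix(metric, "test")
    gaps = train - test
    rows = []
    for name in gaps.columns:
        g = gaps[name].to_numpy()
        rows.append(
            {
                "classifier": name,
                "metric": metric,
                "gap_mean": float(np.mean(g)),
                "gap_sem": float(np.std(g, ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def feature_importance(models: list[TrainedIsingModel]) -> pd.DataFrame:
    """Mean |averaged weight| per feature across splits and class blocks.

    Only Ising-family models carry weights; RBMs are excluded by
    construction.  Ties are broken by feature index.
    """
    if not models:
        raise ValueError("need at least one trained Ising model")
    stacked = np.stack([np.abs(m.weights).mean(axis=0) for m in models])
    importance = stacked.mean(axis=0)
    order = np.lexsort((np.arange(len(importance)), -importance))
    ranks = np.empty(len(importance), dtype=int)
    ranks[order] = np.arange(1, len(importance) + 1)
    return pd.DataFrame(
        {
            "feature": np.arange(len(importance)),
            "importance": importance,
            "rank": ranks,
        }
    ).sort_values("rank").reset_index(drop=True)


def select_top_loading_features(
    loadings: np.ndarray, component: int = 1, k: int = 44
) -> np.ndarray:
    """Indices of the k largest-|loading| features on one component.

    ``component`` is 1-based; ordering is descending |loading| with ties
    broken by feature index.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    col = np.abs(loadings[:, component - 1])
    if k > col.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {col.shape[0]}")
    order = np.lexsort((np.arange(col.shape[0]), -col))
    return order[:k]


# ---------------------------------------------------------------------------
# Classifier adapters


class IsingClassifier:
    """Adapter running encode -> solve -> postprocess through `model.fit`."""

    def __init__(self, spec: SolverSpec | None = None, cv_folds: int = 10):
        self.spec = spec or SolverSpec()
        self.cv_folds = cv_folds
        self.name = self.spec.name
        self.model: TrainedIsingModel | None = None

    def fit(self, dataset: LabeledDataset, seed: int = 0) -> "IsingClassifier":
        self.model = fit_ising(dataset, self.spec, cv_folds=self.cv_folds, seed=seed)
        return self

    def predict(self, x_mat: np.ndarray) -> np.ndarray:
        return predict(self.model.weights, x_mat)

    def predict_proba(self, x_mat: np.ndarray) -> np.ndarray:
        return predict_proba(self.model.weights, x_mat)


class RBMClassifier:
    """Adapter around the classification RBM."""

    def __init__(self, **hyperparams):
        self.hyperparams = hyperparams
        self.name = "rbm"
        self.model = None

    def fit(self, dataset: LabeledDataset, seed: int = 0) -> "RBMClassifier":
        self.model = rbm_train(dataset, seed=seed, **self.hyperparams)
        return self

    def predict(self, x_mat: np.ndarray) -> np.ndarray:
        return rbm_predict(self.model, x_mat)

    def predict_proba(self, x_mat: np.ndarray) -> np.ndarray:
        return np.atleast_2d(rbm_predict_proba(self.model, x_mat))


class _SklearnAdapter:
    def __init__(self, name: str, estimator_factory):
        self.name = name
        self._factory = estimator_factory
        self.estimator = None

    def fit(self, dataset: LabeledDataset, seed: int = 0):
        est = self._factory(seed)
        est.fit(dataset.features, dataset.labels)
        self.estimator = est
        return self

    def predict(self, x_mat: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(x_mat), dtype=int)

    def predict_proba(self, x_mat: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(x_mat)
        # align columns to 1..K order
        order = np.argsort(self.estimator.classes_)
        return np.asarray(proba)[:, order]


def baseline_classifier(name: str):
    """Thin adapter over established library baselines (not re-implemented)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    factories = {
        "logistic": lambda seed: LogisticRegression(
            C=np.inf, max_iter=2000, random_state=seed % 2**32
        ),
        "lasso": lambda seed: LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=2000, random_state=seed % 2**32
        ),
        "ridge": lambda seed: LogisticRegression(
            l1_ratio=0.0, max_iter=2000, random_state=seed % 2**32
        ),
        "rf": lambda seed: RandomForestClassifier(
            n_estimators=200, random_state=seed % 2**32
        ),
        "nb": lambda seed: GaussianNB(),
        "svm": lambda seed: SVC(probability=True, random_state=seed % 2**32),
    }
    if name not in factories:
        raise ValueError(f"unknown baseline {name!r}")
    return _SklearnAdapter(name, factories[name])


# ---------------------------------------------------------------------------
# Protocol drivers


def _clone_classifier(clf):
    if isinstance(clf, IsingClassifier):
        return IsingClassifier(clf.spec, clf.cv_folds)
    if isinstance(clf, RBMClassifier):
        return RBMClassifier(**clf.hyperparams)
    if isinstance(clf, _SklearnAdapter):
        return _SklearnAdapter(clf.name, clf._factory)
    raise TypeError(f"cannot clone {type(clf)!r}")


def _eval_on_split(
    dataset: LabeledDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    classifiers: list,
    n_pcs: int | None,
    seed: int,
    split_id: int,
    records: list,
    fitted_out: dict | None = None,
) -> None:
    x_train, x_test = dataset.features[train_idx], dataset.features[test_idx]
    y_train, y_test = dataset.labels[train_idx], dataset.labels[test_idx]
    train_z, test_z, _, _ = zscore_fit_apply(x_train, x_test)
    if n_pcs is not None:
        train_f, test_f, _, _ = pca_fit_project(train_z, test_z, n_pcs)
    else:
        train_f, test_f = train_z, test_z
    train_ds = LabeledDataset(
        features=train_f, labels=y_train, n_classes=dataset.n_classes,
        class_names=list(dataset.class_names),
    )
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(split_id,))
    clf_seeds = ss.generate_state(len(classifiers))
    for clf_proto, clf_seed in zip(classifiers, clf_seeds):
        clf = _clone_classifier(clf_proto)
        clf.fit(train_ds, seed=int(clf_seed))
        for phase, xf, yf in (("train", train_f, y_train), ("test", test_f, y_test)):
            mets = compute_metrics(
                yf, clf.predict(xf), clf.predict_proba(xf), dataset.n_classes
            )
            for metric, value in mets.items():
                records.append(
                    {
                        "classifier": clf.name,
                        "split": split_id,
                        "phase": phase,
                        "metric": metric,
                        "value": value,
                    }
                )
        if fitted_out is not None and isinstance(clf, IsingClassifier):
            fitted_out.setdefault(clf.name, []).append(clf.model)


def evaluate_classifiers(
    dataset: LabeledDataset,
    classifiers: list,
    plan: SplitPlan,
    n_pcs: int | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full leakage-free protocol over every split of ``plan``."""
    records: list[dict] = []
    models: dict[str, list] = {}
    for split_id, (tr, te) in enumerate(zip(plan.train_indices, plan.test_indices)):
        _eval_on_split(
            dataset, tr, te, classifiers, n_pcs, seed, split_id, records, models
        )
    return EvaluationReport(
        records=pd.DataFrame(records), models=models, n_splits=plan.n_splits
    )


def training_fraction_sweep(
    dataset: LabeledDataset,
    classifiers: list,
    fractions: list[float],
    n_replicates: int = 50,
    train_fraction: float = 0.8,
    n_pcs: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Shrinking-training-set protocol against one fixed held-out test set.

    A single stratified split fixes the test set; for each fraction,
    ``n_replicates`` stratified subsamples of the training set are drawn,
    each classifier refitted, and train/test metrics recorded.
    """
    base = make_splits(dataset.labels, n_splits=1, train_fraction=train_fraction, seed=seed)
    full_train, fixed_test = base.train_indices[0], base.test_indices[0]
    records: list[dict] = []
    for frac_id, fraction in enumerate(fractions):
        reps = subsample_training(
            full_train, dataset.labels, fraction,
            n_replicates=n_replicates, seed=seed + 7919 * (frac_id + 1),
        )
        for rep_id, sub_idx in enumerate(reps):
            rows: list[dict] = []
            _eval_on_split(
                dataset, sub_idx, fixed_test, classifiers, n_pcs,
                seed=seed + 104729 * (frac_id + 1), split_id=rep_id, records=rows,
            )
            for row in rows:
                row["fraction"] = fraction
            records.extend(rows)
    return pd.DataFrame(records)
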