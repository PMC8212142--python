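"""Classifier built from low-energy spin ensembles.

The K-1 weight vectors live in [-1, 1]^M: raw solver output is +/-1, and
the postprocessing step averages the lowest-energy configurations whenever
doing so improves the exact training negative log likelihood (the Taylor
approximation is only used for the search; model selection and averaging
use the true objective).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .encoder import encode, scale_to_unit, spins_to_weights
from .solvers import (
    BETA_FINAL_GRID,
    AnnealSchedule,
    SolverResult,
    solve_field,
    solve_random,
    solve_sa,
)

__all__ = [
    "SolverSpec",
    "TrainedIsingModel",
    "class_probabilities",
    "negative_log_likelihood",
    "postprocess_average",
    "predict",
    "fit",
    "model_to_json",
    "model_from_json",
]

logger = logging.getLogger(__name__)


@dataclass
class SolverSpec:
    """Which solver to run and with what budget.

    ``beta_final=None`` for the SA solver means "tune over ``beta_grid``
    by cross-validation"; Field and Random have no hyperparameters.
    """

    name: str = "sa"
    n_reads: int = 1000
    n_sweeps: int = 1000
    beta_initial: float = 0.01
    beta_final: float | None = None
    beta_grid: tuple[float, ...] = BETA_FINAL_GRID
    n_keep: int = 20

    def __post_init__(self) -> None:
        if self.name not in ("sa", "random", "field"):
            raise ValueError(f"unknown solver {self.name!r}")


@dataclass
class TrainedIsingModel:
    weights: np.ndarray  # (K-1, M) in [-1, 1]
    class_names: list[str]
    solver_name: str
    beta_final_selected: float | None
    n_averaged: int
    training_nll: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.abs(self.weights) > 1 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")


def _logits(weights: np.ndarray, x_mat: np.ndarray) -> np.ndarray:
    """(N, K) log-scores: w_k^T x for k < K, and 0 for the pivot class."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    x2 = np.atleast_2d(np.asarray(x_mat, dtype=float))
    if x2.shape[1] != w.shape[1]:
        raise ValueError(
            f"feature dimension {x2.shape[1]} != weight dimension {w.shape[1]}"
        )
    z = x2 @ w.T
    return np.hstack([z, np.zeros((z.shape[0], 1))])


def class_probabilities(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Softmax class probabilities with the last class as pivot.

    Pr(k) = exp(w_k^T x) / (1 + sum_k' exp(w_k'^T x)) for k < K and
    Pr(K) = 1 / (1 + sum_k' exp(w_k'^T x)).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    z = _logits(weights, x)
    p = np.exp(z - logsumexp(z, axis=1, keepdims=True))
    return p[0] if squeeze else p


def negative_log_likelihood(weights: np.ndarray, dataset: LabeledDataset) -> float:
    """Exact softmax NLL, -sum_i ln Pr(y_i | x_i), in nats.

    A zero probability on an observed class yields +inf rather than an
    exception.
    """
    z = _logits(weights, dataset.features)
    log_p = z - logsumexp(z, axis=1, keepdims=True)
    picked = log_p[np.arange(dataset.n_samples), dataset.labels - 1]
    return float(0.0 - picked.sum())  # 0.0 - x avoids IEEE -0.0 for perfect fits


def predict(weights: np.ndarray, x_mat: np.ndarray) -> np.ndarray:
    """Argmax-probability labels (1..K); ties go to the lowest class index."""
    z = _logits(weights, np.atleast_2d(np.asarray(x_mat, dtype=float)))
    return np.argmax(z, axis=1) + 1


def predict_proba(weights: np.ndarray, x_mat: np.ndarray) -> np.ndarray:
    return class_probabilities(weights, np.atleast_2d(np.asarray(x_mat, dtype=float)))


def postprocess_average(
    result: SolverResult,
    dataset: LabeledDataset,
    n_keep: int = 20,
    solver_name: str | None = None,
    beta_final: float | None = None,
) -> TrainedIsingModel:
    """Greedy ensemble averaging of the lowest-energy configurations.

    Duplicates are removed, the ``n_keep`` lowest-energy configurations
    retained, and configurations are admitted in ascending energy order
    iff the element-wise mean of the enlarged set strictly lowers the
    exact training NLL.
    """
    if result.configurations.shape[0] == 0:
        raise ValueError("empty solver result")
    m, k = dataset.n_features, dataset.n_classes
    _, first_idx = np.unique(result.configurations, axis=0, return_index=True)
    keep_idx = np.sort(first_idx)[: max(n_keep, 1)]
    candidates = result.configurations[keep_idx].astype(float)

    accepted = candidates[:1]
    best_w = spins_to_weights(accepted.mean(axis=0), m, k)
    best_nll = negative_log_likelihood(best_w, dataset)
    for cand in candidates[1:]:
        trial = np.vstack([accepted, cand[np.newaxis, :]])
        w = spins_to_weights(trial.mean(axis=0), m, k)
        nll = negative_log_likelihood(w, dataset)
        if nll < best_nll:
            accepted, best_w, best_nll = trial, w, nll
    return TrainedIsingModel(
        weights=best_w,
        class_names=list(dataset.class_names),
        solver_name=solver_name or result.solver_name,
        beta_final_selected=beta_final,
        n_averaged=accepted.shape[0],
        training_nll=best_nll,
    )


def _solve(problem, spec: SolverSpec, beta_final: float | None, seed: int):
    if spec.name == "field":
        return solve_field(problem)
    if spec.name == "random":
        return solve_random(problem, n_reads=spec.n_reads, seed=seed)
    schedule = AnnealSchedule(
        n_sweeps=spec.n_sweeps,
        beta_initial=spec.beta_initial,
        beta_final=beta_final if beta_final is not None else 3.0,
    )
    return solve_sa(problem, schedule, n_reads=spec.n_reads, seed=seed)


def _fit_once(
    dataset: LabeledDataset, spec: SolverSpec, beta_final: float | None, seed: int
) -> TrainedIsingModel:
    problem = scale_to_unit(encode(dataset))
    result = _solve(problem, spec, beta_final, seed)
    return postprocess_average(
        result, dataset, n_keep=spec.n_keep, solver_name=spec.name, beta_final=beta_final
    )


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)
    ]
    return float(np.mean(recalls))


def fit(
    dataset: LabeledDataset,
    solver_spec: SolverSpec | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> TrainedIsingModel:
    """Cross-validated hyperparameter selection, then a full refit.

    For SA without a fixed ``beta_final``, each grid candidate is scored
    by mean validation balanced accuracy over stratified folds; ties
    favour the smaller candidate.  Field and Random skip CV.  Fold counts
    above the minimum class size are reduced with a warning.
    """
    spec = solver_spec or SolverSpec()
    ss = np.random.SeedSequence(seed)
    needs_cv = spec.name == "sa" and spec.beta_final is None and len(spec.beta_grid) > 1
    if not needs_cv:
        beta = spec.beta_final if spec.name == "sa" else None
        if spec.name == "sa" and beta is None:
            beta = spec.beta_grid[0]
        return _fit_once(dataset, spec, beta, seed=int(ss.generate_state(1)[0]))

    counts = np.bincount(dataset.labels)[1:]
    min_class = int(counts.min())
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d members)",
            cv_folds, folds, min_class,
        )
    folds = max(folds, 2)

    fold_seed = int(ss.generate_state(1)[0])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed % 2**32)
    splits = list(skf.split(dataset.features, dataset.labels))
    child_seeds = ss.spawn(len(spec.beta_grid))
    scores = []
    for beta, child in zip(spec.beta_grid, child_seeds):
        fold_seeds = child.generate_state(len(splits))
        accs = []
        for (tr, va), fseed in zip(splits, fold_seeds):
            model = _fit_once(dataset.subset(tr), spec, float(beta), seed=int(fseed))
            y_hat = predict(model.weights, dataset.features[va])
            accs.append(_balanced_accuracy(dataset.labels[va], y_hat))
        scores.append(float(np.mean(accs)))
    best = int(np.argmax(scores))  # argmax takes the first max: smaller beta wins ties
    best_beta = float(spec.beta_grid[best])
    refit_seed = int(ss.generate_state(2)[1])
    return _fit_once(dataset, spec, best_beta, seed=refit_seed)


def model_to_json(model: TrainedIsingModel) -> str:
    return json.dumps(
        {
            "weights": model.weights.tolist(),
            "class_names": model.class_names,
            "solver": model.solver_name,
            "beta_final": model.beta_final_selected,
            "n_averaged": model.n_averaged,
            "training_nll": model.training_nll,
        }
    )


def model_from_json(text: str) -> TrainedIsingModel:
    obj = json.loads(text)
    return TrainedIsingModel(
        weights=np.asarray(obj["weights"], dtype=float),
        class_names=list(obj["class_names"]),
        solver_name=obj["solver"],
        beta_final_selected=obj["beta_final"],
        n_averaged=int(obj["n_averaged"]),
        training_nll=float(obj["training_nll"]),
    )
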