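"""Readers/writers and the reproducible experiment driver.

Feature matrices are CSV/TSV with a header row and a first column of
sample IDs; labels are two-column CSV (sample_id, class).  Every random
draw in :func:`run_experiment` derives from the master seed through
``numpy.random.SeedSequence`` spawning, so a run log plus the config
suffice to replay a run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import LabeledDataset
from .evaluation import (
    EvaluationReport,
    IsingClassifier,
    RBMClassifier,
    baseline_classifier,
    compare_classifiers,
    evaluate_classifiers,
    make_splits,
)
from .model import SolverSpec

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "load_dataset",
    "RunConfig",
    "build_classifiers",
    "run_experiment",
]

logger = logging.getLogger(__name__)


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a samples-by-features table; returns (matrix, sample_ids, feature_names).

    Non-numeric or missing cells raise with the offending coordinates;
    duplicate sample IDs are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric or missing value at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return values, [str(s) for s in df.index], [str(c) for c in df.columns]


def write_feature_matrix(
    path: str | Path,
    matrix: np.ndarray,
    sample_ids: list[str],
    feature_names: list[str],
) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix, index=sample_ids, columns=feature_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_delimiter_for(path))


def read_labels(path: str | Path) -> tuple[list[str], list[str]]:
    """Read (sample_id, class) pairs; returns (sample_ids, class values)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs sample_id and class columns")
    return df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist()


def write_labels(path: str | Path, sample_ids: list[str], classes: list[str]) -> None:
    pd.DataFrame({"sample_id": sample_ids, "class": classes}).to_csv(
        Path(path), index=False
    )


def load_dataset(features_path: str | Path, labels_path: str | Path) -> LabeledDataset:
    """Join a feature matrix and a label file into a LabeledDataset.

    Class names are the sorted unique label strings; integer labels follow
    that order (the last name is the softmax pivot).
    """
    matrix, sample_ids, feature_names = read_feature_matrix(features_path)
    label_ids, classes = read_labels(labels_path)
    lookup = dict(zip(label_ids, classes))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    class_names = sorted(set(classes))
    to_int = {name: i + 1 for i, name in enumerate(class_names)}
    labels = np.array([to_int[lookup[s]] for s in sample_ids], dtype=int)
    return LabeledDataset(
        features=matrix,
        labels=labels,
        n_classes=len(class_names),
        class_names=class_names,
        feature_names=feature_names,
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce one evaluation run."""

    features_path: str
    labels_path: str
    classifiers: list[str] = field(default_factory=lambda: ["sa", "random", "field"])
    n_splits: int = 100
    train_fraction: float = 0.8
    n_pcs: int | None = None
    n_reads: int = 1000
    n_sweeps: int = 1000
    beta_initial: float = 0.01
    beta_grid: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0, 3.0)
    n_keep: int = 20
    cv_folds: int = 10
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "beta_grid" in raw:
            raw["beta_grid"] = tuple(raw["beta_grid"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["beta_grid"] = list(d["beta_grid"])
        return yaml.safe_dump(d, sort_keys=True)


def build_classifiers(config: RunConfig) -> list:
    """Instantiate adapter objects for every requested classifier name."""
    out = []
    for name in config.classifiers:
        if name in ("sa", "random", "field"):
            spec = SolverSpec(
                name=name,
                n_reads=config.n_reads,
                n_sweeps=config.n_sweeps,
                beta_initial=config.beta_initial,
                beta_grid=config.beta_grid,
                n_keep=config.n_keep,
            )
            out.append(IsingClassifier(spec, cv_folds=config.cv_folds))
        elif name == "rbm":
            out.append(RBMClassifier())
        else:
            out.append(baseline_classifier(name))
    return out


def run_experiment(config: RunConfig) -> EvaluationReport:
    """Splits -> scaling -> PCA -> fits -> metrics -> statistics, on disk.

    Writes report.csv (tidy), summary.csv, comparisons.csv and
    run_config.yaml under ``config.out_dir``; reruns with an identical
    config are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        dataset = load_dataset(config.features_path, config.labels_path)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[load] failed reading inputs: {exc}") from exc

    if config.n_pcs is not None:
        approx_train = int(round(config.train_fraction * dataset.n_samples))
        if config.n_pcs > min(approx_train, dataset.n_features):
            raise RuntimeError(
                f"[config] n_pcs={config.n_pcs} exceeds the rank available "
                f"from ~{approx_train} training rows x {dataset.n_features} features"
            )
    try:
        plan = make_splits(
            dataset.labels, config.n_splits, config.train_fraction, config.seed
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[split] failed building split plan: {exc}") from exc

    classifiers = build_classifiers(config)
    try:
        report = evaluate_classifiers(
            dataset, classifiers, plan, n_pcs=config.n_pcs, seed=config.seed
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[evaluate] pipeline failed: {exc}") from exc

    report.records.to_csv(out_dir / "report.csv", index=False)
    report.summary("test").to_csv(out_dir / "summary.csv", index=False)
    if len(config.classifiers) >= 2:
        compare_classifiers(report).to_csv(out_dir / "comparisons.csv", index=False)
    (out_dir / "run_config.yaml").write_text(config.to_yaml())
    logger.info("experiment complete: %d splits, %d classifiers",
                config.n_splits, len(classifiers))
    return report
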