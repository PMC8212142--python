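"""Labeled dataset container shared by the encoder, solvers and evaluator."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class LabeledDataset:
    """A real-valued feature matrix with integer class labels 1..K.

    Parameters
    ----------
    features : (N, M) float array
        Feature matrix, assumed standardized (dimensionless).
    labels : (N,) int array
        Class labels in ``1..n_classes``.
    n_classes : int
        Number of classes K >= 2 (K >= 1 is tolerated only transiently;
        the encoder rejects K < 2).
    class_names : list of str
        K display names; the last one is the pivot class of the softmax
        parameterization.
    feature_names : list of str, optional
    metadata : dict
        Free-form provenance (e.g. planted signs from a generator).
    """

    features: np.ndarray
    labels: np.ndarray
    n_classes: int
    class_names: list[str] | None = None
    feature_names: list[str] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, m = self.features.shape
        if n < 1 or m < 1:
            raise ValueError("features must have at least one row and column")
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match N={n}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")
        k = int(self.n_classes)
        if k < 1:
            raise ValueError("n_classes must be positive")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > k:
            raise ValueError(f"labels must lie in 1..{k}")
        # A class may be legitimately absent in tiny fixtures or CV folds;
        # fitting and split planning enforce completeness where it matters.
        missing = set(range(1, k + 1)) - set(present.tolist())
        if missing:
            warnings.warn(
                f"classes {sorted(missing)} absent from labels", stacklevel=2
            )
        if self.class_names is None:
            self.class_names = [f"class_{i}" for i in range(1, k + 1)]
        if len(self.class_names) != k:
            raise ValueError("class_names length must equal n_classes")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(m)]
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must equal M")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row subset preserving class bookkeeping."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            n_classes=self.n_classes,
            class_names=list(self.class_names),
            feature_names=list(self.feature_names),
            metadata=dict(self.metadata),
        )
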