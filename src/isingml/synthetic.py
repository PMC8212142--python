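"""Seeded generators emulating standardized multi-omics-like matrices.

Features follow a block-constant correlation structure (blocks stand in for
concatenated assay platforms), class signal enters as mean shifts of
planted sign on a few informative features, and n << M regimes are a
configuration choice, not a special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset
from .encoder import IsingProblem, encode

__all__ = [
    "SyntheticSpec",
    "make_multiomics",
    "make_separable_toy",
    "make_small_n_benchmark",
    "worked_fixture",
]


@dataclass
class SyntheticSpec:
    """Configuration for :func:`make_multiomics`."""

    n_per_class: list[int]
    n_features: int
    n_informative: int
    effect_size: float  # class mean shift on informative features, sd units
    block_sizes: list[int] | None = None  # defaults to one block of M
    within_block_correlation: float = 0.0
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2:
            raise ValueError("need at least two classes")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("each class needs at least one sample")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.block_sizes is None:
            self.block_sizes = [self.n_features]
        if sum(self.block_sizes) != self.n_features:
            raise ValueError("block_sizes must partition the features")
        rho = self.within_block_correlation
        if not (0.0 <= rho < 1.0):
            raise ValueError("within_block_correlation must be in [0, 1)")

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)


def make_multiomics(spec: SyntheticSpec) -> LabeledDataset:
    """Block-correlated Gaussian features with planted class mean shifts.

    Within a block the correlation is constant (equicorrelated), across
    blocks features are independent.  Each non-pivot class k < K shifts
    informative feature j by ``+effect_size * sign[k, j]``; the pivot
    (last) class is unshifted.  Planted signs and informative indices are
    stored in ``metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_classes
    n_total = sum(spec.n_per_class)
    m = spec.n_features
    rho = spec.within_block_correlation

    # Equicorrelated block draw: sqrt(rho)*shared + sqrt(1-rho)*idiosyncratic.
    x = np.empty((n_total, m))
    col = 0
    for size in spec.block_sizes:
        shared = rng.standard_normal((n_total, 1))
        noise = rng.standard_normal((n_total, size))
        x[:, col : col + size] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        col += size

    labels = np.repeat(np.arange(1, k + 1), spec.n_per_class)
    informative = rng.choice(m, size=spec.n_informative, replace=False)
    informative.sort()
    signs = rng.choice([-1.0, 1.0], size=(k - 1, spec.n_informative))
    for cls in range(1, k):  # classes 1..K-1 shifted, pivot class K untouched
        rows = labels == cls
        x[np.ix_(rows, informative)] += spec.effect_size * signs[cls - 1]

    if spec.standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - mu) / sd

    perm = rng.permutation(n_total)
    return LabeledDataset(
        features=x[perm],
        labels=labels[perm],
        n_classes=k,
        metadata={
            "informative_indices": informative.tolist(),
            "planted_signs": signs.tolist(),
            "effect_size": spec.effect_size,
            "seed": spec.seed,
        },
    )


def make_small_n_benchmark(
    seed: int,
    n_samples: int = 280,
    n_blocks: int = 10,
    block_size: int = 20,
    rho: float = 0.6,
    n_signal_blocks: int = 3,
    effect_size: float = 0.7,
) -> LabeledDataset:
    """Binary benchmark for the shrinking-training-set phenomenon.

    Raw dimensionality exceeds the retained feature count so that a
    training-set PCA truncation (the harness default of 44 components)
    concentrates the class signal in a few high-variance directions, as
    in multi-omics matrices.  The signal is block-coherent: the first
    ``n_signal_blocks`` correlated blocks are shifted wholesale for class
    1, with alternating block sign.  Features are standardized marginally.
    """
    rng = np.random.default_rng(seed)
    m = n_blocks * block_size
    half = n_samples // 2
    n_total = 2 * half
    x = np.empty((n_total, m))
    for b in range(n_blocks):
        shared = rng.standard_normal((n_total, 1))
        noise = rng.standard_normal((n_total, block_size))
        x[:, b * block_size : (b + 1) * block_size] = (
            np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        )
    labels = np.repeat([1, 2], half)
    for b in range(n_signal_blocks):
        sign = 1.0 if b % 2 == 0 else -1.0
        x[labels == 1, b * block_size : (b + 1) * block_size] += sign * effect_size
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    x = (x - mu) / np.where(sd == 0, 1.0, sd)
    perm = rng.permutation(n_total)
    return LabeledDataset(
        features=x[perm],
        labels=labels[perm],
        n_classes=2,
        metadata={
            "n_signal_blocks": n_signal_blocks,
            "block_size": block_size,
            "rho": rho,
            "effect_size": effect_size,
            "seed": seed,
        },
    )


def make_separable_toy(n: int, margin: float, seed: int = 0) -> LabeledDataset:
    """Two unit-noise Gaussian clusters at (+margin, 0) and (-margin, 0)."""
    if n % 2 != 0:
        raise ValueError("n must be even")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rng = np.random.default_rng(seed)
    half = n // 2
    x = rng.standard_normal((n, 2))
    x[:half, 0] += margin
    x[half:, 0] -= margin
    labels = np.concatenate([np.ones(half, dtype=int), np.full(half, 2)])
    perm = rng.permutation(n)
    return LabeledDataset(
        features=x[perm], labels=labels[perm], n_classes=2,
        metadata={"margin": margin, "seed": seed},
    )


def worked_fixture() -> tuple[LabeledDataset, IsingProblem]:
    """Single-point binary fixture with its hand-evaluated encoding.

    One example x = [1.0] in class 1 of 2 encodes to linear = [-0.5],
    no pair terms, offset = 0.125.
    """
    dataset = LabeledDataset(
        features=np.array([[1.0]]), labels=np.array([1]), n_classes=2
    )
    expected = IsingProblem(
        linear=np.array([-0.5]),
        quadratic=np.zeros((1, 1)),
        offset=0.125,
        n_features=1,
        n_classes=2,
    )
    # Regression guard: the stored expectation must match the encoder.
    got = encode(dataset)
    assert np.allclose(got.linear, expected.linear)
    assert abs(got.offset - expected.offset) < 1e-15
    return dataset, expected
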