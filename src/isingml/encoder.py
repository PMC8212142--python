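"""Encoding of a multinomial classification task as an Ising objective.

The softmax negative log likelihood with K-1 weight vectors of length M is
Taylor-expanded to second order around zero weights, yielding an Ising
objective over D = M*(K-1) spins: per-class linear blocks, within-class
pair couplings, and between-class pair couplings.  Diagonal quadratic terms
are constant under +/-1 spins and are folded into the scalar offset; the
additive constant N*log(K) of the expansion is dropped (it never affects
the argmin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset

__all__ = [
    "IsingProblem",
    "encode",
    "ising_energy",
    "scale_to_unit",
    "logical_variable_count",
    "max_features",
    "spins_to_weights",
    "problem_to_json",
    "problem_from_json",
    "problem_to_qubo_text",
]


@dataclass
class IsingProblem:
    """Linear + strictly-upper-triangular quadratic Ising coefficients.

    ``quadratic[i, j]`` is the coefficient of ``s_i * s_j`` with each
    unordered pair counted once (i < j); entries with i >= j are zero.
    """

    linear: np.ndarray
    quadratic: np.ndarray
    offset: float
    n_features: int
    n_classes: int

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        d = self.linear.shape[0]
        if self.quadratic.shape != (d, d):
            raise ValueError("quadratic must be D x D")
        if not np.all(np.isfinite(self.linear)) or not np.all(
            np.isfinite(self.quadratic)
        ):
            raise ValueError("non-finite Ising coefficients")
        if np.any(np.tril(self.quadratic) != 0.0):
            raise ValueError("quadratic must be strictly upper triangular")
        if d != self.n_features * (self.n_classes - 1):
            raise ValueError("D must equal M*(K-1)")

    @property
    def n_variables(self) -> int:
        return self.linear.shape[0]


def logical_variable_count(n_features: int, n_classes: int) -> int:
    """Number of logical spin variables, M*(K-1)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return n_features * (n_classes - 1)


def max_features(capacity: int, n_classes: int) -> int:
    """Largest M with M*(K-1) <= capacity (hardware feasibility bound)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if capacity < n_classes - 1:
        raise ValueError("capacity below K-1: no feature fits")
    return capacity // (n_classes - 1)


def encode(dataset: LabeledDataset) -> IsingProblem:
    """Build the second-order Ising objective from a labeled dataset.

    Linear block k holds ``b_k + h`` with ``b_k = -sum_{i: y_i=k} x_i`` and
    ``h = (1/K) sum_i x_i``.  Within a class block, the pair (n, m) gets
    coupling ``(K-1)/K^2 * S_nm``; across blocks it gets ``-(1/K^2) * S_nm``,
    where ``S = sum_i x_i x_i^T`` (both folded from the symmetric quadratic
    form, so each unordered spin pair is counted once).
    """
    k = dataset.n_classes
    if k < 2:
        raise ValueError("encoding requires at least two classes")
    x = dataset.features
    y = dataset.labels
    n, m = x.shape
    d = m * (k - 1)

    s_mat = x.T @ x  # sum_i x_i x_i^T
    h_vec = x.sum(axis=0) / k

    linear = np.empty(d)
    for blk in range(k - 1):
        b_k = -x[y == blk + 1].sum(axis=0) if np.any(y == blk + 1) else np.zeros(m)
        linear[blk * m : (blk + 1) * m] = b_k + h_vec

    intra = (k - 1) / k**2 * s_mat  # folded 2*J' off-diagonal
    inter = -(1.0 / k**2) * s_mat  # folded -2*J'' for every (n, m)
    quadratic = np.zeros((d, d))
    for bj in range(k - 1):
        sl_j = slice(bj * m, (bj + 1) * m)
        quadratic[sl_j, sl_j] = np.triu(intra, 1)
        for bk in range(bj + 1, k - 1):
            quadratic[sl_j, bk * m : (bk + 1) * m] = inter

    # w_i^2 = 1 makes the J' diagonal a constant: one trace per class block.
    offset = (k - 1) ** 2 / (2 * k**2) * float(np.trace(s_mat))
    return IsingProblem(linear, quadratic, offset, n_features=m, n_classes=k)


def ising_energy(problem: IsingProblem, spins: np.ndarray) -> float:
    """Energy sum_i h_i s_i + sum_{i<j} J_ij s_i s_j + offset."""
    s = np.asarray(spins, dtype=float)
    if s.shape != (problem.n_variables,):
        raise ValueError(
            f"spin vector length {s.shape} != D={problem.n_variables}"
        )
    return float(problem.linear @ s + s @ problem.quadratic @ s + problem.offset)


def scale_to_unit(problem: IsingProblem) -> IsingProblem:
    """Rescale so every coefficient lies in [-1, 1] (argmin-preserving).

    Divides linear, quadratic and offset by the largest coefficient
    magnitude; a zero problem is returned unchanged.
    """
    c = max(
        np.abs(problem.linear).max(initial=0.0),
        np.abs(problem.quadratic).max(initial=0.0),
    )
    if c == 0.0:
        return problem
    return IsingProblem(
        problem.linear / c,
        problem.quadratic / c,
        problem.offset / c,
        n_features=problem.n_features,
        n_classes=problem.n_classes,
    )


def spins_to_weights(spins: np.ndarray, n_features: int, n_classes: int) -> np.ndarray:
    """Reshape D = M*(K-1) spins into a (K-1, M) block-major weight matrix."""
    s = np.asarray(spins, dtype=float)
    d = logical_variable_count(n_features, n_classes)
    if s.shape != (d,):
        raise ValueError(f"expected {d} spins, got {s.shape}")
    return s.reshape(n_classes - 1, n_features)


def problem_to_json(problem: IsingProblem) -> str:
    """Serialize as JSON with sparse 0-based (i, j, value) quadratic triples."""
    iu, ju = np.nonzero(problem.quadratic)
    triples = [
        [int(i), int(j), float(problem.quadratic[i, j])] for i, j in zip(iu, ju)
    ]
    return json.dumps(
        {
            "n_features": problem.n_features,
            "n_classes": problem.n_classes,
            "linear": problem.linear.tolist(),
            "quadratic": triples,
            "offset": problem.offset,
        }
    )


def problem_from_json(text: str) -> IsingProblem:
    obj = json.loads(text)
    linear = np.asarray(obj["linear"], dtype=float)
    d = linear.shape[0]
    quadratic = np.zeros((d, d))
    for i, j, v in obj["quadratic"]:
        if not i < j:
            raise ValueError("quadratic triples must satisfy i < j")
        quadratic[int(i), int(j)] = float(v)
    return IsingProblem(
        linear,
        quadratic,
        float(obj["offset"]),
        n_features=int(obj["n_features"]),
        n_classes=int(obj["n_classes"]),
    )


def problem_to_qubo_text(problem: IsingProblem) -> str:
    """Plain-text triple dialect: 'i i h_i' lines then 'i j J_ij' lines."""
    lines = [
        f"{i} {i} {float(problem.linear[i])!r}" for i in range(problem.n_variables)
    ]
    iu, ju = np.nonzero(problem.quadratic)
    lines += [f"{i} {j} {float(problem.quadratic[i, j])!r}" for i, j in zip(iu, ju)]
    return "\n".join(lines) + "\n"
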