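"""Classical annealing-family heuristics producing low-energy spin ensembles.

All solvers return a :class:`SolverResult` whose configurations are sorted
by ascending Ising energy and whose energies are exact re-evaluations of
the returned spins.  Every solver is a deterministic function of
(problem, hyperparameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoder import IsingProblem, ising_energy

__all__ = [
    "AnnealSchedule",
    "SolverResult",
    "solve_field",
    "solve_random",
    "solve_sa",
    "solve_exhaustive",
    "BETA_FINAL_GRID",
]

#: Final inverse-temperature candidates tuned by cross-validation.
BETA_FINAL_GRID = (0.03, 0.1, 0.3, 1.0, 3.0)

_EXHAUSTIVE_MAX_D = 20


@dataclass
class AnnealSchedule:
    """Linear inverse-temperature schedule for simulated annealing."""

    n_sweeps: int = 1000
    beta_initial: float = 0.01
    beta_final: float = 3.0
    schedule_type: str = "linear"

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.beta_initial < 0 or self.beta_final < self.beta_initial:
            raise ValueError("need 0 <= beta_initial <= beta_final")
        if self.schedule_type != "linear":
            raise ValueError("only the linear schedule is supported")

    def betas(self) -> np.ndarray:
        if self.n_sweeps == 1:
            return np.array([self.beta_final])
        return np.linspace(self.beta_initial, self.beta_final, self.n_sweeps)


@dataclass
class SolverResult:
    """Spin ensemble sorted by ascending energy."""

    configurations: np.ndarray  # (n, D) entries in {-1, +1}
    energies: np.ndarray  # (n,) ascending
    n_reads: int
    seed: int | None
    solver_name: str

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.configurations.shape[0] != self.energies.shape[0]:
            raise ValueError("configurations/energies length mismatch")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("energies must be sorted ascending")

    @property
    def best_configuration(self) -> np.ndarray:
        return self.configurations[0]

    @property
    def best_energy(self) -> float:
        return float(self.energies[0])

    def to_json_lines(self) -> str:
        return "\n".join(
            json.dumps({"spins": c.tolist(), "energy": float(e)})
            for c, e in zip(self.configurations, self.energies)
        ) + "\n"


def _sorted_result(
    problem: IsingProblem,
    configs: np.ndarray,
    n_reads: int,
    seed: int | None,
    name: str,
) -> SolverResult:
    energies = _batch_energies(problem, configs)
    order = np.argsort(energies, kind="stable")
    return SolverResult(
        configurations=configs[order].astype(np.int8),
        energies=energies[order],
        n_reads=n_reads,
        seed=seed,
        solver_name=name,
    )


def _batch_energies(problem: IsingProblem, configs: np.ndarray) -> np.ndarray:
    s = configs.astype(float)
    return (
        s @ problem.linear
        + np.einsum("ni,ij,nj->n", s, problem.quadratic, s)
        + problem.offset
    )


def solve_field(problem: IsingProblem) -> SolverResult:
    """Analytic single-spin solution ignoring couplings: s_i = -sign(h_i).

    Zero fields break the tie toward +1.
    """
    spins = np.where(problem.linear > 0, -1, 1).astype(np.int8)
    configs = spins[np.newaxis, :]
    return _sorted_result(problem, configs, n_reads=1, seed=None, name="field")


def solve_random(
    problem: IsingProblem, n_reads: int = 1000, seed: int = 0
) -> SolverResult:
    """I.i.d. uniform +/-1 configurations, energy-sorted.

    Per spin a uniform u in [0, 1) is drawn; u < 0.5 maps to -1, else +1.
    Draws consume the stream in (read, spin) order.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_reads, problem.n_variables))
    configs = np.where(u < 0.5, -1, 1).astype(np.int8)
    return _sorted_result(problem, configs, n_reads, seed, "random")


def solve_sa(
    problem: IsingProblem,
    schedule: AnnealSchedule | None = None,
    n_reads: int = 1000,
    seed: int = 0,
) -> SolverResult:
    """Simulated annealing with single-spin-flip Metropolis sweeps.

    Each read starts from a random +/-1 state; each sweep is one pass over
    the spins in fixed index order at the sweep's inverse temperature, with
    a flip accepted with probability min(1, exp(-beta * dE)).  All reads
    are annealed in lockstep (vectorized over reads), which is equivalent
    to running them independently.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    d = problem.n_variables
    spins = np.where(rng.random((n_reads, d)) < 0.5, -1.0, 1.0)

    # Symmetrized couplings give the local field of each spin in one product.
    j_sym = problem.quadratic + problem.quadratic.T
    h = problem.linear
    betas = schedule.betas()
    for beta in betas:
        accept_u = rng.random((d, n_reads))
        for i in range(d):
            local = h[i] + spins @ j_sym[i]
            delta_e = -2.0 * spins[:, i] * local
            flip = (delta_e <= 0) | (accept_u[i] < np.exp(-beta * np.clip(delta_e, 0, None)))
            spins[flip, i] *= -1.0
    return _sorted_result(problem, spins, n_reads, seed, "sa")


def solve_exhaustive(problem: IsingProblem) -> SolverResult:
    """All 2^D configurations by brute force (test oracle, D <= 20).

    Ties are broken lexicographically with -1 ordered before +1.
    """
    d = problem.n_variables
    if d > _EXHAUSTIVE_MAX_D:
        raise ValueError(f"exhaustive enumeration refused for D={d} > {_EXHAUSTIVE_MAX_D}")
    n = 1 << d
    idx = np.arange(n, dtype=np.uint32)
    # Bit d-1-j of the index is spin j, so index order == lexicographic order.
    bits = (idx[:, None] >> np.arange(d - 1, -1, -1)) & 1
    configs = np.where(bits == 0, -1, 1).astype(np.int8)
    result = _sorted_result(problem, configs, n_reads=n, seed=None, name="exhaustive")
    return result
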