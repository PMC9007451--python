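"""Genetic-algorithm fitting of torsion and valence-angle parameters.

The chromosome concatenates, across all fitted dihedral labels and their
allowed periodicities, one (barrier height, phase) gene pair. Barriers are
real-coded in [0, barrier_upper_bound]; phases are categorical, drawn from
the configured phase policy ({0, 180} for hydrocarbon torsions, 60-degree
increments for headgroup torsions). A brute-force grid oracle over the same
fitness provides an independent global optimum on small problems.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ff_energy import (
    DEG2RAD,
    FitDataset,
    HarmonicAngleParam,
    TorsionSeries,
    TorsionTerm,
    fit_diagnostics,
    fitness,
)

__all__ = [
    "PhasePolicy",
    "PeriodicityPolicy",
    "GAConfig",
    "FitResult",
    "run_ga_fit",
    "ga_oracle_fit",
    "fit_harmonic_angle",
    "train_test_split_report",
]


@dataclass(frozen=True)
class PhasePolicy:
    """Which discrete phase values gamma_n may take during fitting."""

    mode: str = "binary_0_180"
    fixed_values: Mapping[str, Sequence[float]] | None = None

    _MODES = ("binary_0_180", "increments_60", "fixed")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown phase mode {self.mode!r}; choose from {self._MODES}")
        if self.mode == "fixed" and not self.fixed_values:
            raise ValueError("mode='fixed' requires fixed_values")

    def phases(self, label: str) -> tuple[float, ...]:
        if self.mode == "binary_0_180":
            return (0.0, 180.0)
        if self.mode == "increments_60":
            return tuple(float(p) for p in range(0, 360, 60))
        vals = self.fixed_values.get(label)  # type: ignore[union-attr]
        if not vals:
            raise ValueError(f"no fixed phases configured for label {label!r}")
        return tuple(float(v) % 360.0 for v in vals)


@dataclass(frozen=True)
class PeriodicityPolicy:
    """Which periodicities n are carried per fitted label."""

    mode: str = "ensemble_1to3"
    retained: Mapping[str, Sequence[int]] | None = None

    _MODES = ("scan_1to5", "ensemble_1to3", "retain_from_start")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown periodicity mode {self.mode!r}; choose from {self._MODES}")
        if self.mode == "retain_from_start" and not self.retained:
            raise ValueError("mode='retain_from_start' requires retained sets")

    def periodicities(self, label: str) -> tuple[int, ...]:
        if self.mode == "scan_1to5":
            return (1, 2, 3, 4, 5)
        if self.mode == "ensemble_1to3":
            return (1, 2, 3)
        ns = self.retained.get(label)  # type: ignore[union-attr]
        if not ns:
            raise ValueError(f"empty allowed-periodicity set for label {label!r}")
        return tuple(int(n) for n in ns)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    elitism_count: int = 2
    barrier_upper_bound: float = 10.0
    mutation_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be smaller than population_size")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")


@dataclass
class FitResult:
    fitted: dict[str, TorsionSeries]
    train_fitness: float
    train_rmse: float
    train_r2: float
    history: list[float]
    seed: int
    test_rmse: float | None = None
    test_r2: float | None = None

    def to_report(self) -> dict:
        rep = {
            "labels": list(self.fitted),
            "terms": {
                lab: [
                    {"periodicity": t.periodicity, "barrier": t.barrier, "phase": t.phase}
                    for t in s.terms
                ]
                for lab, s in self.fitted.items()
            },
            "train": {"rmse": self.train_rmse, "r2": self.train_r2},
            "test": (
                {"rmse": self.test_rmse, "r2": self.test_r2}
                if self.test_rmse is not None
                else None
            ),
            "generations": len(self.history),
            "seed": self.seed,
        }
        return rep


class _FitnessKernel:
    """Vectorized evaluation of the fitting objective over many candidates.

    The model torsion energy of one candidate decomposes as
        E(theta) = sum_k V_k + sum_k V_k cos(gamma_k) cos(n_k theta)
                             + sum_k V_k sin(gamma_k) sin(n_k theta)
    so a whole population evaluates as two matrix products against
    precomputed cos/sin design matrices.
    """

    def __init__(
        self,
        dataset: FitDataset,
        phase_policy: PhasePolicy,
        periodicity_policy: PeriodicityPolicy,
        align_offset: bool = True,
    ) -> None:
        self.dataset = dataset
        self.align_offset = align_offset
        self.gene_labels: list[str] = []
        self.gene_ns: list[int] = []
        self.gene_phases: list[tuple[float, ...]] = []
        cols_c, cols_s = [], []
        for lab in dataset.fitted_labels:
            ns = periodicity_policy.periodicities(lab)
            if not ns:
                raise ValueError(f"empty allowed-periodicity set for label {lab!r}")
            ph = phase_policy.phases(lab)
            th = dataset.angles_array(lab) * DEG2RAD
            for n in ns:
                self.gene_labels.append(lab)
                self.gene_ns.append(n)
                self.gene_phases.append(ph)
                cols_c.append(np.cos(n * th))
                cols_s.append(np.sin(n * th))
        self.n_genes = len(self.gene_ns)
        self.C = np.column_stack(cols_c)  # (N, K)
        self.S = np.column_stack(cols_s)
        self.target = dataset.e_qm - dataset.e_zeroed
        self.w = dataset.weights
        self.wsum = float(self.w.sum())

    def evaluate(self, barriers: np.ndarray, phase_idx: np.ndarray) -> np.ndarray:
        """Fitness for a population; barriers/phase_idx are (P, K) arrays."""
        gamma = np.empty_like(barriers)
        for k, phases in enumerate(self.gene_phases):
            gamma[:, k] = np.asarray(phases)[phase_idx[:, k]]
        gamma *= DEG2RAD
        vc = barriers * np.cos(gamma)
        vs = barriers * np.sin(gamma)
        e_pop = self.C @ vc.T + self.S @ vs.T + barriers.sum(axis=1)  # (N, P)
        resid = self.target[:, None] - e_pop
        if self.align_offset and self.wsum > 0:
            resid = resid - (self.w @ resid)[None, :] / self.wsum
        return self.w @ (resid * resid)

    def to_series(self, barriers: np.ndarray, phase_idx: np.ndarray) -> dict[str, TorsionSeries]:
        """Decode one chromosome (1D gene arrays) into per-label series."""
        out: dict[str, list[TorsionTerm]] = {lab: [] for lab in self.dataset.fitted_labels}
        for k in range(self.n_genes):
            out[self.gene_labels[k]].append(
                TorsionTerm(
                    periodicity=self.gene_ns[k],
                    barrier=float(barriers[k]),
                    phase=float(self.gene_phases[k][int(phase_idx[k])]),
                )
            )
        return {lab: TorsionSeries(terms, label=lab) for lab, terms in out.items()}


def _best_index(fit_vals: np.ndarray, barriers: np.ndarray) -> int:
    """Index of the minimum fitness; exact ties broken by lowest sum(V) (parsimony)."""
    best = fit_vals.min()
    tied = np.flatnonzero(fit_vals == best)
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[np.argmin(barriers[tied].sum(axis=1))])


def run_ga_fit(
    dataset: FitDataset,
    phase_policy: PhasePolicy,
    periodicity_policy: PeriodicityPolicy,
    config: GAConfig,
    test_set: FitDataset | None = None,
) -> FitResult:
    """Real-coded GA minimizing the QM-vs-MM sum-of-squares objective.

    Deterministic for a given (dataset, policies, config): all randomness
    flows from one generator seeded by ``config.seed``. Elitism guarantees a
    non-increasing best-fitness history.
    """
    kern = _FitnessKernel(dataset, phase_policy, periodicity_policy)
    rng = np.random.default_rng(config.seed)
    P, K = config.population_size, kern.n_genes
    ub = config.barrier_upper_bound

    V = rng.uniform(0.0, ub, size=(P, K))
    G = np.column_stack(
        [rng.integers(0, len(kern.gene_phases[k]), size=P) for k in range(K)]
    )
    fit_vals = kern.evaluate(V, G)
    history: list[float] = []

    n_elite = config.elitism_count
    for _ in range(config.generations):
        order = np.argsort(fit_vals, kind="stable")
        elite_idx = order[:n_elite]

        # tournament selection (size 3) for the non-elite slots
        n_child = P - n_elite
        cand = rng.integers(0, P, size=(n_child, 3))
        winners = cand[np.arange(n_child), np.argmin(fit_vals[cand], axis=1)]
        childV = V[winners].copy()
        childG = G[winners].copy()

        # uniform crossover on consecutive pairs
        for i in range(0, n_child - 1, 2):
            if rng.random() < config.crossover_rate:
                mask = rng.random(K) < 0.5
                childV[i, mask], childV[i + 1, mask] = (
                    childV[i + 1, mask].copy(),
                    childV[i, mask].copy(),
                )
                childG[i, mask], childG[i + 1, mask] = (
                    childG[i + 1, mask].copy(),
                    childG[i, mask].copy(),
                )

        # Gaussian creep on barriers: coarse/fine sigma mixture, clipped to bounds
        mut = rng.random((n_child, K)) < config.mutation_rate
        sigma = np.where(rng.random((n_child, K)) < 0.5, config.mutation_sigma,
                         config.mutation_sigma * 0.05)
        childV = np.clip(childV + mut * rng.normal(0.0, 1.0, (n_child, K)) * sigma, 0.0, ub)

        # phase genes resample uniformly from the policy set
        pmut = rng.random((n_child, K)) < config.mutation_rate
        for k in range(K):
            hit = pmut[:, k]
            if hit.any():
                childG[hit, k] = rng.integers(0, len(kern.gene_phases[k]), size=int(hit.sum()))

        child_fit = kern.evaluate(childV, childG)
        V = np.vstack([V[elite_idx], childV])
        G = np.vstack([G[elite_idx], childG])
        fit_vals = np.concatenate([fit_vals[elite_idx], child_fit])
        history.append(float(fit_vals[_best_index(fit_vals, V)]))

    b = _best_index(fit_vals, V)
    fitted = kern.to_series(V[b], G[b])
    diag = fit_diagnostics(fitted, dataset)
    result = FitResult(
        fitted=fitted,
        train_fitness=float(fit_vals[b]),
        train_rmse=diag["rmse"],
        train_r2=diag["r_squared"],
        history=history,
        seed=config.seed,
    )
    if test_set is not None:
        tdiag = fit_diagnostics(fitted, test_set)
        result.test_rmse = tdiag["rmse"]
        result.test_r2 = tdiag["r_squared"]
    return result


_ORACLE_CAP = 10**7


def ga_oracle_fit(
    dataset: FitDataset,
    phase_policy: PhasePolicy,
    periodicity_policy: PeriodicityPolicy,
    barrier_grid: Sequence[float],
) -> tuple[dict[str, TorsionSeries], float]:
    """Exhaustive grid search over (barrier, phase) combinations.

    Returns the global minimum of the same fitness the GA uses; intended as
    an independent validation oracle on small problems.
    """
    kern = _FitnessKernel(dataset, phase_policy, periodicity_policy)
    grid = np.asarray(sorted(barrier_grid), dtype=float)
    sizes = [len(grid) * len(kern.gene_phases[k]) for k in range(kern.n_genes)]
    total = math.prod(sizes)
    if total > _ORACLE_CAP:
        raise ValueError(
            f"grid of {total} candidates exceeds the {_ORACLE_CAP} cap; use a coarser barrier grid"
        )

    # enumerate per-gene option tables then take the cartesian product
    optsV, optsG = [], []
    for k in range(kern.n_genes):
        nph = len(kern.gene_phases[k])
        optsV.append(np.repeat(grid, nph))
        optsG.append(np.tile(np.arange(nph), len(grid)))
    idx_mesh = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
    allV = np.column_stack([optsV[k][m.ravel()] for k, m in enumerate(idx_mesh)])
    allG = np.column_stack([optsG[k][m.ravel()] for k, m in enumerate(idx_mesh)])

    fit_vals = np.empty(total)
    step = max(1, 2_000_000 // max(len(dataset), 1))
    for start in range(0, total, step):
        sl = slice(start, min(start + step, total))
        fit_vals[sl] = kern.evaluate(allV[sl], allG[sl])
    b = _best_index(fit_vals, allV)
    return kern.to_series(allV[b], allG[b]), float(fit_vals[b])


def fit_harmonic_angle(
    scan: Sequence[tuple[float, float, float]],
) -> tuple[HarmonicAngleParam, dict[str, float]]:
    """Least-squares fit of K*(theta-theta0)^2 + c to (e_qm - e_zeroed).

    ``scan`` holds (theta_deg, e_zeroed, e_qm) records. The quadratic is
    linear in (a, b, c) with theta0 = -b/2a; a must be positive and theta0
    interior to the scan, otherwise there is no harmonic minimum to fit.
    """
    arr = np.asarray([(t, ez, eq) for t, ez, eq in scan], dtype=float)
    if arr.shape[0] < 5:
        raise ValueError("angle scan needs at least 5 points")
    theta = arr[:, 0]
    target = arr[:, 2] - arr[:, 1]
    X = np.column_stack([theta**2, theta, np.ones_like(theta)])
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    a, b, c = coef
    resid = target - X @ coef
    if a <= 0 or abs(a) < 1e-12 * max(1.0, float(np.abs(target).max())):
        raise ValueError("scan has no interior harmonic minimum (non-positive curvature)")
    theta0 = -b / (2.0 * a)
    if not theta.min() < theta0 < theta.max():
        raise ValueError(f"fitted minimum {theta0:.2f} deg lies outside the scan range")
    k_rad = float(a) / (DEG2RAD**2)
    rmse = float(np.sqrt(np.mean(resid**2)))
    offset = float(c - b * b / (4.0 * a))  # quadratic value at its minimum
    return (
        HarmonicAngleParam(force_constant=k_rad, equilibrium=float(theta0)),
        {"rmse": rmse, "offset": offset, "theta0": float(theta0), "k": k_rad},
    )


OVERFIT_RATIO = 2.0


def train_test_split_report(fit: FitResult) -> dict:
    """Side-by-side train/test metrics with an overfitting flag.

    Flags test RMSE exceeding twice the train RMSE, the symptom reported for
    over-parameterized torsion sets.
    """
    if fit.test_rmse is None:
        raise ValueError("fit result carries no test metrics")
    warning = None
    if fit.train_rmse > 0 and fit.test_rmse > OVERFIT_RATIO * fit.train_rmse:
        warning = (
            f"possible overfitting: test RMSE {fit.test_rmse:.4f} exceeds "
            f"{OVERFIT_RATIO}x train RMSE {fit.train_rmse:.4f}"
        )
    elif fit.train_rmse == 0 and fit.test_rmse > 0:
        warning = f"possible overfitting: perfect train fit but test RMSE {fit.test_rmse:.4f}"
    report = {
        "train": {"rmse": fit.train_rmse, "r2": fit.train_r2},
        "test": {"rmse": fit.test_rmse, "r2": fit.test_r2},
        "overfitting_warning": warning,
        "seed": fit.seed,
    }
    # must survive a JSON round trip losslessly
    json.loads(json.dumps(report))
    return report
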