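"""Force-field functional forms and the QM-vs-MM least-squares fitness.

Implements the AMBER-style cosine torsion series, the harmonic valence
angle, the SCNB-scaled 1-4 Lennard-Jones pair energy, and the
sum-of-squares objective used to fit torsion parameters to reference
quantum-chemical energies.

Units: energies in kcal/mol, distances in angstrom, angles in degrees at
the API surface (radians internally where a harmonic form requires it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TorsionTerm",
    "TorsionSeries",
    "HarmonicAngleParam",
    "LJ14Pair",
    "ConformerRecord",
    "FitDataset",
    "torsion_energy",
    "harmonic_angle_energy",
    "lj14_energy",
    "fitness",
    "fit_diagnostics",
]

DEG2RAD = math.pi / 180.0


@dataclass(frozen=True)
class TorsionTerm:
    """One cosine term V_n * (1 + cos(n*theta - gamma_n)).

    ``periodicity`` is n (>= 1), ``barrier`` is V_n in kcal/mol (>= 0;
    phase carries the sign information), ``phase`` is gamma_n in degrees,
    normalized to [0, 360).
    """

    periodicity: int
    barrier: float
    phase: float

    def __post_init__(self) -> None:
        if int(self.periodicity) != self.periodicity or self.periodicity < 1:
            raise ValueError(f"periodicity must be a positive integer, got {self.periodicity}")
        if self.barrier < 0:
            raise ValueError(f"barrier must be non-negative, got {self.barrier}")
        object.__setattr__(self, "phase", float(self.phase) % 360.0)


@dataclass(frozen=True)
class TorsionSeries:
    """An ordered set of cosine terms for one dihedral type."""

    terms: tuple[TorsionTerm, ...]
    label: str = ""

    def __init__(self, terms: Iterable[TorsionTerm], label: str = "") -> None:
        terms = tuple(terms)
        ns = [t.periodicity for t in terms]
        if len(set(ns)) != len(ns):
            raise ValueError(f"duplicate periodicities in series {label!r}: {sorted(ns)}")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "label", label)

    @property
    def total_barrier(self) -> float:
        return sum(t.barrier for t in self.terms)


@dataclass(frozen=True)
class HarmonicAngleParam:
    """Harmonic valence-angle parameters K (kcal/mol/rad^2) and theta0 (deg)."""

    force_constant: float
    equilibrium: float

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError(f"force_constant must be > 0, got {self.force_constant}")
        if not 0.0 < self.equilibrium < 180.0:
            raise ValueError(f"equilibrium must lie in (0, 180), got {self.equilibrium}")


@dataclass(frozen=True)
class LJ14Pair:
    """A 1-4 Lennard-Jones interaction with an SCNB scaling divisor.

    scnb = 2 reproduces the conventional 0.5 scaling; scnb = 6 the 0.167
    scaling used to tune the acyl-chain melting behaviour.
    """

    r: float
    A: float
    B: float
    scnb: float = 2.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.scnb <= 0:
            raise ValueError(f"scnb must be > 0, got {self.scnb}")


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer: fitted-torsion angles plus zeroed-MM and QM energies."""

    angles: Mapping[str, float]
    e_zeroed: float
    e_qm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")
        object.__setattr__(self, "angles", dict(self.angles))


@dataclass
class FitDataset:
    """A collection of conformers sharing a set of fitted-torsion labels."""

    conformers: list[ConformerRecord]
    fitted_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.conformers = list(self.conformers)
        self.fitted_labels = tuple(self.fitted_labels)
        if len(self.conformers) < 2:
            raise ValueError("a fit dataset needs at least 2 conformers")
        for i, c in enumerate(self.conformers):
            for lab in self.fitted_labels:
                if lab not in c.angles:
                    raise ValueError(f"conformer {i} is missing angle for label {lab!r}")

    def __len__(self) -> int:
        return len(self.conformers)

    def angles_array(self, label: str) -> np.ndarray:
        return np.array([c.angles[label] for c in self.conformers], dtype=float)

    @property
    def e_zeroed(self) -> np.ndarray:
        return np.array([c.e_zeroed for c in self.conformers], dtype=float)

    @property
    def e_qm(self) -> np.ndarray:
        return np.array([c.e_qm for c in self.conformers], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.conformers], dtype=float)


def torsion_energy(series: TorsionSeries, angle) -> float | np.ndarray:
    """Cosine-series torsion energy E = sum_n V_n*(1 + cos(n*theta - gamma_n)).

    ``angle`` (degrees, any real value; periodic in 360) may be a scalar or
    an array; the return matches its shape.
    """
    theta = np.asarray(angle, dtype=float) * DEG2RAD
    e = np.zeros_like(theta)
    for t in series.terms:
        e = e + t.barrier * (1.0 + np.cos(t.periodicity * theta - t.phase * DEG2RAD))
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(e)
    return e


def harmonic_angle_energy(param: HarmonicAngleParam, theta: float) -> float:
    """K*(theta - theta0)^2 with the deviation taken in radians."""
    if not 0.0 < theta < 180.0:
        raise ValueError(f"theta must lie in (0, 180), got {theta}")
    d = (theta - param.equilibrium) * DEG2RAD
    return param.force_constant * d * d


def lj14_energy(pair: LJ14Pair) -> float:
    """(1/scnb) * (A/r^12 - B/r^6)."""
    r6 = pair.r**6
    return (pair.A / (r6 * r6) - pair.B / r6) / pair.scnb


def _predicted_torsion(candidate: Mapping[str, TorsionSeries], dataset: FitDataset) -> np.ndarray:
    total = np.zeros(len(dataset))
    for lab in dataset.fitted_labels:
        if lab not in candidate:
            raise KeyError(f"candidate is missing a torsion series for label {lab!r}")
        total += torsion_energy(candidate[lab], dataset.angles_array(lab))
    return total


def fitness(
    candidate: Mapping[str, TorsionSeries],
    dataset: FitDataset,
    align_offset: bool = True,
) -> float:
    """Weighted sum of squared residuals between QM and model energies.

    The model energy is e_zeroed + the candidate torsion energies. With
    ``align_offset`` the analytically optimal constant shift (the weighted
    mean residual) is removed first, since QM and MM absolute energy zeros
    are unrelated.
    """
    resid = dataset.e_qm - dataset.e_zeroed - _predicted_torsion(candidate, dataset)
    w = dataset.weights
    if align_offset:
        wsum = w.sum()
        if wsum > 0:
            resid = resid - np.average(resid, weights=w)
    return float(np.sum(w * resid * resid))


def fit_diagnostics(
    candidate: Mapping[str, TorsionSeries],
    dataset: FitDataset,
) -> dict[str, float]:
    """RMSE and squared Pearson correlation of offset-aligned predictions.

    Returns ``{"rmse": ..., "r_squared": ...}``; r_squared is NaN when
    either series has zero variance (undefined, not zero).
    """
    if len(dataset) < 3:
        raise ValueError("diagnostics need at least 3 conformers")
    pred = dataset.e_zeroed + _predicted_torsion(candidate, dataset)
    qm = dataset.e_qm
    resid = qm - pred
    resid = resid - resid.mean()
    rmse = float(np.sqrt(np.mean(resid**2)))
    sp = pred - pred.mean()
    sq = qm - qm.mean()
    vp = float(np.dot(sp, sp))
    vq = float(np.dot(sq, sq))
    if vp == 0.0 or vq == 0.0:
        r2 = float("nan")
    else:
        r = float(np.dot(sp, sq)) / math.sqrt(vp * vq)
        r2 = r * r
    return {"rmse": rmse, "r_squared": r2}
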