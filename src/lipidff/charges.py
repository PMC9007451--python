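"""Ensemble averaging of per-conformer partial-charge sets.

Final fragment charges are the per-atom arithmetic mean over the ensemble
(200 conformers in the reference workflow); any rounding-scale residual is
redistributed uniformly so the fragment total equals its integer target net
charge exactly. Modular head/tail assembly is validated by summing the
integer fragment targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ChargeSet", "ChargeEnsemble", "average_charges", "validate_modular_assembly"]


@dataclass
class ChargeSet:
    atom_names: tuple[str, ...]
    charges: np.ndarray
    fragment_label: str = ""
    target_net: int = 0

    def __post_init__(self) -> None:
        self.atom_names = tuple(self.atom_names)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.atom_names) != len(self.charges):
            raise ValueError(
                f"{len(self.atom_names)} atom names but {len(self.charges)} charges"
            )
        if int(self.target_net) != self.target_net:
            raise ValueError(f"target_net must be an integer, got {self.target_net}")
        self.target_net = int(self.target_net)

    @property
    def total(self) -> float:
        return float(self.charges.sum())


@dataclass
class ChargeEnsemble:
    members: list[ChargeSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = list(self.members)
        if not self.members:
            raise ValueError("ensemble needs at least 1 member")
        ref = self.members[0]
        for m in self.members[1:]:
            if m.fragment_label != ref.fragment_label:
                raise ValueError(
                    f"fragment label mismatch: {m.fragment_label!r} vs {ref.fragment_label!r}"
                )
            if m.atom_names != ref.atom_names:
                for i, (a, b) in enumerate(zip(m.atom_names, ref.atom_names)):
                    if a != b:
                        raise ValueError(f"atom name mismatch at position {i}: {a!r} vs {b!r}")
                raise ValueError("members differ in atom count")
            if m.target_net != ref.target_net:
                raise ValueError("members disagree on target_net")

    def matrix(self) -> np.ndarray:
        return np.vstack([m.charges for m in self.members])


def average_charges(ensemble: ChargeEnsemble) -> ChargeSet:
    """Per-atom mean over the ensemble, then exact-total correction.

    The mean total can drift from the integer target only through numerical
    rounding; the residual is spread uniformly across atoms so the returned
    set sums to ``target_net`` exactly.
    """
    ref = ensemble.members[0]
    mean = ensemble.matrix().mean(axis=0)
    residual = float(mean.sum()) - ref.target_net
    mean = mean - residual / len(mean)
    return ChargeSet(
        atom_names=ref.atom_names,
        charges=mean,
        fragment_label=ref.fragment_label,
        target_net=ref.target_net,
    )


def validate_modular_assembly(
    head: ChargeSet, tails: Sequence[ChargeSet], declared_net: int | None = None
) -> tuple[int, bool, str]:
    """Sum fragment target charges and check against the declared species charge.

    Returns (combined net charge, pass flag, message). With no declared net,
    passes iff the combined charge is 0 (zwitterionic) or -1 (anionic).
    """
    fragments = [head, *tails]
    if not fragments:
        raise ValueError("at least one fragment required")
    net = sum(f.target_net for f in fragments)
    if declared_net is None:
        ok = net in (0, -1)
        msg = f"combined net charge {net:+d}" + ("" if ok else " is neither 0 nor -1")
    else:
        if int(declared_net) != declared_net:
            raise ValueError(f"declared net charge must be an integer, got {declared_net}")
        ok = net == int(declared_net)
        msg = (
            f"combined net charge {net:+d} matches declared {int(declared_net):+d}"
            if ok
            else f"combined net charge {net:+d} does not match declared {int(declared_net):+d}"
        )
    return net, ok, msg
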