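"""Synthetic ground-truth fixtures for every input class the package consumes.

Each generator is deterministic under its seed and returns (or writes) a
truth sidecar describing the planted signal, so analyzers can be validated
end to end without quantum chemistry or molecular dynamics. The fixture
"lipids" are deliberately non-physical bead constructions: they exist to
carry exact, known statistics (order parameters, head-to-head spacing,
tilt distributions, scripted midplane crossings), nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .charges import ChargeEnsemble, ChargeSet
from .ff_energy import ConformerRecord, FitDataset, TorsionSeries, torsion_energy
from .membrane import EventRecord, Frame, Topology

__all__ = [
    "make_fit_dataset",
    "make_angle_scan",
    "make_charge_ensemble",
    "make_bilayer_traj",
    "make_heating_scan",
    "make_z_paths",
]


def make_fit_dataset(
    truth: Mapping[str, TorsionSeries],
    n_conformers: int = 1000,
    noise_sigma: float = 0.0,
    offset: float = 0.0,
    seed: int = 0,
) -> tuple[FitDataset, dict]:
    """Conformer records whose QM energies embed a known torsion signal.

    Angles are uniform over (-180, 180]; e_zeroed is a smooth nuisance
    background in the angles; e_qm = e_zeroed + truth torsion energy +
    offset + N(0, noise_sigma). Returns (dataset, truth sidecar).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    labels = tuple(truth)
    angles = {lab: rng.uniform(-180.0, 180.0, size=n_conformers) for lab in labels}

    # smooth nuisance background uncorrelated with the planted cosine terms
    e_zeroed = np.full(n_conformers, 5.0)
    for k, lab in enumerate(labels):
        th = np.radians(angles[lab])
        e_zeroed = e_zeroed + 0.7 * np.sin(th + 0.3 * (k + 1)) + 0.2 * np.cos(4 * th + k)

    e_torsion = np.zeros(n_conformers)
    for lab in labels:
        e_torsion += torsion_energy(truth[lab], angles[lab])
    e_qm = e_zeroed + e_torsion + offset
    if noise_sigma > 0:
        e_qm = e_qm + rng.normal(0.0, noise_sigma, size=n_conformers)

    conformers = [
        ConformerRecord(
            angles={lab: float(angles[lab][i]) for lab in labels},
            e_zeroed=float(e_zeroed[i]),
            e_qm=float(e_qm[i]),
        )
        for i in range(n_conformers)
    ]
    sidecar = {
        "kind": "fit_dataset",
        "seed": seed,
        "noise_sigma": noise_sigma,
        "offset": offset,
        "truth": {
            lab: [
                {"periodicity": t.periodicity, "barrier": t.barrier, "phase": t.phase}
                for t in s.terms
            ]
            for lab, s in truth.items()
        },
    }
    return FitDataset(conformers=conformers, fitted_labels=labels), sidecar


def make_angle_scan(
    force_constant: float = 120.0,
    equilibrium: float = 112.0,
    offset: float = -3.1,
    theta_start: float = 90.0,
    theta_stop: float = 150.0,
    theta_step: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float, float]], dict]:
    """A 1-degree valence-angle scan around a known harmonic minimum."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    thetas = np.arange(theta_start, theta_stop + 0.5 * theta_step, theta_step)
    e_zeroed = np.zeros_like(thetas)
    d = np.radians(thetas - equilibrium)
    e_qm = force_constant * d * d + offset
    if noise_sigma > 0:
        e_qm = e_qm + rng.normal(0.0, noise_sigma, size=len(thetas))
    scan = [(float(t), float(z), float(q)) for t, z, q in zip(thetas, e_zeroed, e_qm)]
    sidecar = {
        "kind": "angle_scan",
        "seed": seed,
        "force_constant": force_constant,
        "equilibrium": equilibrium,
        "offset": offset,
        "noise_sigma": noise_sigma,
    }
    return scan, sidecar


def make_charge_ensemble(
    n_members: int = 200,
    n_atoms: int = 10,
    target_net: int = 0,
    spread: float = 0.05,
    fragment_label: str = "HEAD",
    seed: int = 0,
) -> tuple[ChargeEnsemble, dict]:
    """Per-conformer charge sets scattered around a base set; every member
    sums to target_net exactly."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 0.4, size=n_atoms)
    base -= (base.sum() - target_net) / n_atoms
    names = tuple(f"A{i + 1}" for i in range(n_atoms))
    members = []
    for _ in range(n_members):
        jitter = rng.normal(0.0, spread, size=n_atoms)
        jitter -= jitter.mean()  # keep each member exactly on target
        members.append(
            ChargeSet(
                atom_names=names,
                charges=base + jitter,
                fragment_label=fragment_label,
                target_net=target_net,
            )
        )
    sidecar = {
        "kind": "charge_ensemble",
        "seed": seed,
        "n_members": n_members,
        "target_net": target_net,
        "base_charges": base.tolist(),
    }
    return ChargeEnsemble(members=members), sidecar


def _orientations_for_scd(
    rng: np.random.Generator, n: int, s_cd: float, mode: str = "exact", kappa: float = 20.0
) -> np.ndarray:
    """Unit C->H vectors with <(3cos^2 theta - 1)/2> = s_cd.

    'exact' places every vector at cos^2 theta = (2 s_cd + 1)/3 (sign and
    azimuth random) so the per-sample order parameter equals the target;
    'vonmises' draws theta around the matching angle for smoother, only
    asymptotically exact statistics.
    """
    if not -0.5 <= s_cd <= 1.0:
        raise ValueError(f"S_CD target {s_cd} outside the feasible range [-0.5, 1]")
    c2 = (2.0 * s_cd + 1.0) / 3.0
    c = math.sqrt(c2)
    if mode == "exact":
        cos_t = c * rng.choice([-1.0, 1.0], size=n)
    elif mode == "vonmises":
        theta0 = math.acos(c)
        theta = rng.vonmises(0.0, kappa, size=n) + theta0
        cos_t = np.cos(theta) * rng.choice([-1.0, 1.0], size=n)
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def make_bilayer_traj(
    n_lipids: int = 64,
    dhh: float = 38.0,
    scd_targets: Sequence[float] = (0.2, 0.18, 0.15, 0.1),
    head_sigma: float = 0.5,
    box: tuple[float, float, float] = (64.0, 64.0, 80.0),
    n_frames: int = 5,
    n_cholesterol: int = 0,
    tilt_deg: float | None = None,
    tilt_sigma: float = 0.0,
    ch_bond: float = 1.09,
    orientation_mode: str = "exact",
    seed: int = 0,
) -> tuple[list[Frame], Topology, dict, dict]:
    """An idealized two-leaflet bead bilayer with planted statistics.

    Each lipid is one headgroup phosphorus (z near +-dhh/2, giving a known
    head-to-head spacing) plus, per chain carbon, a C bead with one H bead
    whose orientation distribution realizes the target order parameter.
    Optional sterol probes are O->C two-bead rods at a prescribed tilt.

    Returns (frames, topology, ch_pairs, truth sidecar); ch_pairs maps
    carbon position -> list of (C, H) atom-index pairs for order_parameters.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    for s in scd_targets:
        if not -0.5 <= s <= 1.0:
            raise ValueError(f"S_CD target {s} outside [-0.5, 1]")
    rng = np.random.default_rng(seed)
    n_carbons = len(scd_targets)
    half = n_lipids // 2

    names, elements, zs, charges, resids, resnames, roles = [], [], [], [], [], [], []
    ch_pairs: dict[int, list[tuple[int, int]]] = {i + 2: [] for i in range(n_carbons)}
    frames_xyz = [[] for _ in range(n_frames)]
    resid = 0

    def add_atom(name: str, el: str, z: int, q: float, rname: str, role: str) -> int:
        names.append(name)
        elements.append(el)
        zs.append(z)
        charges.append(q)
        resids.append(resid)
        resnames.append(rname)
        roles.append(role)
        return len(names) - 1

    for lip in range(n_lipids):
        resid += 1
        leaflet = 1.0 if lip < half else -1.0
        x = rng.uniform(0, box[0])
        y = rng.uniform(0, box[1])
        zhead = leaflet * dhh / 2.0
        ip = add_atom("P", "P", 15, 1.1, "LIP", "lipid")
        for fi in range(n_frames):
            frames_xyz[fi].append(
                [x, y, zhead + rng.normal(0.0, head_sigma) if head_sigma > 0 else zhead]
            )
        for ci in range(n_carbons):
            # chain beads start well below the head peak and are smeared so
            # they cannot out-spike it
            zc0 = leaflet * (dhh / 2.0 - 5.0 - 2.5 * ci)
            zc = zc0 + rng.normal(0.0, 1.0, size=n_frames)
            ic = add_atom(f"C{ci + 2}", "C", 6, -0.1, "LIP", "lipid")
            for fi in range(n_frames):
                frames_xyz[fi].append([x, y, zc[fi]])
            ih = add_atom(f"H{ci + 2}", "H", 1, 0.05, "LIP", "lipid")
            orient = _orientations_for_scd(rng, n_frames, scd_targets[ci], orientation_mode)
            for fi in range(n_frames):
                frames_xyz[fi].append(
                    [x + ch_bond * orient[fi, 0], y + ch_bond * orient[fi, 1],
                     zc[fi] + ch_bond * orient[fi, 2]]
                )
            ch_pairs[ci + 2].append((ic, ih))

    o_idx, c_idx = [], []
    rod_len = 8.0
    for ch in range(n_cholesterol):
        resid += 1
        leaflet = 1.0 if ch % 2 == 0 else -1.0
        x = rng.uniform(0, box[0])
        y = rng.uniform(0, box[1])
        io = add_atom("O3", "O", 8, -0.6, "CHL", "lipid")
        ic = add_atom("C17", "C", 6, 0.0, "CHL", "lipid")
        o_idx.append(io)
        c_idx.append(ic)
        for fi in range(n_frames):
            tilt = tilt_deg if tilt_deg is not None else 0.0
            if tilt_sigma > 0:
                tilt = float(np.clip(rng.normal(tilt, tilt_sigma), 0.0, 89.0))
            phi = rng.uniform(0, 2 * math.pi)
            zo = leaflet * (dhh / 2.0 - 1.0)
            dxy = rod_len * math.sin(math.radians(tilt))
            dz = -leaflet * rod_len * math.cos(math.radians(tilt))
            frames_xyz[fi].append([x, y, zo])
            frames_xyz[fi].append([x + dxy * math.cos(phi), y + dxy * math.sin(phi), zo + dz])

    topology = Topology(
        names=names, elements=elements, atomic_numbers=zs, partial_charges=charges,
        residue_ids=resids, residue_names=resnames, roles=roles,
    )
    frames = [
        Frame(coordinates=np.asarray(xyz, dtype=float), box=box, time=float(fi))
        for fi, xyz in enumerate(frames_xyz)
    ]
    sidecar = {
        "kind": "bilayer_traj",
        "seed": seed,
        "n_lipids": n_lipids,
        "dhh": dhh,
        "scd_targets": list(scd_targets),
        "n_cholesterol": n_cholesterol,
        "tilt_deg": tilt_deg,
        "cholesterol_o_indices": o_idx,
        "cholesterol_c_indices": c_idx,
    }
    return frames, topology, ch_pairs, sidecar


def make_heating_scan(
    midpoint: float = 335.0,
    width: float = 1.0,
    t_start: float = 300.0,
    t_stop: float = 350.0,
    rate_k_per_ns: float = 0.5,
    dt_ns: float = 0.1,
    apl_gel: float = 48.0,
    apl_fluid: float = 62.0,
    n_lipids: int = 128,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """A heating scan whose area-per-lipid follows a logistic in temperature.

    Returns ({'time','temperature','lx','ly'}, truth sidecar); box lengths
    encode the APL as Lx = Ly = sqrt(APL * n_lipids / 2).
    """
    if rate_k_per_ns <= 0:
        raise ValueError("heating rate must be positive")
    if not t_start < midpoint < t_stop:
        raise ValueError("midpoint must lie inside the temperature range")
    rng = np.random.default_rng(seed)
    duration = (t_stop - t_start) / rate_k_per_ns
    time = np.arange(0.0, duration + 0.5 * dt_ns, dt_ns)
    temp = t_start + rate_k_per_ns * time
    apl = apl_gel + (apl_fluid - apl_gel) / (1.0 + np.exp(-(temp - midpoint) / width))
    if noise_sigma > 0:
        apl = apl + rng.normal(0.0, noise_sigma, size=len(apl))
    side = np.sqrt(np.clip(apl, 1.0, None) * n_lipids / 2.0)
    series = {"time": time, "temperature": temp, "lx": side, "ly": side.copy()}
    sidecar = {
        "kind": "heating_scan",
        "seed": seed,
        "midpoint": midpoint,
        "width": width,
        "rate_k_per_ns": rate_k_per_ns,
        "dt_ns": dt_ns,
        "noise_sigma": noise_sigma,
        "n_lipids": n_lipids,
    }
    return series, sidecar


@dataclass(frozen=True)
class TransitScriptItem:
    """One scripted band visit: dwell frames near the midplane, then exit to
    the same leaflet ('return') or the opposite one ('cross')."""

    outcome: str  # 'cross' | 'return'
    dwell: int = 5

    def __post_init__(self) -> None:
        if self.outcome not in ("cross", "return"):
            raise ValueError(f"outcome must be 'cross' or 'return', got {self.outcome!r}")
        if self.dwell < 1:
            raise ValueError("dwell must be >= 1")


def make_z_paths(
    script: Sequence[TransitScriptItem | str],
    start_leaflet: int = 1,
    plateau: float = 15.0,
    plateau_frames: int = 20,
    band_halfwidth: float = 2.0,
    noise_sigma: float = 0.3,
    molecule_id: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, list[EventRecord], dict]:
    """A piecewise z(t) path executing scripted midplane visits.

    Noise is kept small enough (clipped to plateau +- 3 A, outside the band)
    that no unscripted band entry can occur; in-band dwell values stay within
    half the band. Returns (z array, truth events, sidecar).
    """
    if start_leaflet not in (1, -1):
        raise ValueError("start_leaflet must be +1 or -1")
    items = [TransitScriptItem(outcome=s) if isinstance(s, str) else s for s in script]
    rng = np.random.default_rng(seed)
    margin = band_halfwidth + 1.0

    def plateau_block(sign: int, n: int) -> np.ndarray:
        vals = sign * plateau + rng.normal(0.0, noise_sigma, size=n)
        return np.clip(vals * sign, margin + 1.0, None) * sign  # never near the band

    ramp_steps = 4
    z_parts = [plateau_block(start_leaflet, plateau_frames)]
    truth: list[EventRecord] = []
    pos = plateau_frames
    side = start_leaflet
    for item in items:
        # approach: from plateau to just outside the band
        approach = np.linspace(side * plateau, side * margin, ramp_steps + 1)[1:]
        z_parts.append(approach)
        pos += ramp_steps
        # in-band dwell, |z| < band/2 strictly
        dwell = rng.uniform(-0.5, 0.5, size=item.dwell) * band_halfwidth
        z_parts.append(dwell)
        start = pos
        end = pos + item.dwell - 1
        pos += item.dwell
        out_side = -side if item.outcome == "cross" else side
        kind = "flip_flop" if item.outcome == "cross" else "transient_visit"
        truth.append(
            EventRecord(
                molecule_id=molecule_id, start=start, end=end, kind=kind, start_leaflet=side
            )
        )
        exit_ramp = np.linspace(out_side * margin, out_side * plateau, ramp_steps)
        z_parts.append(exit_ramp)
        pos += ramp_steps
        z_parts.append(plateau_block(out_side, plateau_frames))
        pos += plateau_frames
        side = out_side
    z = np.concatenate(z_parts)
    sidecar = {
        "kind": "z_paths",
        "seed": seed,
        "molecule_id": molecule_id,
        "n_events": len(truth),
        "kinds": [e.kind for e in truth],
        "band_halfwidth": band_halfwidth,
    }
    return z, truth, sidecar
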