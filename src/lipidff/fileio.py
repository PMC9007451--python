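"""Readers and writers for the formats the package touches.

Trajectories: multi-model PDB (read via MDAnalysis, written here with one
CRYST1 box record) and AMBER NetCDF coordinate files (NetCDF3 classic, via
scipy). Parameters: AMBER frcmod DIHE/ANGLE records. Datasets, charge
tables, profiles and events: CSV / JSON / two-column whitespace text.

All writers are atomic: content goes to a temporary file in the target
directory and is renamed into place, so an interrupted run never leaves a
truncated output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .charges import ChargeEnsemble, ChargeSet
from .ff_energy import (
    ConformerRecord,
    FitDataset,
    HarmonicAngleParam,
    TorsionSeries,
    TorsionTerm,
)
from .membrane import DensityProfile, EventRecord, FormFactor, Frame, Topology

__all__ = [
    "atomic_write",
    "write_provenance",
    "read_fit_dataset_csv",
    "write_fit_dataset_csv",
    "read_fit_dataset_json",
    "write_fit_dataset_json",
    "write_frcmod",
    "read_frcmod",
    "read_charge_ensemble_csv",
    "write_charge_ensemble_csv",
    "write_charge_table",
    "read_trajectory",
    "write_pdb",
    "write_netcdf",
    "read_topology_csv",
    "write_topology_csv",
    "write_profile",
    "read_profile",
    "write_form_factor",
    "write_events_jsonl",
    "read_events_jsonl",
]


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a sibling temp file, rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_provenance(
    out_path: str | Path,
    command: str,
    inputs: dict | None = None,
    options: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Record enough context beside an output to re-run the command."""
    out_path = Path(out_path)
    prov_path = out_path.with_suffix(out_path.suffix + ".provenance.json")
    record = {
        "command": command,
        "inputs": inputs or {},
        "options": options or {},
        "seed": seed,
        "version": __version__,
    }
    with atomic_write(prov_path) as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
    return prov_path


# ---------------------------------------------------------------------------
# fit datasets

_RESERVED = ("e_zeroed", "e_qm", "weight")


def write_fit_dataset_csv(dataset: FitDataset, path: str | Path) -> None:
    cols = {lab: dataset.angles_array(lab) for lab in dataset.fitted_labels}
    cols["e_zeroed"] = dataset.e_zeroed
    cols["e_qm"] = dataset.e_qm
    w = dataset.weights
    if not np.all(w == 1.0):
        cols["weight"] = w
    df = pd.DataFrame(cols)
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False, float_format="%.12g")


def read_fit_dataset_csv(path: str | Path) -> FitDataset:
    df = pd.read_csv(path)
    labels = tuple(c for c in df.columns if c not in _RESERVED)
    for need in ("e_zeroed", "e_qm"):
        if need not in df.columns:
            raise ValueError(f"dataset CSV lacks required column {need!r}")
    weights = df["weight"].to_numpy() if "weight" in df.columns else np.ones(len(df))
    conformers = [
        ConformerRecord(
            angles={lab: float(row[lab]) for lab in labels},
            e_zeroed=float(row["e_zeroed"]),
            e_qm=float(row["e_qm"]),
            weight=float(weights[i]),
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return FitDataset(conformers=conformers, fitted_labels=labels)


def write_fit_dataset_json(dataset: FitDataset, path: str | Path) -> None:
    doc = {
        "fitted_labels": list(dataset.fitted_labels),
        "conformers": [
            {
                "angles": {k: float(v) for k, v in c.angles.items()},
                "e_zeroed": c.e_zeroed,
                "e_qm": c.e_qm,
                "weight": c.weight,
            }
            for c in dataset.conformers
        ],
    }
    with atomic_write(path) as fh:
        json.dump(doc, fh)


def read_fit_dataset_json(path: str | Path) -> FitDataset:
    with open(path) as fh:
        doc = json.load(fh)
    conformers = [
        ConformerRecord(
            angles=c["angles"],
            e_zeroed=c["e_zeroed"],
            e_qm=c["e_qm"],
            weight=c.get("weight", 1.0),
        )
        for c in doc["conformers"]
    ]
    return FitDataset(conformers=conformers, fitted_labels=tuple(doc["fitted_labels"]))


# ---------------------------------------------------------------------------
# frcmod

_TYPE_FIELD = 2  # AMBER atom-type strings are at most two characters


def _check_types(label: str, n_atoms: int) -> list[str]:
    parts = label.split("-")
    if len(parts) != n_atoms:
        raise ValueError(f"label {label!r} does not name {n_atoms} atom types")
    for p in parts:
        if not 1 <= len(p) <= _TYPE_FIELD:
            raise ValueError(f"atom type {p!r} exceeds the {_TYPE_FIELD}-character frcmod field")
    return parts


def write_frcmod(
    series_list: Sequence[TorsionSeries],
    angle_params: Sequence[tuple[str, HarmonicAngleParam]],
    path: str | Path,
    title: str = "parameters written by lipidff",
) -> None:
    """AMBER frcmod text: multi-term dihedrals chain continuation rows via a
    negative periodicity on every term but the last."""
    lines = [title, "MASS", "", "BOND", "", "ANGLE"]
    for label, p in angle_params:
        parts = _check_types(label, 3)
        tstr = "-".join(f"{t:<2s}" for t in parts)
        lines.append(f"{tstr}   {p.force_constant:10.3f}{p.equilibrium:12.3f}")
    lines += ["", "DIHE"]
    for series in series_list:
        parts = _check_types(series.label, 4)
        tstr = "-".join(f"{t:<2s}" for t in parts)
        terms = series.terms
        for i, t in enumerate(terms):
            pn = -t.periodicity if i < len(terms) - 1 else t.periodicity
            lines.append(
                f"{tstr}   1{t.barrier:15.5f}{t.phase:15.3f}{float(pn):15.1f}"
            )
    lines += ["", "IMPROPER", "", "NONBON", ""]
    with atomic_write(path) as fh:
        fh.write("\n".join(lines) + "\n")


def read_frcmod(
    path: str | Path,
) -> tuple[list[TorsionSeries], list[tuple[str, HarmonicAngleParam]]]:
    section = None
    dihe: dict[str, list[TorsionTerm]] = {}
    order: list[str] = []
    angles: list[tuple[str, HarmonicAngleParam]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for raw in lines[1:]:
        line = raw.rstrip()
        if not line.strip():
            continue
        word = line.strip()
        if word in ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON"):
            section = word
            continue
        if section == "ANGLE":
            types = line[:8].replace(" ", "")
            rest = line[8:].split()
            angles.append(
                (types, HarmonicAngleParam(force_constant=float(rest[0]), equilibrium=float(rest[1])))
            )
        elif section == "DIHE":
            types = line[:11].replace(" ", "")
            rest = line[11:].split()
            _div, pk, phase, pn = rest[:4]
            if types not in dihe:
                dihe[types] = []
                order.append(types)
            dihe[types].append(
                TorsionTerm(
                    periodicity=abs(int(float(pn))), barrier=float(pk), phase=float(phase)
                )
            )
    series = [TorsionSeries(terms=dihe[lab], label=lab) for lab in order]
    return series, angles


# ---------------------------------------------------------------------------
# charges

def write_charge_ensemble_csv(ensemble: ChargeEnsemble, path: str | Path) -> None:
    ref = ensemble.members[0]
    df = pd.DataFrame(ensemble.matrix(), columns=list(ref.atom_names))
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False, float_format="%.12g")


def read_charge_ensemble_csv(
    path: str | Path, fragment_label: str = "", target_net: int = 0
) -> ChargeEnsemble:
    df = pd.read_csv(path)
    names = tuple(df.columns)
    members = [
        ChargeSet(
            atom_names=names,
            charges=row.to_numpy(dtype=float),
            fragment_label=fragment_label,
            target_net=target_net,
        )
        for _, row in df.iterrows()
    ]
    return ChargeEnsemble(members=members)


def write_charge_table(
    charge_set: ChargeSet, path: str | Path, n_members: int, residual_before_fix: float
) -> None:
    """Two-column (atom, charge) table, 6-decimal print with an exact total.

    Rounding is applied first and the rounding residual redistributed so the
    printed charges sum to the integer target exactly.
    """
    rounded = np.round(charge_set.charges, 6)
    resid = round(float(rounded.sum()) - charge_set.target_net, 6)
    n = len(rounded)
    if resid != 0.0:
        per = round(resid / n, 6)
        rounded = np.round(rounded - per, 6)
        rounded[-1] = round(charge_set.target_net - rounded[:-1].sum(), 6)
    with atomic_write(path) as fh:
        for name, q in zip(charge_set.atom_names, rounded):
            fh.write(f"{name:<8s}{q:12.6f}\n")
    sidecar = {
        "fragment_label": charge_set.fragment_label,
        "n_members": n_members,
        "target_net": charge_set.target_net,
        "residual_before_fix": residual_before_fix,
    }
    with atomic_write(Path(path).with_suffix(".json")) as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# topology sidecar

_TOP_COLS = ["name", "element", "atomic_number", "partial_charge", "residue_id", "residue_name", "role"]


def write_topology_csv(topology: Topology, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": topology.names,
            "element": topology.elements,
            "atomic_number": topology.atomic_numbers,
            "partial_charge": topology.partial_charges,
            "residue_id": topology.residue_ids,
            "residue_name": topology.residue_names,
            "role": topology.roles,
        }
    )
    if topology.leaflets is not None:
        df["leaflet"] = topology.leaflets
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False, float_format="%.12g")


def read_topology_csv(path: str | Path) -> Topology:
    df = pd.read_csv(path)
    missing = [c for c in _TOP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"topology CSV lacks columns: {missing}")
    return Topology(
        names=df["name"].to_numpy(dtype=object),
        elements=df["element"].to_numpy(dtype=object),
        atomic_numbers=df["atomic_number"].to_numpy(),
        partial_charges=df["partial_charge"].to_numpy(),
        residue_ids=df["residue_id"].to_numpy(),
        residue_names=df["residue_name"].to_numpy(dtype=object),
        roles=df["role"].to_numpy(dtype=object),
        leaflets=df["leaflet"].to_numpy() if "leaflet" in df.columns else None,
    )


# ---------------------------------------------------------------------------
# trajectories


def write_pdb(frames: Sequence[Frame], topology: Topology, path: str | Path) -> None:
    """Multi-model PDB with a CRYST1 record (box of the first frame)."""
    b = frames[0].box
    with atomic_write(path) as fh:
        fh.write(
            f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for mi, frame in enumerate(frames, start=1):
            if frame.coordinates.shape[0] != len(topology):
                raise ValueError(
                    f"frame {mi - 1} has {frame.coordinates.shape[0]} atoms, "
                    f"topology has {len(topology)}"
                )
            fh.write(f"MODEL     {mi:4d}\n")
            for i in range(len(topology)):
                x, y, z = frame.coordinates[i]
                name = str(topology.names[i])[:4]
                res = str(topology.residue_names[i])[:3]
                el = str(topology.elements[i])[:2]
                fh.write(
                    f"ATOM  {(i % 99999) + 1:5d} {name:<4s} {res:<3s} A{int(topology.residue_ids[i]) % 9999 + 0:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _read_pdb_frames(path: str | Path) -> tuple[list[np.ndarray], tuple[float, float, float]]:
    """Light multi-model PDB coordinate reader (CRYST1 + ATOM/HETATM records)."""
    box = None
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
            elif rec == "MODEL ":
                in_model = True
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                frames.append(np.asarray(current, dtype=float))
                in_model = False
                current = []
    if current and not frames:
        frames.append(np.asarray(current, dtype=float))  # single-model file
    if box is None:
        raise ValueError("PDB lacks a CRYST1 box record")
    if not frames:
        raise ValueError("PDB contains no coordinates")
    return frames, box


def read_trajectory(
    path: str | Path,
    meta_path: str | Path,
    topology_path: str | Path | None = None,
) -> tuple[list[Frame], Topology]:
    """Load frames from multi-model PDB or AMBER NetCDF plus a topology CSV.

    Atom counts are validated frame by frame against the topology; a
    mismatch is rejected with the offending frame index.
    """
    topology = read_topology_csv(meta_path)
    path = Path(path)
    frames: list[Frame] = []
    if path.suffix.lower() in (".nc", ".ncdf", ".netcdf"):
        coords, boxes, times = _read_netcdf_arrays(path)
        for fi in range(coords.shape[0]):
            if coords.shape[1] != len(topology):
                raise ValueError(
                    f"frame {fi} has {coords.shape[1]} atoms, topology has {len(topology)}"
                )
            frames.append(Frame(coordinates=coords[fi], box=tuple(boxes[fi]), time=float(times[fi])))
    else:
        raw, box = _read_pdb_frames(path)
        for fi, xyz in enumerate(raw):
            if xyz.shape[0] != len(topology):
                raise ValueError(
                    f"frame {fi} has {xyz.shape[0]} atoms, topology has {len(topology)}"
                )
            frames.append(Frame(coordinates=xyz, box=box, time=float(fi)))
    return frames, topology


def write_netcdf(frames: Sequence[Frame], path: str | Path) -> None:
    """AMBER NetCDF coordinate convention (NetCDF3 classic via scipy)."""
    from scipy.io import netcdf_file

    n_frames = len(frames)
    n_atoms = frames[0].coordinates.shape[0]
    for fi, f in enumerate(frames):
        if f.coordinates.shape[0] != n_atoms:
            raise ValueError(f"frame {fi} has {f.coordinates.shape[0]} atoms, expected {n_atoms}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    nc = netcdf_file(str(tmp), "w", version=2)
    try:
        nc.Conventions = b"AMBER"
        nc.ConventionVersion = b"1.0"
        nc.program = b"lipidff"
        nc.programVersion = __version__.encode()
        nc.title = b"synthetic trajectory"
        nc.createDimension("frame", None)
        nc.createDimension("atom", n_atoms)
        nc.createDimension("spatial", 3)
        nc.createDimension("cell_spatial", 3)
        nc.createDimension("cell_angular", 3)
        v_time = nc.createVariable("time", "f", ("frame",))
        v_time.units = b"picosecond"
        v_xyz = nc.createVariable("coordinates", "f", ("frame", "atom", "spatial"))
        v_xyz.units = b"angstrom"
        v_len = nc.createVariable("cell_lengths", "d", ("frame", "cell_spatial"))
        v_len.units = b"angstrom"
        v_ang = nc.createVariable("cell_angles", "d", ("frame", "cell_angular"))
        v_ang.units = b"degree"
        for fi, f in enumerate(frames):
            v_time[fi] = f.time
            v_xyz[fi] = f.coordinates.astype(np.float32)
            v_len[fi] = np.asarray(f.box)
            v_ang[fi] = (90.0, 90.0, 90.0)
        nc.flush()
    finally:
        nc.close()
    os.replace(tmp, path)


def _read_netcdf_arrays(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.io import netcdf_file

    with netcdf_file(str(path), "r", mmap=False) as nc:
        coords = np.array(nc.variables["coordinates"][:], dtype=float)
        if "cell_lengths" not in nc.variables:
            raise ValueError("NetCDF trajectory lacks cell_lengths (box) information")
        boxes = np.array(nc.variables["cell_lengths"][:], dtype=float)
        if "time" in nc.variables:
            times = np.array(nc.variables["time"][:], dtype=float)
        else:
            times = np.arange(coords.shape[0], dtype=float)
    return coords, boxes, times


# ---------------------------------------------------------------------------
# profiles, form factors, events


def write_profile(profile: DensityProfile, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for z, v in zip(profile.z_centers, profile.values):
            fh.write(f"{z:12.4f} {v:16.8e}\n")


def read_profile(path: str | Path, species: str = "", bin_width: float | None = None) -> DensityProfile:
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    bw = bin_width if bin_width is not None else float(arr[1, 0] - arr[0, 0]) if len(arr) > 1 else 0.25
    return DensityProfile(z_centers=arr[:, 0], values=arr[:, 1], species=species, bin_width=bw)


def write_form_factor(ff: FormFactor, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for q, m in zip(ff.q, ff.magnitude):
            fh.write(f"{q:10.4f} {m:16.8e}\n")


def write_events_jsonl(events: Sequence[EventRecord], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {
                        "molecule_id": e.molecule_id,
                        "start": e.start,
                        "end": e.end,
                        "kind": e.kind,
                        "start_leaflet": e.start_leaflet,
                    }
                )
                + "\n"
            )


def read_events_jsonl(path: str | Path) -> list[EventRecord]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                events.append(EventRecord(**d))
    return events
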