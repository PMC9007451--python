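"""Structural observables of lipid bilayers.

Everything a bilayer trajectory analysis needs downstream of the MD engine:
area and volume per lipid, z-binned number/electron density profiles and
head-to-head thickness, C-H (NMR) order parameters, X-ray and neutron
scattering form factors, sterol tilt histograms, midplane transit-event
detection, and melting-point extraction from heating scans.

Conventions: coordinates in angstrom, the bilayer normal along z, z = 0 at
the per-frame center of mass of lipid-role atoms. Frames and atoms are
0-indexed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import COHERENT_SCATTERING_LENGTHS_FM, WATER_ELECTRON_DENSITY

__all__ = [
    "Topology",
    "Frame",
    "DensityProfile",
    "FormFactor",
    "OrderParameterSeries",
    "EventRecord",
    "area_per_lipid",
    "volume_per_lipid",
    "density_profile",
    "dhh_from_profile",
    "order_parameters",
    "xray_form_factor",
    "sld_profile",
    "neutron_form_factor",
    "cholesterol_tilt",
    "transit_events",
    "melting_point",
]


@dataclass
class Topology:
    """Per-atom metadata for a bilayer system.

    ``role`` tags each atom as lipid / water / ion; ``mass`` defaults to the
    atomic number when not supplied (adequate for center-of-mass z-centering
    of synthetic systems).
    """

    names: np.ndarray
    elements: np.ndarray
    atomic_numbers: np.ndarray
    partial_charges: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    roles: np.ndarray
    leaflets: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        n = len(self.names)
        self.elements = np.asarray(self.elements, dtype=object)
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.partial_charges = np.asarray(self.partial_charges, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        for arr, nm in [
            (self.elements, "elements"), (self.atomic_numbers, "atomic_numbers"),
            (self.partial_charges, "partial_charges"), (self.residue_ids, "residue_ids"),
            (self.residue_names, "residue_names"), (self.roles, "roles"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{nm} has length {len(arr)}, expected {n}")
        if (self.atomic_numbers < 1).any():
            raise ValueError("atomic numbers must be >= 1")
        bad = set(self.roles) - {"lipid", "water", "ion"}
        if bad:
            raise ValueError(f"unknown role tags: {sorted(bad)}")
        if self.masses is None:
            self.masses = self.atomic_numbers.astype(float)
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    def __len__(self) -> int:
        return len(self.names)

    def select_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)


@dataclass
class Frame:
    """One trajectory frame: coordinates (N, 3) A, orthorhombic box, time in ps."""

    coordinates: np.ndarray
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        self.box = tuple(float(b) for b in self.box)
        if any(b <= 0 for b in self.box):
            raise ValueError(f"box lengths must be positive, got {self.box}")


@dataclass
class DensityProfile:
    z_centers: np.ndarray
    values: np.ndarray
    species: str = ""
    bin_width: float = 0.25

    def __post_init__(self) -> None:
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_centers.shape != self.values.shape:
            raise ValueError("z_centers and values must have matching shapes")
        if len(self.z_centers) > 1:
            dz = np.diff(self.z_centers)
            if not np.allclose(dz, dz[0], atol=1e-9):
                raise ValueError("z grid must be uniform")

    def symmetrized(self) -> "DensityProfile":
        """Average of rho(z) and rho(-z) on the same grid (grid must be symmetric)."""
        return DensityProfile(
            z_centers=self.z_centers,
            values=0.5 * (self.values + self.values[::-1]),
            species=self.species,
            bin_width=self.bin_width,
        )


@dataclass
class FormFactor:
    q: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if (self.q < 0).any() or (np.diff(self.q) <= 0).any():
            raise ValueError("q grid must be non-negative and strictly increasing")


@dataclass
class OrderParameterSeries:
    chain: str
    carbon_index: np.ndarray
    scd_signed: np.ndarray
    scd_abs: np.ndarray = field(default=None)  # type: ignore[assignment]
    scd_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.carbon_index = np.asarray(self.carbon_index, dtype=int)
        self.scd_signed = np.asarray(self.scd_signed, dtype=float)
        if self.scd_abs is None:
            self.scd_abs = np.abs(self.scd_signed)
        if (self.scd_abs > 1.0 + 1e-12).any():
            raise ValueError("|S_CD| cannot exceed 1")


@dataclass(frozen=True)
class EventRecord:
    molecule_id: int
    start: int
    end: int
    kind: Literal["flip_flop", "transient_visit"]
    start_leaflet: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end must be >= start")


# ---------------------------------------------------------------------------
# scalar box observables


def area_per_lipid(frames: Sequence[Frame], n_lipids: int) -> dict:
    """Lateral box area per leaflet lipid, Lx*Ly/(n_lipids/2), per frame."""
    if n_lipids <= 0 or n_lipids % 2:
        raise ValueError(f"n_lipids must be a positive even number, got {n_lipids}")
    series = np.array([f.box[0] * f.box[1] for f in frames]) / (n_lipids / 2)
    return {
        "series": series,
        "mean": float(series.mean()),
        "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
    }


def volume_per_lipid(
    frames: Sequence[Frame], n_waters: int, water_volume: float, n_lipids: int
) -> dict:
    """(box volume - n_waters * water volume) / n_lipids, per frame."""
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    vols = np.array([f.box[0] * f.box[1] * f.box[2] for f in frames])
    lipid_vol = vols - n_waters * water_volume
    if (lipid_vol <= 0).any():
        bad = int(np.argmax(lipid_vol <= 0))
        raise ValueError(
            f"non-positive lipid volume at frame {bad}; check n_waters/water_volume"
        )
    series = lipid_vol / n_lipids
    return {
        "series": series,
        "mean": float(series.mean()),
        "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# density profiles and thickness


def _centered_z(frame: Frame, topology: Topology) -> np.ndarray:
    """z coordinates with the lipid center of mass shifted to zero."""
    lip = topology.select_role("lipid")
    z = frame.coordinates[:, 2]
    if len(lip) == 0:
        return z - z.mean()
    m = topology.masses[lip]
    return z - float(np.average(z[lip], weights=m))


def density_profile(
    frames: Sequence[Frame],
    topology: Topology,
    selection: np.ndarray,
    bin_width: float = 0.25,
    weighting: Literal["number", "electron", "electron_z"] = "number",
    z_max: float | None = None,
) -> DensityProfile:
    """Frame-averaged density along z, recentered on the lipid center of mass.

    ``weighting='number'`` counts atoms; ``'electron'`` weights each atom by
    atomic_number - partial_charge (partial charges redistribute electrons);
    ``'electron_z'`` uses the bare atomic number. Densities are per bin
    volume Lx*Ly*bin_width.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if not frames:
        raise ValueError("no frames supplied")

    if weighting == "number":
        w_atom = np.ones(len(topology))
    elif weighting == "electron":
        w_atom = topology.atomic_numbers - topology.partial_charges
    elif weighting == "electron_z":
        w_atom = topology.atomic_numbers.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    if z_max is None:
        z_max = max(f.box[2] for f in frames) / 2.0
    nbins = max(1, int(np.ceil(z_max / bin_width)))
    edges = np.linspace(-nbins * bin_width, nbins * bin_width, 2 * nbins + 1)
    acc = np.zeros(2 * nbins)
    for f in frames:
        z = _centered_z(f, topology)[selection]
        hist, _ = np.histogram(z, bins=edges, weights=w_atom[selection])
        acc += hist / (f.box[0] * f.box[1] * bin_width)
    acc /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z_centers=centers, values=acc, species=weighting, bin_width=bin_width)


def dhh_from_profile(profile: DensityProfile) -> float:
    """Head-to-head thickness: distance between the density maxima at z<0 and z>0."""
    z, v = profile.z_centers, profile.values
    interior = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])) + 1
    peaks_neg = [i for i in interior if z[i] < 0]
    peaks_pos = [i for i in interior if z[i] > 0]
    if not peaks_neg or not peaks_pos:
        raise ValueError("profile lacks two local maxima straddling z=0")
    i_neg = max(peaks_neg, key=lambda i: v[i])
    i_pos = max(peaks_pos, key=lambda i: v[i])
    # reject a single broad central hump masquerading as two peaks
    between = v[min(i_neg, i_pos): max(i_neg, i_pos) + 1]
    if between.min() >= min(v[i_neg], v[i_pos]) - 1e-15:
        raise ValueError("no trough between candidate peaks; profile is single-peaked")
    return float(z[i_pos] - z[i_neg])


# ---------------------------------------------------------------------------
# order parameters


def order_parameters(
    frames: Sequence[Frame],
    topology: Topology,
    ch_pairs: dict[int, list[tuple[int, int]]],
    chain: str = "sn-1",
) -> OrderParameterSeries:
    """C-H order parameters S_CD = <(3 cos^2 theta - 1)/2> per carbon.

    ``ch_pairs`` maps a carbon index (position along the chain) to the
    (C, H) atom-index pairs contributing to it, pooled over molecules and
    equivalent hydrogens; theta is the C-H angle to the z axis. Returns
    signed values alongside |S_CD|.
    """
    carbons = sorted(ch_pairs)
    signed = np.empty(len(carbons))
    sds = np.empty(len(carbons))
    for ci, carbon in enumerate(carbons):
        pairs = np.asarray(ch_pairs[carbon], dtype=int)
        if pairs.size == 0:
            raise ValueError(f"no C-H pairs for carbon {carbon}")
        samples = []
        for f in frames:
            vec = f.coordinates[pairs[:, 1]] - f.coordinates[pairs[:, 0]]
            norm2 = np.einsum("ij,ij->i", vec, vec)
            if (norm2 == 0).any():
                raise ValueError(f"zero-length C-H vector at carbon {carbon}")
            cos2 = vec[:, 2] ** 2 / norm2
            samples.append(1.5 * cos2 - 0.5)
        alls = np.concatenate(samples)
        signed[ci] = alls.mean()
        sds[ci] = alls.std(ddof=1) if len(alls) > 1 else 0.0
    return OrderParameterSeries(
        chain=chain,
        carbon_index=np.asarray(carbons),
        scd_signed=signed,
        scd_abs=np.abs(signed),
        scd_sd=sds,
    )


# ---------------------------------------------------------------------------
# scattering form factors


def xray_form_factor(
    profile: DensityProfile,
    q_grid: np.ndarray,
    water_density: float = WATER_ELECTRON_DENSITY,
) -> FormFactor:
    """|F(q)| = |integral (rho_e(z) - rho_water) cos(qz) dz| by trapezoid rule.

    The profile should be symmetric (or symmetrized) about z = 0, in which
    case the cosine transform is the full Fourier transform.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("q grid is empty")
    contrast = profile.values - water_density
    z = profile.z_centers
    integrand = contrast[None, :] * np.cos(q[:, None] * z[None, :])
    mag = np.abs(np.trapezoid(integrand, z, axis=1))
    return FormFactor(q=q, magnitude=mag)


def sld_profile(
    frames: Sequence[Frame],
    topology: Topology,
    d2o_fraction: float = 1.0,
    bin_width: float = 0.25,
    z_max: float | None = None,
) -> DensityProfile:
    """Neutron scattering-length density profile, fm/A^3.

    Water hydrogens take a scattering length interpolated between H and D by
    ``d2o_fraction``; lipid hydrogens are treated as non-exchangeable.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError("d2o_fraction must lie in [0, 1]")
    b = np.empty(len(topology))
    bh, bd = COHERENT_SCATTERING_LENGTHS_FM["H"], COHERENT_SCATTERING_LENGTHS_FM["D"]
    for i, (el, role) in enumerate(zip(topology.elements, topology.roles)):
        if el not in COHERENT_SCATTERING_LENGTHS_FM:
            raise ValueError(f"no coherent scattering length for element {el!r}")
        if el == "H" and role == "water":
            b[i] = (1.0 - d2o_fraction) * bh + d2o_fraction * bd
        else:
            b[i] = COHERENT_SCATTERING_LENGTHS_FM[el]

    sel = np.arange(len(topology))
    if z_max is None:
        z_max = max(f.box[2] for f in frames) / 2.0
    nbins = max(1, int(np.ceil(z_max / bin_width)))
    edges = np.linspace(-nbins * bin_width, nbins * bin_width, 2 * nbins + 1)
    acc = np.zeros(2 * nbins)
    for f in frames:
        z = _centered_z(f, topology)[sel]
        hist, _ = np.histogram(z, bins=edges, weights=b[sel])
        acc += hist / (f.box[0] * f.box[1] * bin_width)
    acc /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z_centers=centers, values=acc, species="sld", bin_width=bin_width)


def neutron_form_factor(
    profile: DensityProfile,
    q_grid: np.ndarray,
    solvent_sld: float,
) -> FormFactor:
    """Cosine transform of the SLD contrast profile, same machinery as X-ray."""
    return xray_form_factor(profile, q_grid, water_density=solvent_sld)


# ---------------------------------------------------------------------------
# sterol tilt and transit events


def cholesterol_tilt(
    frames: Sequence[Frame],
    o_indices: np.ndarray,
    c_indices: np.ndarray,
    bin_width_deg: float = 1.0,
) -> dict:
    """Tilt of the O->C sterol axis against the bilayer normal.

    The angle is taken against +z or -z, whichever is <= 90 degrees, so both
    leaflets pool into one distribution. Returns the histogram over all
    molecules and frames plus the most probable tilt (mode bin center).
    """
    o_indices = np.asarray(o_indices, dtype=int)
    c_indices = np.asarray(c_indices, dtype=int)
    if len(o_indices) != len(c_indices) or len(o_indices) == 0:
        raise ValueError("o_indices and c_indices must be non-empty and congruent")
    if bin_width_deg <= 0:
        raise ValueError("bin width must be positive")
    angles = []
    skipped = 0
    for f in frames:
        vec = f.coordinates[c_indices] - f.coordinates[o_indices]
        norm = np.linalg.norm(vec, axis=1)
        ok = norm > 0
        skipped += int((~ok).sum())
        cosang = np.abs(vec[ok, 2]) / norm[ok]
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if skipped:
        warnings.warn(f"skipped {skipped} coincident O/C atom pairs", stacklevel=2)
    allang = np.concatenate(angles) if angles else np.array([])
    if allang.size == 0:
        raise ValueError("no valid tilt vectors")
    nb = int(np.ceil(90.0 / bin_width_deg))
    edges = np.linspace(0.0, nb * bin_width_deg, nb + 1)
    hist, _ = np.histogram(allang, bins=edges)
    mode_bin = int(np.argmax(hist))
    return {
        "bin_edges": edges,
        "counts": hist,
        "mode_deg": float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
        "mean_deg": float(allang.mean()),
        "n_skipped": skipped,
    }


def transit_events(
    z_series: np.ndarray,
    molecule_id: int = 0,
    band_halfwidth: float = 2.0,
) -> list[EventRecord]:
    """Detect midplane transits: maximal runs with |z| < band_halfwidth.

    Each run is one event; it is a flip_flop when the leaflet sign after the
    run differs from before, otherwise a transient_visit. Runs touching the
    series boundary cannot be classified and count as transient visits.
    """
    z = np.asarray(z_series, dtype=float)
    if z.size == 0:
        raise ValueError("empty z series")
    inband = np.abs(z) < band_halfwidth
    events: list[EventRecord] = []
    i = 0
    n = len(z)
    while i < n:
        if not inband[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inband[j + 1]:
            j += 1
        if i == 0 or j == n - 1:
            before = int(np.sign(z[i - 1])) if i > 0 else (int(np.sign(z[j + 1])) if j + 1 < n else 0)
            kind = "transient_visit"  # unresolved boundary run
        else:
            before = int(np.sign(z[i - 1]))
            after = int(np.sign(z[j + 1]))
            kind = "flip_flop" if after != before else "transient_visit"
        events.append(
            EventRecord(molecule_id=molecule_id, start=i, end=j, kind=kind, start_leaflet=before)
        )
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# melting point


def melting_point(
    time: np.ndarray,
    temperature: np.ndarray,
    lx: np.ndarray,
    ly: np.ndarray,
    n_lipids: int,
    window: float,
) -> dict:
    """Phase-transition temperature from a heating-scan area-per-lipid curve.

    APL(t) is smoothed with a centered running average spanning ``window``
    (same time units as ``time``), mapped onto temperature, and centrally
    differenced over a window-wide stencil; the maximum of dAPL/dT marks the
    sigmoid inflection, i.e. the transition.
    """
    t = np.asarray(time, dtype=float)
    T = np.asarray(temperature, dtype=float)
    lx = np.asarray(lx, dtype=float)
    ly = np.asarray(ly, dtype=float)
    if not (len(t) == len(T) == len(lx) == len(ly)):
        raise ValueError("time/temperature/Lx/Ly must have equal lengths")
    if (np.diff(T) < 0).any():
        raise ValueError("temperature must be monotone non-decreasing")
    if n_lipids <= 0 or n_lipids % 2:
        raise ValueError("n_lipids must be a positive even number")
    dt = np.diff(t)
    if len(dt) == 0 or (dt <= 0).any():
        raise ValueError("time must be strictly increasing")
    step = float(np.median(dt))
    half = max(1, int(round(window / step / 2)))
    if 2 * half + 1 > len(t):
        raise ValueError("window longer than the scan")

    apl = lx * ly / (n_lipids / 2)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    sm = np.convolve(apl, kernel, mode="valid")
    Ts = np.convolve(T, kernel, mode="valid")

    # derivative over a window-wide stencil: adjacent-sample differences of
    # window-averaged noise would swamp the signal
    lag = max(1, half)
    dA = sm[2 * lag:] - sm[:-2 * lag]
    dT = Ts[2 * lag:] - Ts[:-2 * lag]
    if (dT <= 0).any():
        raise ValueError("temperature plateau wider than the derivative stencil")
    deriv = dA / dT
    Tm_grid = Ts[lag:-lag]
    spread = float(deriv.max() - deriv.min())
    scale = max(abs(float(deriv.max())), abs(float(deriv.min())), 1e-30)
    if spread <= 1e-6 * scale:
        raise ValueError("no distinct inflection: dAPL/dT is constant over the scan")
    k = int(np.argmax(deriv))
    return {
        "tm": float(Tm_grid[k]),
        "temperature_grid": Tm_grid,
        "dapl_dt": deriv,
        "apl_smoothed": sm,
        "temperature_smoothed": Ts,
    }
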