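import math

import numpy as np
import pytest

from lipidff.fixtures import make_bilayer_traj, make_heating_scan, make_z_paths
from lipidff.membrane import (
    DensityProfile,
    Frame,
    Topology,
    area_per_lipid,
    cholesterol_tilt,
    density_profile,
    dhh_from_profile,
    melting_point,
    neutron_form_factor,
    order_parameters,
    sld_profile,
    transit_events,
    volume_per_lipid,
    xray_form_factor,
)


def _tiny_topology(n, role="lipid", element="C", z=6, charge=0.0):
    return Topology(
        names=[f"X{i}" for i in range(n)],
        elements=[element] * n,
        atomic_numbers=[z] * n,
        partial_charges=[charge] * n,
        residue_ids=list(range(n)),
        residue_names=["LIP"] * n,
        roles=[role] * n,
    )


def _frame(coords, box=(10.0, 10.0, 40.0)):
    return Frame(coordinates=np.asarray(coords, dtype=float), box=box)


class TestAreaVolume:
    def test_apl_64_box(self):
        frames = [_frame(np.zeros((1, 3)), box=(64.0, 64.0, 80.0))] * 3
        res = area_per_lipid(frames, 128)
        assert res["mean"] == 64.0
        assert np.all(res["series"] == 64.0)

    def test_apl_rectangular(self):
        frames = [_frame(np.zeros((1, 3)), box=(60.0, 70.0, 80.0))]
        assert area_per_lipid(frames, 128)["mean"] == pytest.approx(65.625)

    def test_apl_odd_lipids_rejected(self):
        with pytest.raises(ValueError):
            area_per_lipid([_frame(np.zeros((1, 3)))], 127)

    def test_apl_fluctuating_statistics_oracle(self):
        rng = np.random.default_rng(5)
        sides = rng.uniform(60, 68, size=(50, 2))
        frames = [_frame(np.zeros((1, 3)), box=(a, b, 80.0)) for a, b in sides]
        res = area_per_lipid(frames, 128)
        vals = sides[:, 0] * sides[:, 1] / 64.0
        # independent two-pass mean/sd
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        assert res["mean"] == pytest.approx(mean, abs=1e-12)
        assert res["sd"] == pytest.approx(sd, abs=1e-12)

    def test_vpl_arithmetic(self):
        frames = [_frame(np.zeros((1, 3)), box=(50.0, 50.0, 80.0))]  # 200000 A^3
        res = volume_per_lipid(frames, 5120, 30.0, 128)
        assert res["mean"] == pytest.approx(362.5)

    def test_vpl_zero_waters_limit(self):
        frames = [_frame(np.zeros((1, 3)), box=(50.0, 50.0, 80.0))]
        assert volume_per_lipid(frames, 0, 30.0, 128)["mean"] == pytest.approx(200000.0 / 128)

    def test_vpl_negative_volume_rejected(self):
        frames = [_frame(np.zeros((1, 3)), box=(10.0, 10.0, 10.0))]
        with pytest.raises(ValueError, match="water"):
            volume_per_lipid(frames, 5120, 30.0, 128)

    def test_vpl_random_series_oracle(self):
        rng = np.random.default_rng(9)
        boxes = rng.uniform(55, 65, size=(20, 3))
        frames = [_frame(np.zeros((1, 3)), box=tuple(b)) for b in boxes]
        res = volume_per_lipid(frames, 100, 30.0, 64)
        expected = (boxes.prod(axis=1) - 3000.0) / 64
        assert res["mean"] == pytest.approx(expected.mean(), rel=1e-12)


class TestDensityProfile:
    def test_single_atom_electron_weight(self):
        top = _tiny_topology(1, z=6, charge=-0.1)
        f = _frame([[5.0, 5.0, 3.1]], box=(10.0, 20.0, 40.0))
        prof = density_profile([f], top, np.array([0]), bin_width=0.5, weighting="electron")
        nz = np.flatnonzero(prof.values)
        assert len(nz) == 1
        assert prof.values[nz[0]] == pytest.approx(6.1 / (10.0 * 20.0 * 0.5))
        # lipid COM recentering: the single lipid atom sits at z = 0
        assert abs(prof.z_centers[nz[0]]) < 0.5

    def test_symmetric_bilayer_profile(self):
        frames, top, _, _ = make_bilayer_traj(n_lipids=128, n_frames=4, seed=2)
        prof = density_profile(frames, top, top.select_role("lipid"), bin_width=1.0,
                               weighting="electron")
        sym = prof.symmetrized()
        # mirror asymmetry is small relative to the peak
        assert np.max(np.abs(prof.values - sym.values)) < 0.35 * prof.values.max()

    def test_histogram_oracle(self):
        rng = np.random.default_rng(11)
        n = 200
        top = _tiny_topology(n, z=7, charge=0.2)
        coords = np.column_stack([rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                                  rng.uniform(-15, 15, n)])
        f = _frame(coords, box=(10.0, 10.0, 40.0))
        bw = 0.25
        prof = density_profile([f], top, np.arange(n), bin_width=bw, weighting="electron")
        zc = coords[:, 2] - np.average(coords[:, 2])  # equal masses -> plain mean
        oracle = np.zeros_like(prof.values)
        edges = np.concatenate([prof.z_centers - bw / 2, [prof.z_centers[-1] + bw / 2]])
        for z in zc:
            k = np.searchsorted(edges, z, side="right") - 1
            oracle[k] += (7 - 0.2) / (10.0 * 10.0 * bw)
        np.testing.assert_allclose(prof.values, oracle, atol=1e-12)

    def test_number_density_integrates_to_count(self):
        frames, top, _, _ = make_bilayer_traj(n_lipids=32, n_frames=3, seed=7)
        sel = top.select_role("lipid")
        prof = density_profile(frames, top, sel, weighting="number")
        total = prof.values.sum() * prof.bin_width * frames[0].box[0] * frames[0].box[1]
        assert total == pytest.approx(len(sel), rel=1e-6)

    def test_bad_inputs(self):
        top = _tiny_topology(1)
        f = _frame([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            density_profile([f], top, np.array([]), weighting="number")
        with pytest.raises(ValueError):
            density_profile([f], top, np.array([0]), bin_width=0.0)


class TestDhh:
    def _two_gauss(self, c1, c2, sigma=1.5, bw=0.25, noise=0.0, seed=0):
        z = np.arange(-30, 30 + bw / 2, bw)
        v = np.exp(-((z - c1) ** 2) / (2 * sigma**2)) + np.exp(-((z - c2) ** 2) / (2 * sigma**2))
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, len(z))
            v = np.clip(v, 0, None)
        return DensityProfile(z_centers=z, values=v, bin_width=bw)

    def test_symmetric_peaks(self):
        assert dhh_from_profile(self._two_gauss(-19.0, 19.0)) == pytest.approx(38.0, abs=0.25)

    def test_asymmetric_peaks(self):
        assert dhh_from_profile(self._two_gauss(-18.5, 20.5)) == pytest.approx(39.0, abs=0.25)

    def test_noisy_within_one_bin(self):
        clean = dhh_from_profile(self._two_gauss(-19.0, 19.0))
        noisy = dhh_from_profile(self._two_gauss(-19.0, 19.0, noise=0.02, seed=3))
        assert abs(noisy - clean) <= 0.25 + 1e-12

    def test_single_peak_rejected(self):
        z = np.arange(-30, 30.01, 0.25)
        prof = DensityProfile(z_centers=z, values=np.exp(-(z**2) / 50.0), bin_width=0.25)
        with pytest.raises(ValueError):
            dhh_from_profile(prof)

    def test_monotone_rejected(self):
        z = np.arange(-30, 30.01, 0.25)
        prof = DensityProfile(z_centers=z, values=np.linspace(0, 1, len(z)), bin_width=0.25)
        with pytest.raises(ValueError):
            dhh_from_profile(prof)


class TestOrderParameters:
    def _frames_with_orientation(self, vec, n=50):
        # C at origin-ish, H displaced by vec; one pair per "molecule"
        coords = []
        for i in range(n):
            coords.append([float(i), 0.0, 0.0])
            coords.append([float(i) + vec[0], vec[1], vec[2]])
        top = _tiny_topology(2 * n)
        pairs = {2: [(2 * i, 2 * i + 1) for i in range(n)]}
        return [_frame(coords, box=(100.0, 100.0, 100.0))], top, pairs

    def test_axial_limit(self):
        frames, top, pairs = self._frames_with_orientation([0.0, 0.0, 1.09])
        s = order_parameters(frames, top, pairs)
        assert s.scd_abs[0] == pytest.approx(1.0, abs=1e-12)

    def test_planar_limit(self):
        frames, top, pairs = self._frames_with_orientation([1.09, 0.0, 0.0])
        s = order_parameters(frames, top, pairs)
        assert s.scd_signed[0] == pytest.approx(-0.5, abs=1e-12)
        assert s.scd_abs[0] == pytest.approx(0.5, abs=1e-12)

    def test_isotropic_limit(self):
        rng = np.random.default_rng(123)
        n = 100_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        coords = np.zeros((2 * n, 3))
        coords[1::2] = u
        top = _tiny_topology(2 * n)
        pairs = {2: [(2 * i, 2 * i + 1) for i in range(n)]}
        s = order_parameters([_frame(coords, box=(10, 10, 10))], top, pairs)
        assert s.scd_abs[0] <= 0.01

    def test_rotation_about_z_invariance(self):
        frames, top, pairs = self._frames_with_orientation([0.7, 0.2, 0.69])
        base = order_parameters(frames, top, pairs).scd_signed[0]
        a = np.radians(73.0)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rot = [_frame(frames[0].coordinates @ R.T, box=frames[0].box)]
        assert order_parameters(rot, top, pairs).scd_signed[0] == pytest.approx(base, abs=1e-12)

    def test_zero_length_vector_rejected(self):
        frames, top, pairs = self._frames_with_orientation([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            order_parameters(frames, top, pairs)


class TestFormFactors:
    Q = np.arange(0.0, 0.8001, 0.005)

    def test_zero_contrast_zero_everywhere(self):
        z = np.arange(-40, 40.01, 0.1)
        prof = DensityProfile(z_centers=z, values=np.full_like(z, 0.333), bin_width=0.1)
        ff = xray_form_factor(prof, self.Q, water_density=0.333)
        assert np.all(ff.magnitude == 0.0)

    def test_gaussian_closed_form(self):
        z = np.arange(-40, 40.0001, 0.1)
        A, sg = 0.1, 3.0
        prof = DensityProfile(z_centers=z, values=0.333 + A * np.exp(-(z**2) / (2 * sg**2)),
                              bin_width=0.1)
        ff = xray_form_factor(prof, self.Q, water_density=0.333)
        analytic = A * sg * math.sqrt(2 * math.pi) * np.exp(-(self.Q**2) * sg**2 / 2)
        assert np.max(np.abs(ff.magnitude - analytic)) <= 0.005 * analytic.max()

    def test_f0_is_contrast_integral(self):
        rng = np.random.default_rng(2)
        z = np.arange(-30, 30.01, 0.25)
        v = 0.333 + np.abs(rng.normal(0, 0.05, len(z)))
        prof = DensityProfile(z_centers=z, values=v, bin_width=0.25)
        ff = xray_form_factor(prof, np.array([0.0]), water_density=0.333)
        assert ff.magnitude[0] == pytest.approx(abs(np.trapezoid(v - 0.333, z)), rel=1e-12)

    def test_linearity_in_contrast(self):
        z = np.arange(-30, 30.01, 0.25)
        bump = 0.05 * np.exp(-(z**2) / 18.0)
        p1 = DensityProfile(z_centers=z, values=0.333 + bump, bin_width=0.25)
        p2 = DensityProfile(z_centers=z, values=0.333 + 2 * bump, bin_width=0.25)
        f1 = xray_form_factor(p1, self.Q, 0.333)
        f2 = xray_form_factor(p2, self.Q, 0.333)
        np.testing.assert_allclose(f2.magnitude, 2 * f1.magnitude, atol=1e-12)

    def test_boxcar_closed_form(self):
        z = np.arange(-40, 40.0001, 0.02)
        w, drho, solvent = 30.0, 0.08, 0.2
        v = np.where(np.abs(z) <= w / 2, solvent + drho, solvent)
        prof = DensityProfile(z_centers=z, values=v, bin_width=0.02)
        q = self.Q[1:]  # closed form 2*drho*sin(qw/2)/q undefined at q=0
        ff = neutron_form_factor(prof, q, solvent_sld=solvent)
        analytic = np.abs(2 * drho * np.sin(q * w / 2) / q)
        assert np.max(np.abs(ff.magnitude - analytic)) <= 0.005 * analytic.max()

    def test_empty_q_rejected(self):
        z = np.arange(-10, 10.01, 0.25)
        prof = DensityProfile(z_centers=z, values=np.zeros_like(z), bin_width=0.25)
        with pytest.raises(ValueError):
            xray_form_factor(prof, np.array([]))


class TestSldProfile:
    def test_d2o_fraction_only_touches_water_hydrogens(self):
        # pure-lipid system: profile independent of the D2O fraction
        frames, top, _, _ = make_bilayer_traj(n_lipids=16, n_frames=2, seed=5)
        p0 = sld_profile(frames, top, d2o_fraction=0.0, bin_width=1.0)
        p1 = sld_profile(frames, top, d2o_fraction=1.0, bin_width=1.0)
        np.testing.assert_allclose(p0.values, p1.values, atol=1e-15)

    def test_unknown_element_named(self):
        top = Topology(
            names=["U1"], elements=["Xx"], atomic_numbers=[54], partial_charges=[0.0],
            residue_ids=[1], residue_names=["UNK"], roles=["lipid"],
        )
        with pytest.raises(ValueError, match="Xx"):
            sld_profile([_frame([[0.0, 0.0, 0.0]])], top)

    def test_bad_fraction(self):
        frames, top, _, _ = make_bilayer_traj(n_lipids=4, n_frames=1, seed=5)
        with pytest.raises(ValueError):
            sld_profile(frames, top, d2o_fraction=1.5)


class TestCholesterolTilt:
    def _probe_frames(self, tilt_deg, n=40):
        coords = np.zeros((2 * n, 3))
        t = math.radians(tilt_deg)
        for i in range(n):
            coords[2 * i] = [i, 0.0, 10.0]
            coords[2 * i + 1] = [i + 8 * math.sin(t), 0.0, 10.0 - 8 * math.cos(t)]
        o_idx = np.arange(0, 2 * n, 2)
        c_idx = np.arange(1, 2 * n, 2)
        return [_frame(coords, box=(100, 100, 60))], o_idx, c_idx

    def test_zero_tilt(self):
        frames, o, c = self._probe_frames(0.0)
        res = cholesterol_tilt(frames, o, c)
        assert res["bin_edges"][np.argmax(res["counts"])] == 0.0

    def test_13_degrees(self):
        frames, o, c = self._probe_frames(13.0)
        res = cholesterol_tilt(frames, o, c)
        k = int(np.argmax(res["counts"]))
        assert res["bin_edges"][k] <= 13.0 <= res["bin_edges"][k + 1]

    def test_leaflet_independence(self):
        # mirrored probe (lower leaflet) must give the same angle
        frames, o, c = self._probe_frames(25.0)
        flipped = frames[0].coordinates.copy()
        flipped[:, 2] *= -1
        res_up = cholesterol_tilt(frames, o, c)
        res_dn = cholesterol_tilt([_frame(flipped, box=(100, 100, 60))], o, c)
        assert res_up["mode_deg"] == res_dn["mode_deg"]

    def test_wrapped_normal_mode(self):
        rng = np.random.default_rng(31)
        n = 4000
        tilts = rng.normal(20.0, 2.0, n)
        coords = np.zeros((2 * n, 3))
        for i, td in enumerate(tilts):
            t = math.radians(abs(td))
            coords[2 * i] = [0.0, 0.0, 10.0]
            coords[2 * i + 1] = [8 * math.sin(t), 0.0, 10.0 - 8 * math.cos(t)]
        res = cholesterol_tilt([_frame(coords, box=(50, 50, 60))],
                               np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2))
        assert abs(res["mode_deg"] - 20.0) <= 1.0

    def test_coincident_atoms_skipped_with_warning(self):
        coords = np.zeros((2, 3))
        coords[:] = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
        good = np.array([[0, 0, 10], [0, 0, 2.0]])
        f = _frame(np.vstack([coords, good]), box=(50, 50, 60))
        with pytest.warns(UserWarning, match="coincident"):
            res = cholesterol_tilt([f], np.array([0, 2]), np.array([1, 3]))
        assert res["n_skipped"] == 1


class TestTransitEvents:
    def test_never_enters_band(self):
        assert transit_events(np.full(100, 15.0)) == []

    def test_single_crossing_flip_flop(self):
        ev = transit_events(np.array([15.0, 1.0, -15.0]))
        assert len(ev) == 1
        assert ev[0].kind == "flip_flop"
        assert ev[0].start_leaflet == 1

    def test_hand_traced_three_events(self):
        z = np.array([15, 14, 1.0, -0.5, -14, -15, -1.5, -13, -15, 0.5, 13, 15.0])
        # visits: frames 2-3 (flip), frame 6 (transient), frame 9 (flip)
        ev = transit_events(z)
        assert [(e.start, e.end, e.kind) for e in ev] == [
            (2, 3, "flip_flop"),
            (6, 6, "transient_visit"),
            (9, 9, "flip_flop"),
        ]

    def test_boundary_runs_are_transient(self):
        ev = transit_events(np.array([1.0, 15.0, 14.0]))
        assert ev[0].kind == "transient_visit"
        ev = transit_events(np.array([15.0, 14.0, 1.0]))
        assert ev[0].kind == "transient_visit"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            transit_events(np.array([]))

    def test_subsampling_preserving_visits(self):
        z, truth, _ = make_z_paths(["cross", "return"], plateau_frames=20, seed=1)
        base = transit_events(z)
        sub = transit_events(z[::2])
        assert len(base) == len(truth) == len(sub)
        assert [e.kind for e in base] == [e.kind for e in sub]

    def test_subsampling_that_skips_a_visit_changes_count(self):
        z = np.array([15.0, 1.0, 15.0, 15.0])  # 1-frame visit lost at stride 2
        assert len(transit_events(z)) == 1
        assert len(transit_events(z[::2])) == 0


class TestMeltingPoint:
    def _run(self, midpoint, noise=0.0, seed=0, window=1.0):
        series, _ = make_heating_scan(midpoint=midpoint, noise_sigma=noise, seed=seed)
        return melting_point(series["time"], series["temperature"], series["lx"],
                             series["ly"], 128, window=window)

    def test_noiseless_logistic_319(self):
        assert self._run(319.0)["tm"] == pytest.approx(319.0, abs=0.05 + 1e-9)

    def test_noiseless_logistic_335(self):
        assert self._run(335.0)["tm"] == pytest.approx(335.0, abs=0.05 + 1e-9)

    def test_linear_apl_rejected(self):
        t = np.arange(0.0, 100.01, 0.1)
        temp = 300.0 + 0.5 * t
        apl = 50.0 + 0.1 * temp
        side = np.sqrt(apl * 64)
        with pytest.raises(ValueError, match="inflection"):
            melting_point(t, temp, side, side, 128, window=1.0)

    def test_noisy_recovery_within_2k(self):
        r = self._run(327.0, noise=0.5, seed=4)
        assert abs(r["tm"] - 327.0) <= 2.0

    def test_ten_seed_median_error(self):
        errs = [abs(self._run(331.4, noise=0.5, seed=s)["tm"] - 331.4) for s in range(10)]
        assert float(np.median(errs)) <= 1.0

    def test_non_monotone_temperature_rejected(self):
        t = np.arange(0.0, 10.01, 0.1)
        temp = 300.0 + np.sin(t)
        side = np.full_like(t, 60.0)
        with pytest.raises(ValueError, match="monotone"):
            melting_point(t, temp, side, side, 128, window=1.0)
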