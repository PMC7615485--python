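"""Trajectory I/O, density profiles, interface metrics and RMSF."""

import math

import numpy as np
import pytest

from oxafoul import membrane_analysis as ma
from oxafoul import synthetic_data as sd


@pytest.fixture(scope="module")
def default_slab():
    cfg = sd.MembraneSimConfig(seed=1)
    traj, truth = sd.generate_membrane_trajectory(cfg)
    profile = ma.density_profile(traj)
    return cfg, traj, truth, profile


def tiny_trajectory(n_frames=2, n_atoms=10, box=(3.0, 3.0, 9.0), seed=0):
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0, 1, (n_frames, n_atoms, 3)) * np.asarray(box)
    labels = np.array(["PDMS"] * 4 + ["PMOXA"] * 3 + ["WATER"] * 3)[:n_atoms]
    masses = np.array([ma.DEFAULT_COMPONENT_MASSES[lab] for lab in labels])
    return ma.Trajectory(frames=frames, labels=labels, masses=masses, box=np.asarray(box))


class TestTrajectoryIO:
    @pytest.mark.parametrize("fmt", ["xyz", "gro"])
    def test_write_read_roundtrip(self, tmp_path, fmt):
        traj = tiny_trajectory()
        path = tmp_path / f"t.{fmt}"
        if fmt == "xyz":
            ma.write_xyz(traj, path)
            back = ma.read_trajectory(path, box_nm=(3.0, 3.0, 9.0))
        else:
            ma.write_gro(traj, path)
            back = ma.read_trajectory(path)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        np.testing.assert_array_equal(back.labels, traj.labels)
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)
        if fmt == "gro":
            np.testing.assert_allclose(back.box, traj.box)

    def test_gro_residue_names_map_to_components(self, tmp_path):
        lines = ["water box", "2"]
        lines.append("    1SOL     OW    1   1.000   1.000   1.000")
        lines.append("    2SOL     OW    2   2.000   2.000   2.000")
        lines.append("   3.00000   3.00000   3.00000")
        path = tmp_path / "w.gro"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="PDMS"):
            # parses fine, but a water-only slab cannot be PDMS-centred
            ma.density_profile(ma.read_trajectory(path))
        traj = ma.read_trajectory(path)
        assert set(traj.labels) == {"WATER"}

    def test_truncated_frame_names_frame_index(self, tmp_path):
        content = "3\nframe 0\nPDMS 0 0 0\nPDMS 1 1 1\nPMOXA 2 2 2\n3\nframe 1\nPDMS 0 0 0\n"
        path = tmp_path / "t.xyz"
        path.write_text(content)
        with pytest.raises(ValueError, match="frame 1"):
            ma.read_trajectory(path, box_nm=(3, 3, 3))

    def test_unmapped_names_listed(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("1\nframe\nUNOBTANIUM 0 0 0\n")
        with pytest.raises(ValueError, match="UNOBTANIUM"):
            ma.read_trajectory(path, box_nm=(3, 3, 3))

    def test_xyz_without_box_rejected(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text("1\nframe\nPDMS 0 0 0\n")
        with pytest.raises(ValueError, match="box"):
            ma.read_trajectory(path)


class TestDensityProfile:
    def test_uniform_water_is_flat_at_imposed_density(self):
        rng = np.random.default_rng(0)
        box = (6.0, 6.0, 6.0)
        n = 40_000
        frames = rng.uniform(0, 1, (1, n, 3)) * np.asarray(box)
        traj = ma.Trajectory(
            frames=frames,
            labels=np.array(["WATER"] * n),
            masses=np.full(n, 18.015),
            box=np.asarray(box),
        )
        profile = ma.density_profile(traj, bin_width_nm=0.5, center="midplane")
        imposed = n * 18.015 * ma.AMU_PER_NM3_TO_KG_M3 / (6.0**3)
        total = profile.total_water()
        assert np.all(np.abs(total / imposed - 1.0) < 0.05)

    def test_mass_conservation_per_component(self, default_slab):
        cfg, traj, truth, profile = default_slab
        lateral_area = cfg.box_nm[0] * cfg.box_nm[1]
        bin_vol = profile.bin_width_nm * lateral_area
        for comp, mask in [
            ("PDMS", traj.labels == "PDMS"),
            ("PMOXA", traj.labels == "PMOXA"),
        ]:
            total_mass_amu = traj.masses[mask].sum()
            histogram_mass = profile.rho[comp].sum() * bin_vol / ma.AMU_PER_NM3_TO_KG_M3
            assert histogram_mass == pytest.approx(total_mass_amu, rel=1e-9)
        water_mass = traj.masses[traj.labels == "WATER"].sum()
        hist_water = profile.total_water().sum() * bin_vol / ma.AMU_PER_NM3_TO_KG_M3
        assert hist_water == pytest.approx(water_mass, rel=1e-9)

    def test_plateau_densities_recover_generator_truth(self, default_slab):
        cfg, traj, truth, profile = default_slab
        z = np.abs(profile.z_centers_nm)
        core = z < 0.8 * cfg.core_half_width_nm
        assert profile.rho["PDMS"][core].mean() == pytest.approx(
            truth.core_density_kg_m3, rel=0.05
        )
        b0, b1 = truth.brush_plateau_z_nm
        brush = (z > b0 + 0.3) & (z < b1 - 0.3)
        assert profile.rho["PMOXA"][brush].mean() == pytest.approx(
            truth.brush_plateau_density_kg_m3, rel=0.05
        )
        w0, w1 = truth.bulk_water_z_nm
        bulk = (z > w0 + 0.4) & (z < w1 - 0.4)
        assert profile.rho["WATER_BULK"][bulk].mean() == pytest.approx(
            truth.water_density_kg_m3, rel=0.05
        )

    def test_water_split_sums_to_total_binwise(self, default_slab):
        _, traj, _, profile = default_slab
        recomputed = ma.density_profile(traj, interfacial_cutoff_nm=1e-9)
        # with a vanishing cutoff everything is bulk; totals must agree bin-wise
        total_a = profile.rho["WATER_INT"] + profile.rho["WATER_BULK"]
        total_b = recomputed.rho["WATER_INT"] + recomputed.rho["WATER_BULK"]
        np.testing.assert_allclose(total_a, total_b, rtol=1e-9, atol=1e-9)

    def test_profile_mirror_symmetry(self, default_slab):
        _, _, _, profile = default_slab
        for comp in ("PDMS", "PMOXA", "WATER_INT"):
            rho = profile.rho[comp]
            asym = np.abs(rho - rho[::-1]).sum() / max(rho.sum(), 1e-12)
            assert asym < 0.05

    def test_no_pdms_cannot_center(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 3, (1, 50, 3))
        traj = ma.Trajectory(
            frames=frames,
            labels=np.array(["WATER"] * 50),
            masses=np.full(50, 18.015),
            box=np.array([3.0, 3.0, 3.0]),
        )
        with pytest.raises(ValueError, match="PDMS"):
            ma.density_profile(traj)


class TestMembraneThickness:
    def test_recovers_generator_core_width(self, default_slab):
        cfg, _, truth, profile = default_slab
        assert ma.membrane_thickness(profile) == pytest.approx(
            truth.membrane_thickness_nm, abs=0.1
        )

    def test_scaling_with_coordinates(self, default_slab):
        cfg, traj, truth, _ = default_slab
        doubled = ma.Trajectory(
            frames=traj.frames * 2.0,
            labels=traj.labels,
            masses=traj.masses,
            box=traj.box * 2.0,
        )
        profile = ma.density_profile(doubled, bin_width_nm=0.2)
        assert ma.membrane_thickness(profile) == pytest.approx(
            2.0 * truth.membrane_thickness_nm, abs=0.2
        )

    def test_symmetric_crossings(self, default_slab):
        _, _, _, profile = default_slab
        thickness = ma.membrane_thickness(profile)
        # symmetric slab: the two half-max crossings sit at +/- thickness/2
        z = profile.z_centers_nm
        rho = profile.rho["PDMS"]
        plateau = np.median(rho[rho >= 0.8 * rho.max()])
        above = z[rho > plateau / 2]
        mid = 0.5 * (above.min() + above.max())
        assert abs(mid) < profile.bin_width_nm

    def test_all_water_has_no_thickness(self):
        z = np.linspace(-5, 5, 101)
        profile = ma.DensityProfile(
            z_centers_nm=z,
            rho={"PDMS": np.zeros_like(z), "PMOXA": np.zeros_like(z),
                 "WATER_INT": np.ones_like(z), "WATER_BULK": np.ones_like(z)},
            rho_sd={},
            bin_width_nm=0.1,
        )
        with pytest.raises(ValueError):
            ma.membrane_thickness(profile)


def constructed_profile(fwhm=1.2, crossover=3.0):
    """Analytic profile with a triangular interfacial peak of known FWHM and
    PMOXA/bulk-water lines crossing at |z| = crossover."""
    z = np.linspace(-6, 6, 241)
    az = np.abs(z)
    pdms = np.where(az < 1.5, 960.0, 0.0)
    # PMOXA falls linearly from 600 at the core edge to 0 at z = 4.5
    pmoxa = np.clip(600.0 * (4.5 - az) / 3.0, 0.0, 600.0) * (az >= 1.5)
    # bulk water rises linearly, crossing the PMOXA line at the prescribed |z|
    pmoxa_at_cross = 600.0 * (4.5 - crossover) / 3.0
    bulk = np.clip(pmoxa_at_cross * (az - 1.5) / (crossover - 1.5), 0.0, 1000.0)
    bulk = np.minimum(bulk, 1000.0)
    # triangular interfacial peak centred at 2.5, base half-width = fwhm
    peak_c, half_base = 2.5, fwhm
    interfacial = np.clip(800.0 * (1.0 - np.abs(az - peak_c) / half_base), 0.0, None)
    return ma.DensityProfile(
        z_centers_nm=z,
        rho={"PDMS": pdms, "PMOXA": pmoxa, "WATER_INT": interfacial, "WATER_BULK": bulk},
        rho_sd={},
        bin_width_nm=float(z[1] - z[0]),
    )


class TestInterfaceMetrics:
    def test_triangular_peak_fwhm(self):
        profile = constructed_profile(fwhm=1.2)
        metrics = ma.interface_metrics(profile, per_frame_uncertainty=False)
        assert metrics.water_layer_thickness_nm == pytest.approx(
            1.2, abs=profile.bin_width_nm
        )

    def test_constructed_crossover_height(self):
        profile = constructed_profile(crossover=3.0)
        metrics = ma.interface_metrics(profile, per_frame_uncertainty=False)
        assert metrics.crossover_found
        assert metrics.crossover_height_nm == pytest.approx(
            3.0, abs=profile.bin_width_nm
        )

    def test_zero_interfacial_water_gives_zero_auc_and_thickness(self):
        profile = constructed_profile()
        profile.rho["WATER_INT"][:] = 0.0
        metrics = ma.interface_metrics(profile, per_frame_uncertainty=False)
        assert metrics.interfacial_auc_kg_m3_nm == 0.0
        assert metrics.water_layer_thickness_nm == 0.0

    def test_auc_matches_trapezoid_oracle(self):
        profile = constructed_profile()
        metrics = ma.interface_metrics(profile, per_frame_uncertainty=False)
        z = profile.z_centers_nm
        right = z >= 0
        expected = np.trapezoid(profile.rho["WATER_INT"][right], z[right])
        assert metrics.interfacial_auc_kg_m3_nm == pytest.approx(expected, rel=0.02)

    def test_leaflets_average_to_reported_value(self, default_slab):
        _, _, _, profile = default_slab
        metrics = ma.interface_metrics(profile, per_frame_uncertainty=False)
        for key in ("water_layer_thickness_nm", "crossover_height_nm"):
            pair = metrics.per_leaflet[key]
            assert getattr(metrics, key) == pytest.approx(float(np.mean(pair)))


class TestBrushExtentTrend:
    def test_longer_brush_thickens_water_layer_and_raises_crossover(self):
        """Hydration signature of longer hydrophilic chains: the interfacial
        water layer and its cross-over height both grow with brush extent."""
        wl, cross = [], []
        for ext in (1.0, 2.0, 3.0):
            cfg = sd.MembraneSimConfig(brush_extent_nm=ext, box_nm=(5, 5, 18), seed=2)
            traj, _ = sd.generate_membrane_trajectory(cfg)
            metrics = ma.interface_metrics(
                ma.density_profile(traj), per_frame_uncertainty=False
            )
            wl.append(metrics.water_layer_thickness_nm)
            cross.append(metrics.crossover_height_nm)
        assert wl[0] < wl[1] < wl[2]
        assert cross[0] < cross[1] < cross[2]


class TestRmsf:
    def test_frozen_trajectory_has_zero_rmsf(self):
        cfg = sd.MembraneSimConfig(
            n_frames=3,
            fluct_sigma_nm={"PDMS": 0.0, "PMOXA": 0.0, "WATER": 0.0},
            seed=4,
        )
        traj, _ = sd.generate_membrane_trajectory(cfg)
        assert ma.rmsf(traj, "PMOXA").mean_over_selection_nm < 1e-12

    def test_iid_gaussian_closed_form(self):
        sigma, n_frames = 0.08, 400
        cfg = sd.MembraneSimConfig(
            n_frames=n_frames,
            fluct_sigma_nm={"PDMS": sigma, "PMOXA": sigma, "WATER": sigma},
            seed=4,
        )
        traj, _ = sd.generate_membrane_trajectory(cfg)
        result = ma.rmsf(traj, "PMOXA")
        expected = sigma * math.sqrt(3.0) * math.sqrt((n_frames - 1) / n_frames)
        assert result.mean_over_selection_nm == pytest.approx(expected, rel=0.03)

    def test_rigid_translation_removed_by_alignment(self):
        traj = tiny_trajectory(n_frames=1, n_atoms=10)
        base = traj.frames[0]
        shifts = np.array([[0.0, 0.0, 0.0], [0.3, -0.2, 0.1], [-0.1, 0.4, -0.3]])
        frames = base[None] + shifts[:, None, :]
        moved = ma.Trajectory(
            frames=frames, labels=traj.labels, masses=traj.masses, box=traj.box[0]
        )
        assert ma.rmsf(moved, "PMOXA").mean_over_selection_nm < 1e-12

    def test_frame_order_irrelevant(self):
        cfg = sd.MembraneSimConfig(n_frames=10, seed=6)
        traj, _ = sd.generate_membrane_trajectory(cfg)
        shuffled = ma.Trajectory(
            frames=traj.frames[::-1].copy(),
            labels=traj.labels,
            masses=traj.masses,
            box=traj.box,
        )
        a = ma.rmsf(traj, "PMOXA").mean_over_selection_nm
        b = ma.rmsf(shuffled, "PMOXA").mean_over_selection_nm
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_frame_rejected(self):
        cfg = sd.MembraneSimConfig(n_frames=1, seed=0)
        traj, _ = sd.generate_membrane_trajectory(cfg)
        with pytest.raises(ValueError):
            ma.rmsf(traj, "PMOXA")


class TestGeneratorContract:
    def test_bit_reproducible(self):
        a, _ = sd.generate_membrane_trajectory(sd.MembraneSimConfig(seed=9, n_frames=3))
        b, _ = sd.generate_membrane_trajectory(sd.MembraneSimConfig(seed=9, n_frames=3))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_ou_fluctuations_keep_stationary_sd(self):
        sigma = 0.08
        cfg = sd.MembraneSimConfig(
            n_frames=400,
            fluct_sigma_nm={"PDMS": sigma, "PMOXA": sigma, "WATER": sigma},
            temporal_correlation="ou",
            ou_tau_frames=3.0,
            seed=5,
        )
        traj, _ = sd.generate_membrane_trajectory(cfg)
        result = ma.rmsf(traj, "PMOXA")
        expected = sigma * math.sqrt(3.0)
        # OU is temporally correlated, so allow a wider band than for iid
        assert result.mean_over_selection_nm == pytest.approx(expected, rel=0.10)

    def test_overpacked_density_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            sd.MembraneSimConfig(water_density_kg_m3=5000.0)

    def test_box_must_fit_layers(self):
        with pytest.raises(ValueError, match="box"):
            sd.MembraneSimConfig(box_nm=(5.0, 5.0, 6.0))
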