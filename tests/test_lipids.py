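"""Bilayer analyses: leaflets, boundary lipids, APL, S_CD, density, thickness."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import single_frame_trajectory
from memorient.io_structures import Box, Frame, LipidDialect, MolecularSystem, Trajectory, group_molecules
from memorient.lipids import (ElectronDensityProfile, apl_montecarlo,
                              apl_voronoi, area_per_lipid, assign_leaflets,
                              bilayer_thickness, classify_boundary,
                              electron_density, order_parameters,
                              periodic_voronoi_areas, thickness_map)
from memorient.synthetic import (build_bilayer, build_membrane_protein_system,
                                 scd_for_chain_tilt, toy_dialect)


class TestLeaflets:
    def test_balanced_bilayer_splits_evenly(self, small_bilayer, dialect):
        system, _ = small_bilayer
        part = assign_leaflets(system, dialect)
        assert (part.labels == "upper").sum() == 64
        assert (part.labels == "lower").sum() == 64

    def test_monolayer_all_upper(self, make_simple_system, dialect):
        rows = []
        for rid in range(1, 5):
            rows.append(("P", "LIP", 1000 + rid, "P", (rid * 5, 5, 20)))
            rows.append(("C11", "LIP", 1000 + rid, "C", (rid * 5, 5, 15)))
        system = group_molecules(make_simple_system(rows),
                                 LipidDialect("single-residue", [("LIP",)]))
        part = assign_leaflets(system, LipidDialect("single-residue", [("LIP",)]))
        # the membrane CoM sits below the head plane, so all heads are "upper"
        assert set(part.labels) == {"upper"}

    def test_head_exactly_at_com_goes_lower(self, make_simple_system):
        # two bare-phosphorus lipids: CoM z is midway; a third head exactly at
        # the CoM must take the documented "lower" branch
        rows = [
            ("P", "LIP", 1001, "P", (0, 0, 10)),
            ("P", "LIP", 1002, "P", (5, 0, -10)),
            ("P", "LIP", 1003, "P", (10, 0, 0.0)),
        ]
        d = LipidDialect("single-residue", [("LIP",)])
        system = group_molecules(make_simple_system(rows), d)
        part = assign_leaflets(system, d)
        assert part.labels[2] == "lower"


class TestBoundary:
    def test_matches_brute_force_double_loop(self, embedded_system):
        system, _, _, _ = embedded_system
        assert system.n_atoms <= 10_000
        flags = classify_boundary(system, cutoff=5.0)
        prot = system.indices_by_tag("protein")
        lengths = system.box.lengths
        brute = []
        for mol in system.molecules:
            if mol.tag != "lipid":
                continue
            d = system.positions[mol.indices, None, :] - system.positions[None, prot, :]
            d -= lengths * np.round(d / lengths)
            brute.append(bool((np.sqrt((d**2).sum(-1)) <= 5.0).any()))
        np.testing.assert_array_equal(flags, brute)
        assert flags.sum() + (~flags).sum() == len(brute)

    def test_no_protein_means_no_boundary(self, small_bilayer):
        system, _ = small_bilayer
        with pytest.warns(UserWarning, match="no protein"):
            flags = classify_boundary(system, cutoff=5.0)
        assert not flags.any()

    def test_zero_cutoff_finds_nothing(self, embedded_system):
        system, _, _, _ = embedded_system
        assert classify_boundary(system, cutoff=0.0).sum() == 0

    def test_cutoff_beyond_minimum_image_rejected(self, embedded_system):
        system, _, _, _ = embedded_system
        with pytest.raises(ValueError, match="minimum-image"):
            classify_boundary(system, cutoff=min(system.box.lengths) / 2 + 1)


class TestVoronoi:
    def test_square_lattice_equal_cells(self):
        pts = np.array([(5.0, 5.0), (15.0, 5.0), (5.0, 15.0), (15.0, 15.0)])
        areas = periodic_voronoi_areas(pts, 20.0, 20.0)
        np.testing.assert_allclose(areas, 100.0, rtol=1e-9)

    def test_area_conservation_with_random_seeds(self):
        rng = np.random.default_rng(3)
        pts = rng.random((40, 2)) * [30.0, 25.0]
        areas = periodic_voronoi_areas(pts, 30.0, 25.0)
        assert abs(areas.sum() - 750.0) / 750.0 < 1e-6

    def test_extra_seed_shrinks_neighbours_but_conserves_total(self):
        pts = np.array([(5.0, 5.0), (15.0, 5.0), (5.0, 15.0), (15.0, 15.0),
                        (10.0, 5.0)])  # midpoint interloper
        areas = periodic_voronoi_areas(pts, 20.0, 20.0)
        assert areas[:2].max() < 100.0
        np.testing.assert_allclose(areas.sum(), 400.0, rtol=1e-9)

    def test_coincident_seeds_perturbed_with_warning(self):
        pts = np.array([(5.0, 5.0), (5.0, 5.0), (15.0, 15.0)])
        with pytest.warns(UserWarning, match="coincident"):
            areas = periodic_voronoi_areas(pts, 20.0, 20.0)
        np.testing.assert_allclose(areas.sum(), 400.0, rtol=1e-6)

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            periodic_voronoi_areas(np.array([(1.0, 1.0), (2.0, 2.0)]), 10, 10)

    def test_built_bilayer_mean_apl_recovered(self, jittered_bilayer, dialect):
        system, truth = jittered_bilayer
        tab, prot_area = apl_voronoi(system, dialect, "upper")
        assert prot_area == 0.0
        assert tab["area_A2"].mean() == pytest.approx(truth.apl, abs=1e-3)

    def test_no_jitter_every_cell_exact(self, small_bilayer, dialect):
        system, truth = small_bilayer
        tab, _ = apl_voronoi(system, dialect, "lower")
        np.testing.assert_allclose(tab["area_A2"], truth.apl, rtol=1e-9)


class TestMonteCarlo:
    def test_agrees_with_exact_tessellation_within_3_sigma(self, dialect):
        rng_seeds = [101, 102]
        n = 200_000
        for s in rng_seeds:
            system, _ = build_bilayer(nx=4, ny=4, jitter_xy=1.2, seed=s)
            exact, _ = apl_voronoi(system, dialect, "upper")
            mc, _ = apl_montecarlo(system, dialect, "upper", n_samples=n, seed=s)
            box_area = system.box.area_xy
            p = exact["area_A2"].to_numpy() / box_area
            se = np.sqrt(p * (1 - p) / n) * box_area
            diff = np.abs(mc["area_A2"].to_numpy() - exact["area_A2"].to_numpy())
            assert np.all(diff <= 3 * se + 1e-9)

    def test_single_effective_seed_takes_whole_box(self, make_simple_system):
        d = LipidDialect("single-residue", [("LIP",)])
        rows = [("P", "LIP", 1001, "P", (5.0, 5.0, 10.0)),
                ("P", "LIP", 1002, "P", (5.0, 5.0, -10.0))]
        system = group_molecules(make_simple_system(rows, box=(20, 20, 60)), d)
        # one lipid per leaflet: Voronoi needs ≥3 seeds, but the MC estimator
        # degenerates cleanly — the lone upper seed wins every sample
        tab, _ = apl_montecarlo(system, d, "upper", n_samples=10_000, seed=1)
        assert tab["area_A2"].iloc[0] == pytest.approx(400.0)

    def test_too_few_samples_rejected(self, small_bilayer, dialect):
        system, _ = small_bilayer
        with pytest.raises(ValueError, match="10\\^4"):
            apl_montecarlo(system, dialect, "upper", n_samples=9_999, seed=0)


class TestOrderParameters:
    def test_vertical_chains_give_half(self, small_bilayer, dialect):
        system, truth = small_bilayer
        # default tilt is non-zero; rebuild vertical
        vert, vtruth = build_bilayer(nx=4, ny=4, chain_tilt_deg=0.0, seed=2)
        prof = order_parameters(single_frame_trajectory(vert), dialect)
        for chain in ("sn1", "sn2"):
            np.testing.assert_allclose(prof.abs_values(chain), 0.5, atol=1e-12)

    def test_fixed_tilt_matches_closed_form(self, small_bilayer, dialect):
        system, truth = small_bilayer
        prof = order_parameters(single_frame_trajectory(system), dialect)
        expected = truth.chain_order_target["sn1"][0]
        for chain in ("sn1", "sn2"):
            np.testing.assert_allclose(prof.chains[chain], expected, atol=1e-10)

    def test_parallel_ch_vectors_give_plus_one(self, make_simple_system):
        # degenerate geometry: C–H along z gives S_CD = +1, outside the
        # physical range for chains — the sign survives in the profile
        rows = [("P", "LIP", 1001, "P", (5, 5, 12)),
                ("C11", "LIP", 1001, "C", (5, 5, 10)),
                ("H11A", "LIP", 1001, "H", (5, 5, 11.09)),
                ("H11B", "LIP", 1001, "H", (5, 5, 8.91))]
        d = LipidDialect("single-residue", [("LIP",)],
                         chain_definitions={"sn1": [("C11", ["H11A", "H11B"])]})
        system = group_molecules(make_simple_system(rows), d)
        prof = order_parameters(single_frame_trajectory(system), d)
        assert prof.chains["sn1"][0] == pytest.approx(1.0)
        assert prof.abs_values("sn1")[0] > 0.5  # flags unphysical geometry

    def test_isotropic_orientations_average_to_zero(self):
        # ≥10⁵ independently oriented C–H vectors
        system, _ = build_bilayer(nx=13, ny=13, chain_tilt_deg="isotropic",
                                  n_carbons=8, seed=42)
        d = toy_dialect(8)
        n_vectors = 2 * 13 * 13 * 2 * 8 * 2
        assert n_vectors >= 10_000 and system.n_atoms > 0
        prof = order_parameters(single_frame_trajectory(system), d)
        pooled = np.mean([prof.chains[c].mean() for c in ("sn1", "sn2")])
        assert abs(pooled) < 0.01

    def test_missing_hydrogen_is_an_error(self, make_simple_system):
        rows = [("P", "LIP", 1001, "P", (5, 5, 12)),
                ("C11", "LIP", 1001, "C", (5, 5, 10))]
        d = LipidDialect("single-residue", [("LIP",)],
                         chain_definitions={"sn1": [("C11", ["H11A", "H11B"])]})
        system = group_molecules(make_simple_system(rows), d)
        with pytest.raises(ValueError, match="C11"):
            order_parameters(single_frame_trajectory(system), d)


class TestElectronDensity:
    def test_single_oxygen_slab_density(self, make_simple_system):
        d = LipidDialect("single-residue", [("LIP",)])
        rows = [("P", "LIP", 1001, "P", (5, 5, 0.0)),  # defines membrane CoM
                ("O", "WAT", 2001, "O", (5, 5, 3.27))]
        system = group_molecules(make_simple_system(rows, box=(10, 10, 40)), d)
        prof = electron_density(single_frame_trajectory(system), bin_width=0.1)
        # relative to the P atom the oxygen sits at z = 3.27: its slab holds
        # 8 electrons → 8 / (10·10·0.1) = 0.8 e/Å³
        i = np.argmin(np.abs(prof.z - 3.27))
        assert prof.densities["total"][i] == pytest.approx(0.8)

    def test_electron_count_conserved(self, embedded_system):
        system, _, _, _ = embedded_system
        traj = single_frame_trajectory(system)
        prof = electron_density(traj)
        expected = system.atomic_numbers().sum()
        assert prof.electron_count() == pytest.approx(expected, rel=1e-3)

    def test_headgroup_peaks_at_constructed_planes(self, small_bilayer, dialect):
        system, truth = small_bilayer
        lipid = system.indices_by_tag("lipid")
        heads = lipid[system.names[lipid] == "P"]
        prof = electron_density(single_frame_trajectory(system), {"headgroup": heads})
        rho = prof.densities["headgroup"]
        half = truth.head_plane_separation / 2
        upper_peak = prof.z[np.argmax(rho * (prof.z > 0))]
        lower_peak = prof.z[np.argmax(rho * (prof.z < 0))]
        assert upper_peak == pytest.approx(half, abs=prof.bin_width)
        assert lower_peak == pytest.approx(-half, abs=prof.bin_width)


class TestThickness:
    def test_recovers_constructed_separation(self, dialect):
        for sep in (34.0, 37.0, 41.5):
            system, truth = build_bilayer(nx=4, ny=4, separation=sep, seed=1)
            lipid = system.indices_by_tag("lipid")
            heads = lipid[system.names[lipid] == "P"]
            prof = electron_density(single_frame_trajectory(system),
                                    {"headgroup": heads})
            assert bilayer_thickness(prof) == pytest.approx(sep, abs=0.1)

    def test_symmetric_profile_centred_on_zero(self, small_bilayer, dialect):
        system, truth = small_bilayer
        lipid = system.indices_by_tag("lipid")
        heads = lipid[system.names[lipid] == "P"]
        prof = electron_density(single_frame_trajectory(system), {"headgroup": heads})
        rho = prof.densities["headgroup"]
        z1 = prof.z[np.argmax(rho * (prof.z < 0))]
        z2 = prof.z[np.argmax(rho * (prof.z > 0))]
        assert (z1 + z2) / 2 == pytest.approx(0.0, abs=prof.bin_width)

    def test_merged_single_peak_is_an_error(self):
        z = np.arange(-20, 20, 0.1)
        rho = np.exp(-z**2 / 8.0)  # one central hump: interdigitated signature
        prof = ElectronDensityProfile(z, {"headgroup": rho}, 0.1, 100.0, 1)
        with pytest.raises(ValueError, match="interdigitated or degenerate"):
            bilayer_thickness(prof)


class TestThicknessMap:
    def test_flat_bilayer_uniform_map(self, small_bilayer, dialect):
        system, truth = small_bilayer
        res = thickness_map(system, dialect, grid=(8, 8))
        np.testing.assert_allclose(res.map, truth.head_plane_separation, atol=1e-6)
        assert not res.occluded.any()

    def test_sinusoidal_undulation_range(self, dialect):
        amp = 3.0
        system, truth = build_bilayer(nx=16, ny=4, undulation_amplitude=amp,
                                      undulation_periods=1, seed=2)
        res = thickness_map(system, dialect, grid=(16, 4))
        rng = np.nanmax(res.map) - np.nanmin(res.map)
        assert rng == pytest.approx(2 * amp, rel=0.05)

    def test_single_cell_equals_mean_separation(self, jittered_bilayer, dialect):
        system, truth = jittered_bilayer
        res = thickness_map(system, dialect, grid=(1, 1))
        assert res.map.shape == (1, 1)
        assert res.map[0, 0] == pytest.approx(truth.head_plane_separation, abs=1e-9)

    def test_protein_cells_flagged(self, embedded_system):
        system, _, dialect, _ = embedded_system
        res = thickness_map(system, dialect, grid=(10, 10))
        assert res.occluded.any()


def test_apl_summary_boundary_below_bulk(embedded_system):
    """Boundary lipids squeezed by protein seeds have smaller areas than bulk."""
    system, _, dialect, truth = embedded_system
    apl = area_per_lipid(system, dialect)
    s = apl.summary().set_index("group")
    assert s.loc["boundary", "apl_mean_A2"] < s.loc["non-boundary", "apl_mean_A2"]
    assert s.loc["non-boundary", "apl_mean_A2"] == pytest.approx(truth.apl, abs=2.0)
    assert (s.loc["boundary", "n_lipids"] + s.loc["non-boundary", "n_lipids"]
            == s.loc["all", "n_lipids"])
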