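import numpy as np
import pandas as pd
import pytest

import biotite.structure as struc

from tyrlie.cudum import (
    FrameError,
    GeometryError,
    MetalSite,
    OrientationError,
    build_dummy_model,
    coordination_distances,
    default_dummy_params,
    detect_metal_sites,
    jahn_teller_score,
    radial_distribution,
    read_structure,
    save_structure,
    write_structure_with_dummies,
)
from tyrlie.synthetic import (
    coordination_reference,
    gen_site_trajectory,
    site_trajectory_spec_from_reference,
    SiteTrajectorySpec,
    toy_site_structure,
)


def _site(partner_positions, classes=None, names=None):
    classes = classes or ["protein"] * len(partner_positions)
    names = names or [f"His{i}" for i in range(len(partner_positions))]
    return MetalSite(
        metal_label="CU_1",
        metal_position=np.zeros(3),
        coordinating_atoms=[
            (names[i], "NE2", np.asarray(p, float), classes[i])
            for i, p in enumerate(partner_positions)
        ],
    )


OCTA = [(2.0, 0, 0), (-2.0, 0, 0), (0, 2.0, 0), (0, -2.0, 0), (0, 0, 2.3), (0, 0, -2.0)]


class TestDetectMetalSites:
    def test_mononuclear_toy_site_has_six_partners(self):
        sites = detect_metal_sites(toy_site_structure(binuclear=False))
        assert len(sites) == 1
        assert len(sites[0].coordinating_atoms) == 6
        classes = [c for _, _, _, c in sites[0].coordinating_atoms]
        assert classes.count("protein") == 3 and classes.count("water") == 3

    def test_binuclear_site_yields_two_independent_sites(self):
        sites = detect_metal_sites(toy_site_structure(binuclear=True))
        assert len(sites) == 2
        assert all(len(s.coordinating_atoms) == 6 for s in sites)
        d = np.linalg.norm(sites[0].metal_position - sites[1].metal_position)
        assert d == pytest.approx(4.2)

    def test_metal_free_structure_gives_empty_list(self):
        arr = toy_site_structure(binuclear=False)
        no_metal = arr[arr.element != "CU"]
        assert detect_metal_sites(no_metal) == []

    def test_partners_sorted_by_distance(self):
        sites = detect_metal_sites(toy_site_structure(binuclear=False))
        dists = [np.linalg.norm(p - sites[0].metal_position)
                 for _, _, p, _ in sites[0].coordinating_atoms]
        assert dists == sorted(dists)


class TestBuildDummyModel:
    def test_charge_sums_to_plus_two_exactly(self):
        model = build_dummy_model(_site(OCTA))
        assert model.total_charge == 2.0

    def test_dummies_sit_exactly_at_their_class_distances(self):
        model = build_dummy_model(_site(OCTA))
        rel = np.linalg.norm(model.dummy_positions - model.core_position, axis=1)
        assert np.allclose(rel[:4], model.eq_distance, atol=1e-9)
        assert np.allclose(rel[4:], model.ax_distance, atol=1e-9)
        assert model.ax_distance >= model.eq_distance

    def test_axis_points_at_the_most_distant_partner(self):
        # one elongated contact at 2.3 A among 2.0 A partners
        model = build_dummy_model(_site(OCTA))
        assert model.axis @ np.array([0.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_explicit_axial_partner_overrides_the_distance_rule(self):
        model = build_dummy_model(_site(OCTA), axial_partner="His0_NE2")
        assert model.axis @ np.array([1.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_rigid_motion_equivariance(self, rng):
        site = _site(OCTA)
        model = build_dummy_model(site)
        # random rotation via QR, plus a translation
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(size=3) * 10
        moved = MetalSite(
            metal_label=site.metal_label,
            metal_position=q @ site.metal_position + t,
            coordinating_atoms=[(l, a, q @ p + t, c) for l, a, p, c in site.coordinating_atoms],
        )
        moved_model = build_dummy_model(moved)
        expected = (q @ model.dummy_positions.T).T + t
        # equatorial arms may be relabelled by the fourfold symmetry: compare as sets
        got = moved_model.dummy_positions
        dist = np.linalg.norm(expected[:, None, :] - got[None, :, :], axis=2)
        assert dist.min(axis=1).max() < 1e-8

    def test_too_few_partners_is_a_geometry_error(self):
        with pytest.raises(GeometryError):
            build_dummy_model(_site([(2, 0, 0), (-2, 0, 0)]))

    def test_collinear_coordination_is_an_orientation_error(self):
        with pytest.raises(OrientationError):
            build_dummy_model(_site([(2, 0, 0), (-2, 0, 0), (2.2, 0, 0)]))

    def test_placeholder_parameters_respect_the_invariants(self):
        p = default_dummy_params()
        assert p["core_charge"] + 4 * p["eq_charge"] + 2 * p["ax_charge"] == pytest.approx(2.0)
        assert p["ax_distance"] >= p["eq_distance"]


class TestWriteStructureWithDummies:
    def test_seven_new_records_per_site_with_unique_ids(self, tmp_path):
        arr = toy_site_structure(binuclear=True)
        sites = detect_metal_sites(arr)
        models = [build_dummy_model(s) for s in sites]
        aug = write_structure_with_dummies(arr, models)
        assert len(aug) == len(arr) + 14
        new = aug[aug.res_name == "CUD"]
        assert len(set(zip(new.res_id, new.atom_name))) == 14

    def test_pdb_round_trip_keeps_three_decimals(self, tmp_path):
        arr = toy_site_structure(binuclear=False)
        models = [build_dummy_model(s) for s in detect_metal_sites(arr)]
        aug = write_structure_with_dummies(arr, models)
        path = tmp_path / "aug.pdb"
        save_structure(aug, str(path))
        back = read_structure(str(path))
        assert np.abs(back.coord - aug.coord).max() < 5e-4

    def test_packaged_synthetic_site_parses_and_detects(self):
        from importlib import resources

        with resources.as_file(
            resources.files("tyrlie.data").joinpath("synthetic_cu_site.pdb")
        ) as p:
            arr = read_structure(str(p))
        assert len(detect_metal_sites(arr)) == 2


class TestCoordinationDistances:
    def test_static_trajectory_recovers_crystal_distances(self):
        site = toy_site_structure(binuclear=False)
        rows = []
        for f in range(3):
            for atom in site:
                label = f"{atom.res_name}{atom.res_id}_{atom.atom_name}".strip()
                rows.append((f, label, *atom.coord))
        frames = pd.DataFrame(rows, columns=["frame", "atom_label", "x", "y", "z"])
        stats = coordination_distances(frames, "CU1_CU", ["HIS3_NE2", "HOH5_O"])
        assert stats.per_partner["HIS3_NE2"] == (pytest.approx(2.1), pytest.approx(0.0))
        assert stats.per_partner["HOH5_O"] == (pytest.approx(2.2), pytest.approx(0.0))

    def test_generated_trajectory_recovers_target_statistics(self):
        # one partner with the elongated-His spec: mean 2.15 A, sd 0.07 A
        spec = SiteTrajectorySpec(
            metal_label="Cu_A",
            metal_position=np.zeros(3),
            partners=[("His204_NE2", np.array([1.0, 0, 0]), 2.15, 0.07)],
            n_frames=2000,
            seed=42,
        )
        stats = coordination_distances(gen_site_trajectory(spec), "Cu_A", ["His204_NE2"])
        mean, sd = stats.per_partner["His204_NE2"]
        assert abs(mean - 2.15) < 0.01
        assert abs(sd - 0.07) < 0.02

    def test_all_reference_partner_rows_recover_within_tolerance(self):
        ref = coordination_reference()
        checked = 0
        for ion in ("Cu_A", "Cu_B"):
            spec = site_trajectory_spec_from_reference(ion, n_frames=2000, seed=17)
            frames = gen_site_trajectory(spec)
            stats = coordination_distances(frames, ion, [p[0] for p in spec.partners])
            sub = ref[ref["ion"] == ion]
            for _, row in sub.iterrows():
                mean, _ = stats.per_partner[f"{row['residue']}_{row['atom']}"]
                assert abs(mean - row["sim_mean"]) < 0.02
                checked += 1
        assert checked == 12

    def test_missing_partner_atom_is_a_frame_error(self):
        rows = [(0, "CU", 0.0, 0.0, 0.0), (0, "N1", 2.0, 0.0, 0.0),
                (1, "CU", 0.0, 0.0, 0.0)]
        frames = pd.DataFrame(rows, columns=["frame", "atom_label", "x", "y", "z"])
        with pytest.raises(FrameError, match="frame 1"):
            coordination_distances(frames, "CU", ["N1"])


class TestJahnTellerScore:
    def test_perfect_octahedron_scores_one(self):
        from tyrlie.cudum import CoordinationStats

        stats = CoordinationStats({"a": (2.0, 0.0), "e1": (2.0, 0.0), "e2": (2.0, 0.0)}, 1)
        assert jahn_teller_score(stats, "a", ["e1", "e2"]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ion,axial,equatorial,expected",
        [
            ("Cu_B", "His60_NE2", ["His42_NE2", "His69_NE2"], 2.33 / np.mean([2.00, 2.01])),
            ("Cu_A", "His208_NE2", ["His204_NE2", "His231_NE2"], 2.30 / np.mean([2.15, 2.02])),
        ],
    )
    def test_reference_sites_show_axial_elongation(self, ion, axial, equatorial, expected):
        from tyrlie.cudum import CoordinationStats

        ref = coordination_reference()
        sub = ref[ref["ion"] == ion]
        stats = CoordinationStats(
            {f"{r['residue']}_{r['atom']}": (float(r["sim_mean"]), float(r["sim_sd"]))
             for _, r in sub.iterrows()},
            1,
        )
        score = jahn_teller_score(stats, axial, equatorial)
        assert score == pytest.approx(expected, abs=1e-9)
        assert score > 1.0

    def test_empty_partner_set_is_an_error(self):
        from tyrlie.cudum import CoordinationStats

        stats = CoordinationStats({"a": (2.3, 0.0)}, 1)
        with pytest.raises(ValueError):
            jahn_teller_score(stats, [], ["a"])


class TestRadialDistribution:
    def test_fluctuating_shell_peaks_at_its_mean_distance(self):
        spec = site_trajectory_spec_from_reference("Cu_A", n_frames=500, seed=9)
        frames = gen_site_trajectory(spec)
        rdf = radial_distribution(frames, "Cu_A", [p[0] for p in spec.partners],
                                  r_max=6.0, n_bins=60)
        # all six partners fluctuate around 2.0-2.35 A
        assert 2.0 <= rdf.first_peak <= 2.4

    def test_uniform_points_give_unit_g_at_small_r(self, rng):
        n_atoms, n_frames, r_max = 200, 50, 10.0
        rows = [(f, "C", 0.0, 0.0, 0.0) for f in range(n_frames)]
        for i in range(n_atoms):
            # rejection-sample uniform points in the r_max ball per frame
            for f in range(n_frames):
                while True:
                    p = rng.uniform(-r_max, r_max, 3)
                    if np.linalg.norm(p) <= r_max:
                        break
                rows.append((f, f"A{i}", *p))
        frames = pd.DataFrame(rows, columns=["frame", "atom_label", "x", "y", "z"])
        rdf = radial_distribution(frames, "C", [f"A{i}" for i in range(n_atoms)],
                                  r_max=r_max, n_bins=10)
        # ignore the innermost shell (few expected counts); g ~ 1 elsewhere
        counts_expected = rdf.n_frames * n_atoms * (
            np.diff(np.linspace(0, r_max, 11) ** 3) / r_max**3
        )
        sigma = 3.0 / np.sqrt(counts_expected[1:])
        assert np.all(np.abs(rdf.g[1:] - 1.0) < sigma + 0.05)

    def test_single_static_frame_concentrates_in_one_bin(self):
        frames = pd.DataFrame(
            [(0, "C", 0.0, 0.0, 0.0), (0, "O", 2.0, 0.0, 0.0)],
            columns=["frame", "atom_label", "x", "y", "z"],
        )
        rdf = radial_distribution(frames, "C", ["O"], r_max=4.0, n_bins=20)
        assert np.count_nonzero(rdf.g) == 1
        assert rdf.first_peak == pytest.approx(2.1, abs=0.11)

    def test_parameter_validation(self):
        frames = pd.DataFrame(
            [(0, "C", 0.0, 0.0, 0.0)], columns=["frame", "atom_label", "x", "y", "z"]
        )
        with pytest.raises(ValueError):
            radial_distribution(frames, "C", ["X"], r_max=-1.0)
        with pytest.raises(ValueError):
            radial_distribution(frames, "C", ["X"], n_bins=5)
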