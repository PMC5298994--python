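"""Pore-radius profiling: PDB loading, analytic ring oracles, invariances."""

import numpy as np
import pytest

from poreperm import (
    AtomSet,
    PoreParams,
    PoreSpec,
    Ring,
    compute_profile,
    default_axis,
    gen_pore_geometry,
    load_structure,
    locate_extrema,
    write_pdb,
)

TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   1       1.500   0.000   0.000  1.00  0.00           N
ATOM      3  O   ALA A   1       0.000   1.500   0.000  1.00  0.00           O
END
"""

MIXED_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2 ZN    ZN A   2       2.000   0.000   0.000  1.00  0.00          ZN
HETATM    3  O   HOH A   3       4.000   0.000   0.000  1.00  0.00           O
END
"""


class TestLoadStructure:
    def test_bondi_radii_assigned_per_element(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        atoms = load_structure(p)
        assert len(atoms) == 3
        by_element = dict(zip(atoms.elements, atoms.vdw_radii))
        assert by_element == pytest.approx({"C": 1.70, "N": 1.55, "O": 1.52})

    def test_water_only_file_is_an_error(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(ValueError, match="no atoms"):
            load_structure(p)

    def test_include_hetero_flag_controls_atom_count(self, tmp_path):
        p = tmp_path / "mixed.pdb"
        p.write_text(MIXED_PDB)
        assert len(load_structure(p)) == 1                       # protein only
        assert len(load_structure(p, include_hetero=True)) == 2  # + Zn, never water

    def test_unknown_element_gets_default_radius_with_warning(self, tmp_path):
        p = tmp_path / "odd.pdb"
        p.write_text(
            "ATOM      1 XX   UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00           XX\nEND\n"
        )
        with pytest.warns(UserWarning, match="unknown elements"):
            atoms = load_structure(p)
        assert atoms.vdw_radii[0] == pytest.approx(1.70)


class TestComputeProfile:
    def test_empty_neighborhood_reports_cap(self):
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=0.0, ring_radius=10.0, n_atoms=12, vdw=1.7),))
        )
        params = PoreParams(axis_length=120.0, axis_origin=(0.0, 0.0, 0.0))
        profile = compute_profile(atoms, params)
        assert profile.radius_at(-60.0) == pytest.approx(16.0)
        assert profile.radius.max() == pytest.approx(16.0)

    def test_ring_plane_matches_closed_form(self):
        atoms, oracle = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=5.0, ring_radius=10.0, n_atoms=12, vdw=1.7),))
        )
        params = PoreParams(axis_length=40.0, axis_origin=(0.0, 0.0, 0.0))
        profile = compute_profile(atoms, params)
        (z_ref, r_ref), = oracle
        assert profile.radius_at(z_ref) == pytest.approx(r_ref, abs=1e-9)

    def test_multi_ring_oracle_equivalence(self):
        rings = tuple(
            Ring(z=z, ring_radius=r, n_atoms=24, vdw=1.5)
            for z, r in [(-20.0, 9.0), (-5.0, 5.5), (10.0, 12.0), (25.0, 4.0)]
        )
        atoms, oracle = gen_pore_geometry(PoreSpec(rings=rings))
        params = PoreParams(axis_length=80.0, axis_origin=(0.0, 0.0, 0.0))
        profile = compute_profile(atoms, params)
        for z_ref, r_ref in oracle:
            assert profile.radius_at(z_ref) == pytest.approx(r_ref, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=-4.0, ring_radius=8.0), Ring(z=6.0, ring_radius=5.0)))
        )
        params = PoreParams(axis_length=30.0, axis_origin=(0.0, 0.0, 0.0))
        base = compute_profile(atoms, params)
        # random rotation (QR of a Gaussian matrix) + translation of
        # atoms AND axis together
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([3.0, -7.0, 11.0])
        moved = AtomSet(
            atoms.elements.copy(),
            atoms.positions @ q.T + shift,
            atoms.vdw_radii.copy(),
        )
        moved_params = PoreParams(
            axis_length=30.0,
            axis_origin=tuple(q @ np.zeros(3) + shift),
            axis_direction=tuple(q @ np.array([0.0, 0.0, 1.0])),
        )
        moved_profile = compute_profile(moved, moved_params)
        np.testing.assert_allclose(moved_profile.radius, base.radius, atol=1e-9)

    def test_adding_an_atom_never_increases_radius(self):
        rng = np.random.default_rng(3)
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=0.0, ring_radius=9.0),))
        )
        params = PoreParams(axis_length=40.0, axis_origin=(0.0, 0.0, 0.0))
        base = compute_profile(atoms, params)
        for _ in range(5):
            extra_pos = rng.uniform(-15, 15, size=3)
            grown = AtomSet(
                np.append(atoms.elements, "C"),
                np.vstack([atoms.positions, extra_pos]),
                np.append(atoms.vdw_radii, 1.7),
            )
            grown_profile = compute_profile(grown, params)
            assert np.all(grown_profile.radius <= base.radius + 1e-12)

    def test_radius_clamped_to_zero_when_atom_sits_on_axis(self):
        atoms = AtomSet(
            elements=np.array(["C"], dtype=object),
            positions=np.array([[0.0, 0.0, 0.0]]),
            vdw_radii=np.array([1.7]),
        )
        params = PoreParams(axis_length=10.0, axis_origin=(0.0, 0.0, 0.0))
        profile = compute_profile(atoms, params)
        assert profile.radius_at(0.0) == 0.0
        assert profile.radius.min() >= 0.0

    def test_degenerate_axis_direction_rejected(self):
        atoms, _ = gen_pore_geometry(PoreSpec(rings=(Ring(z=0.0, ring_radius=8.0),)))
        with pytest.raises(ValueError, match="axis direction"):
            compute_profile(
                atoms,
                PoreParams(axis_origin=(0, 0, 0), axis_direction=(0.0, 0.0, 0.0)),
            )


class TestDefaultAxis:
    def test_symmetric_atoms_give_central_origin(self):
        atoms, _ = gen_pore_geometry(PoreSpec(rings=(Ring(z=2.0, ring_radius=6.0),)))
        origin, direction = default_axis(atoms)
        np.testing.assert_allclose(origin[:2], [0.0, 0.0], atol=1e-12)
        assert origin[2] == pytest.approx(2.0)
        np.testing.assert_array_equal(direction, [0.0, 0.0, 1.0])

    def test_translation_equivariance(self):
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=0.0, ring_radius=7.0), Ring(z=8.0, ring_radius=4.0)))
        )
        shift = np.array([5.0, -2.0, 3.0])
        o1, _ = default_axis(atoms)
        o2, _ = default_axis(atoms.translated(shift))
        np.testing.assert_allclose(o2, o1 + shift, atol=1e-12)

    def test_single_atom_axis_passes_through_it(self):
        atoms = AtomSet(
            elements=np.array(["C"], dtype=object),
            positions=np.array([[1.0, 2.0, 3.0]]),
            vdw_radii=np.array([1.7]),
        )
        origin, _ = default_axis(atoms)
        np.testing.assert_allclose(origin, [1.0, 2.0, 3.0])


class TestLocateExtrema:
    def test_monotone_profile_extremes_at_ends(self):
        from poreperm.pore import PoreProfile

        z = np.arange(0.0, 5.0, 0.5)
        profile = PoreProfile(z=z, radius=10.0 - z, params=PoreParams())
        ext = locate_extrema(profile)
        assert ext["max"] == (0.0, 10.0)
        assert ext["min"] == (pytest.approx(4.5), pytest.approx(5.5))

    def test_two_constriction_geometry_min_at_narrower_ring(self):
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(
                Ring(z=-10.0, ring_radius=7.7, vdw=1.7),   # effective 6 A
                Ring(z=10.0, ring_radius=4.7, vdw=1.7),    # effective 3 A
            ))
        )
        params = PoreParams(axis_length=40.0, axis_origin=(0.0, 0.0, 0.0))
        ext = locate_extrema(compute_profile(atoms, params))
        z_min, r_min = ext["min"]
        assert z_min == pytest.approx(10.0)
        assert r_min == pytest.approx(3.0, abs=1e-9)

    def test_empty_window_rejected(self):
        from poreperm.pore import PoreProfile

        profile = PoreProfile(
            z=np.array([0.0, 1.0]), radius=np.array([5.0, 6.0]), params=PoreParams()
        )
        with pytest.raises(ValueError, match="window"):
            locate_extrema(profile, z_window=(10.0, 20.0))


class TestPdbRoundTrip:
    def test_written_geometry_reloads_to_same_coordinates(self, tmp_path):
        atoms, _ = gen_pore_geometry(
            PoreSpec(rings=(Ring(z=5.0, ring_radius=10.0, n_atoms=12, vdw=1.7),),
                     jitter_sd=0.1, seed=4)
        )
        p = write_pdb(atoms, tmp_path / "rings.pdb")
        reloaded = load_structure(p)
        assert len(reloaded) == len(atoms)
        np.testing.assert_allclose(
            reloaded.positions, atoms.positions, atol=1e-3
        )  # PDB stores 3 decimals
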