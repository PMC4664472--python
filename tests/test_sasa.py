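"""Shrake-Rupley areas, deletion-difference maps, reporter selection."""

import numpy as np
import pytest

from confsel.sasa_map import (
    SasaError,
    StructureModel,
    deletion_diff,
    expand_ranges,
    reporter_select,
    sasa,
)
from confsel.synthetic import gen_toy_structure


def _single(radius=1.6):
    return StructureModel.from_arrays(["C"], [1], [[0.0, 0.0, 0.0]],
                                      radius=[radius])


def two_sphere_exact(r, d, probe):
    """Exposed area of one of two equal spheres: sphere minus spherical cap."""
    R = r + probe
    h = R - d / 2.0
    return 4 * np.pi * R * R - 2 * np.pi * R * h


class TestSasa:
    def test_isolated_atom_analytic(self):
        res = sasa(_single(1.6), probe=1.4, n_points=960)
        assert res.per_atom[0] == pytest.approx(4 * np.pi * 3.0**2, rel=1e-9)

    def test_fully_buried_atom(self):
        """An atom enclosed by a dense shell has zero accessible surface."""
        i = np.arange(80)
        z = 1 - 2 * (i + 0.5) / 80
        phi = i * np.pi * (3 - np.sqrt(5))
        rho = np.sqrt(1 - z * z)
        shell = 3.0 * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        xyz = np.vstack([[0.0, 0.0, 0.0], shell])
        s = StructureModel.from_arrays(["C"] * 81, np.arange(1, 82), xyz)
        res = sasa(s, probe=1.4, n_points=960)
        assert res.per_atom[0] == 0.0

    def test_two_sphere_cap_oracle(self):
        s = StructureModel.from_arrays(["C", "C"], [1, 2],
                                       [[0, 0, 0], [2.0, 0, 0]],
                                       radius=[1.6, 1.6])
        res = sasa(s, probe=1.4, n_points=960)
        exact = two_sphere_exact(1.6, 2.0, 1.4)
        for area in res.per_atom:
            assert area == pytest.approx(exact, rel=0.02)

    def test_quadrature_converges_monotonically(self):
        """Worst-case error over a family of sphere separations shrinks with n."""
        errs = []
        for n in (240, 960, 3840):
            worst = 0.0
            for d in (1.0, 1.5, 2.0, 2.5, 3.0):
                s = StructureModel.from_arrays(["C", "C"], [1, 2],
                                               [[0, 0, 0], [d, 0, 0]],
                                               radius=[1.6, 1.6])
                res = sasa(s, probe=1.4, n_points=n)
                exact = two_sphere_exact(1.6, d, 1.4)
                worst = max(worst, abs(res.per_atom[0] - exact) / exact)
            errs.append(worst)
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[1] < 0.02

    def test_rigid_motion_invariance(self):
        structure, _ = gen_toy_structure("helix", n_residues=12, seed=0)
        base = sasa(structure, n_points=960)
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = structure.transformed(q, rng.uniform(-20, 20, 3))
        res = sasa(moved, n_points=960)
        # quadrature points do not rotate with the molecule, so allow ~1%
        assert res.total() == pytest.approx(base.total(), rel=0.01)
        for r in base.per_residue:
            assert res.per_residue[r] == pytest.approx(
                base.per_residue[r], rel=0.05, abs=2.0
            )

    def test_coincident_atoms_warn(self):
        s = StructureModel.from_arrays(["C", "C"], [1, 2],
                                       [[0, 0, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="coincident"):
            sasa(s)

    def test_parameter_validation(self):
        with pytest.raises(SasaError):
            sasa(_single(), probe=-0.1)
        with pytest.raises(SasaError):
            sasa(_single(), n_points=10)


class TestDeletionDiff:
    def test_far_apart_lobes_no_contacts(self):
        structure, info = gen_toy_structure("two_lobe", gap=20.0)
        diff = deletion_diff(structure, info["lobe_b"])
        assert diff.flagged == []
        assert all(abs(v) < 1e-9 for v in diff.delta.values())

    def test_touching_lobes_flag_designed_contacts(self):
        structure, info = gen_toy_structure("two_lobe", gap=3.0)
        diff = deletion_diff(structure, info["lobe_b"])
        assert diff.flagged == info["contacts_a"]
        rev = deletion_diff(structure, info["lobe_a"])
        assert rev.flagged == info["contacts_b"]

    def test_deletion_only_exposes_surface(self):
        structure, info = gen_toy_structure("two_lobe", gap=3.0)
        diff = deletion_diff(structure, info["lobe_b"])
        assert all(v >= -1e-9 for v in diff.delta.values())

    def test_empty_deletion_all_zero(self):
        structure, _ = gen_toy_structure("two_lobe", gap=3.0)
        diff = deletion_diff(structure, "")
        assert set(diff.delta) == set(structure.residues)
        assert all(v == 0.0 for v in diff.delta.values())

    def test_deleting_everything_is_error(self):
        structure, _ = gen_toy_structure("two_lobe", gap=3.0)
        with pytest.raises(SasaError, match="entire"):
            deletion_diff(structure, structure.residues)

    def test_range_spec_parsing(self):
        assert expand_ranges("226-229,300") == {226, 227, 228, 229, 300}
        assert expand_ranges([(1, 3), 9]) == {1, 2, 3, 9}


class TestReporterSelect:
    def _chain(self, n=10, spacing=4.0):
        xyz = np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])
        return StructureModel.from_arrays(["C"] * n, np.arange(1, n + 1), xyz)

    def test_empty_interface_returns_all(self):
        s = self._chain()
        assert reporter_select(s, {}, min_dist=8.0) == s.residues

    def test_tiny_cutoff_excludes_only_interface(self):
        s = self._chain()
        assert reporter_select(s, [{3}], min_dist=1e-6) == \
            [r for r in s.residues if r != 3]

    def test_linear_chain_distance_cutoff(self):
        """Interface at residue 1: only residues beyond 8 A survive."""
        s = self._chain(n=10, spacing=4.0)
        selected = reporter_select(s, {"iface": [1]}, min_dist=8.0)
        assert selected == [4, 5, 6, 7, 8, 9, 10]

    def test_empty_result_is_error(self):
        s = self._chain(n=4, spacing=1.0)
        with pytest.raises(SasaError, match="min_dist"):
            reporter_select(s, [{1}], min_dist=50.0)


class TestCrossCheck:
    def test_matches_biotite_on_random_cluster(self):
        """Independent implementation check against biotite's Shrake-Rupley."""
        import biotite.structure as struc

        rng = np.random.default_rng(8)
        n = 40
        xyz = rng.uniform(0, 12, (n, 3))
        elements = rng.choice(["C", "N", "O"], n)
        ours = StructureModel.from_arrays(elements, np.arange(1, n + 1), xyz)

        arr = struc.AtomArray(n)
        arr.coord = xyz.astype(np.float32)
        arr.chain_id = np.array(["A"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.res_name = np.array(["GLY"] * n)
        arr.atom_name = elements
        arr.element = elements
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii=ours.radius)
        mine = sasa(ours, probe=1.4, n_points=960)
        assert mine.total() == pytest.approx(float(ref.sum()), rel=0.02)
        np.testing.assert_allclose(mine.per_atom, ref, rtol=0.1, atol=2.0)


class TestPdbRoundTrip:
    def test_write_then_read(self, tmp_path):
        structure, _ = gen_toy_structure("two_lobe", gap=3.0)
        path = tmp_path / "toy.pdb"
        structure.to_pdb(path)
        back = StructureModel.from_pdb(path)
        assert back.n_atoms == structure.n_atoms
        np.testing.assert_allclose(back.xyz, structure.xyz, atol=1e-3)
        assert back.residues == structure.residues
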