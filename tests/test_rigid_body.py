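"""Woessner prediction, Perrin ellipsoid estimates, excess-J(0) flags."""

import numpy as np
import pytest

from confsel.relaxometry import SpectralDensities
from confsel.rigid_body import (
    DiffusionTensor,
    NHVector,
    RigidBodyError,
    compare_profiles,
    estimate_tensor_ellipsoid,
    nh_vectors_from_structure,
    perrin_axial_ratio,
    predict_J,
    woessner_weights,
)
from confsel.synthetic import gen_toy_structure


def closed_form_prolate_ratio(q):
    """Perrin D_par/D_perp for a prolate spheroid, unique/equatorial = q > 1.

    Independent closed-form oracle: with u = sqrt(q^2 - 1), L = ln(q + u)
    (b = 1), the spheroid integrals are alpha_a = 2 (L - u/q) / u^3 and
    alpha_b = (q - L/u) / u^2, giving
    D_par/D_perp = alpha_b (q^2 + 1) / (q^2 alpha_a + alpha_b).
    """
    u = np.sqrt(q * q - 1.0)
    L = np.log(q + u)
    alpha_a = 2.0 * (L - u / q) / u**3
    alpha_b = (q - L / u) / u**2
    return alpha_b * (q * q + 1.0) / (q * q * alpha_a + alpha_b)


class TestPredictJ:
    def test_weights_sum_to_one_on_grid(self):
        for alpha in np.linspace(0, np.pi, 37):
            assert woessner_weights(alpha).sum() == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_is_single_lorentzian(self):
        d = 1.0 / (6 * 12e-9)
        tensor = DiffusionTensor.axial(d, d)
        omegas = np.array([0.0, 1e8, 4.4e8, 3.8e9])
        for vec in ([0, 0, 1], [1, 0, 0], [0.6, 0.48, 0.64]):
            j = predict_J(tensor, NHVector(1, vec), omegas)
            expected = 0.4 * 12e-9 / (1 + (omegas * 12e-9) ** 2)
            np.testing.assert_allclose(j, expected, rtol=1e-14)

    def test_axis_aligned_limit(self):
        """alpha = 0 collapses to a single Lorentzian with tau1 = 1/(6 Dperp)."""
        tensor = DiffusionTensor.axial(3e7, 1e7)
        tau1 = 1.0 / (6e7)
        j = predict_J(tensor, NHVector(1, [0, 0, 1]), [0.0, 5e8])
        expected = 0.4 * tau1 / (1 + (np.array([0.0, 5e8]) * tau1) ** 2)
        np.testing.assert_allclose(j, expected, rtol=1e-12)

    def test_perpendicular_three_term_value(self):
        """Frozen value of the three-term sum at alpha=90 deg, omega=0."""
        tensor = DiffusionTensor.axial(2.4e7, 1.2e7)
        j0 = predict_J(tensor, NHVector(1, [1, 0, 0]), [0.0])[0]
        # 0.4 * (0.25/(6*1.2e7) + 0.75/(2*1.2e7 + 4*2.4e7))
        assert j0 == pytest.approx(3.888888888888889e-9, rel=1e-12)

    def test_positive_everywhere_and_anisotropy_monotonicity(self):
        """At fixed tau_iso and alpha=90 deg, J(0) decreases with anisotropy.

        The decrease holds over the moderate-anisotropy range relevant for
        globular proteins (D_par/D_perp <= 2); for extreme ratios the slow
        tau1 = 1/(6 D_perp) component dominates and J(0) rises again, so
        monotonicity is asserted only on the physical range.
        """
        tau_iso = 15e-9
        d_iso = 1.0 / (6 * tau_iso)
        last = np.inf
        for ratio in [1.0, 1.2, 1.5, 1.8, 2.0]:
            d_perp = 3 * d_iso / (2 + ratio)
            tensor = DiffusionTensor.axial(ratio * d_perp, d_perp)
            j = predict_J(tensor, NHVector(1, [1, 0, 0]),
                          np.linspace(0, 5e9, 40))
            assert np.all(j > 0)
            assert j[0] < last + 1e-18
            last = j[0]

    def test_non_axial_tensor_rejected(self):
        tensor = DiffusionTensor(np.array([1e7, 2e7, 3e7]), np.eye(3))
        with pytest.raises(RigidBodyError, match="anisotropic"):
            predict_J(tensor, NHVector(1, [0, 0, 1]), [0.0])

    def test_tau_iso_definition(self):
        tensor = DiffusionTensor.axial(2e7, 1e7)
        assert tensor.tau_iso == pytest.approx(1.0 / (2 * 4e7))


class TestEllipsoidEstimate:
    def test_sphere_cloud_is_isotropic(self):
        structure, _ = gen_toy_structure("sphere_cloud", n_residues=4000, seed=3)
        tensor = estimate_tensor_ellipsoid(structure, 12e-9)
        d_par, d_perp, _ = tensor.axial_components()
        assert d_par / d_perp == pytest.approx(1.0, abs=0.02)
        assert tensor.tau_iso == pytest.approx(12e-9, rel=1e-9)

    def test_prolate_cloud_matches_perrin_closed_form(self):
        """3:1 prolate point cloud recovers the Perrin ratio within 5%."""
        rng = np.random.default_rng(0)
        u = rng.standard_normal((8000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.uniform(0, 1, 8000) ** (1 / 3)
        xyz = u * r[:, None] * np.array([30.0, 10.0, 10.0])
        from confsel.sasa_map import StructureModel

        structure = StructureModel.from_arrays(["C"] * 8000,
                                               np.arange(1, 8001), xyz)
        tensor = estimate_tensor_ellipsoid(structure, 12e-9)
        d_par, d_perp, axis = tensor.axial_components()
        expected = closed_form_prolate_ratio(3.0)
        assert expected > 1.0
        assert d_par / d_perp == pytest.approx(expected, rel=0.05)
        assert abs(axis @ np.array([1.0, 0, 0])) > 0.99

    def test_quadrature_ratio_matches_closed_form(self):
        for q in (1.5, 3.0, 6.0):
            assert perrin_axial_ratio(q) == pytest.approx(
                closed_form_prolate_ratio(q), rel=1e-8
            )

    def test_rotation_equivariance(self):
        structure, _ = gen_toy_structure("helix", n_residues=40, seed=1)
        tensor = estimate_tensor_ellipsoid(structure, 10e-9)
        theta = 1.1
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = structure.transformed(rot, np.array([5.0, -2.0, 9.0]))
        tensor2 = estimate_tensor_ellipsoid(moved, 10e-9)
        np.testing.assert_allclose(tensor2.values, tensor.values, rtol=1e-9)
        _, _, ax1 = tensor.axial_components()
        _, _, ax2 = tensor2.axial_components()
        assert abs(ax2 @ (rot @ ax1)) == pytest.approx(1.0, abs=1e-6)

    def test_collinear_coordinates_rejected(self):
        from confsel.sasa_map import StructureModel

        xyz = np.column_stack([np.linspace(0, 10, 20), np.zeros(20), np.zeros(20)])
        structure = StructureModel.from_arrays(["C"] * 20, np.arange(1, 21), xyz)
        with pytest.raises(RigidBodyError, match="collinear"):
            estimate_tensor_ellipsoid(structure, 10e-9)


class TestNHVectors:
    def test_helix_vectors_unit_norm(self):
        structure, _ = gen_toy_structure("helix", n_residues=15, seed=0)
        vectors = nh_vectors_from_structure(structure)
        assert len(vectors) == 15
        for nh in vectors:
            assert np.linalg.norm(nh.vector) == pytest.approx(1.0, abs=1e-9)
            assert not nh.approximate

    def test_bisector_placement_when_h_missing(self):
        structure, _ = gen_toy_structure("helix", n_residues=15, seed=0)
        heavy = structure.subset(structure.element != "H")
        vectors = nh_vectors_from_structure(heavy)
        assert vectors  # residue 1 lacks a preceding C and is skipped
        assert all(nh.approximate for nh in vectors)
        assert all(abs(np.linalg.norm(nh.vector) - 1) < 1e-9 for nh in vectors)


class TestCompareProfiles:
    def _obs(self, res, j0, err=0.2e-9):
        return SpectralDensities(res, j0, 1e-10, 5e-12, j0_err=err)

    def test_identical_profiles_unflagged(self):
        obs = [self._obs(r, 5e-9) for r in range(1, 11)]
        pred = {r: 5e-9 for r in range(1, 11)}
        cmp = compare_profiles(obs, pred)
        assert cmp.flagged == []
        assert all(v == 0.0 for v in cmp.delta_j0.values())

    def test_elevated_hinge_residues_flagged_exactly(self):
        hinge = {3, 4, 5, 6, 7}
        obs = [self._obs(r, 5e-9 + (1e-9 if r in hinge else 0.0))
               for r in range(1, 21)]
        pred = {r: 5e-9 for r in range(1, 21)}
        cmp = compare_profiles(obs, pred, k=2.0)
        assert cmp.flagged == sorted(hinge)

    def test_empty_overlap_is_error(self):
        obs = [self._obs(1, 5e-9)]
        with pytest.raises(RigidBodyError):
            compare_profiles(obs, {99: 5e-9})
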