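"""Reduced spectral density mapping: round trips, exchange, averages."""

import io

import numpy as np
import pytest

from confsel.relaxometry import (
    PhysicalConstants,
    RelaxationRecord,
    RelaxometryError,
    mc_propagate,
    rates_from_spectral_densities,
    read_relaxation_tsv,
    reduce_map,
    region_average,
    write_relaxation_tsv,
)
from confsel.shift_tables import DomainDefinition
from confsel.synthetic import ModelFreeConfig, gen_relaxation, model_free_j

K = PhysicalConstants()
FIELD = 700.13


def _rec(j0, jwn, jwh, rex=0.0, res=1):
    r1, r2, noe = rates_from_spectral_densities(j0, jwn, jwh, K, FIELD, rex=rex)
    return RelaxationRecord(res, r1, r2, noe, field_MHz=FIELD)


class TestReduceMap:
    def test_algebraic_round_trip(self):
        """Mapping inverts the forward linear relations to machine precision."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            j0 = rng.uniform(2e-9, 9e-9)
            jwn = rng.uniform(5e-11, 2e-10)
            jwh = rng.uniform(1e-12, 2e-11)
            s = reduce_map(_rec(j0, jwn, jwh), K)
            assert s.j0 == pytest.approx(j0, rel=1e-12)
            assert s.jwn == pytest.approx(jwn, rel=1e-12)
            assert s.jwh == pytest.approx(jwh, rel=1e-12)

    def test_noe_of_one_gives_zero_jwh(self):
        rec = RelaxationRecord(1, 1.0, 15.0, 1.0, field_MHz=FIELD)
        assert reduce_map(rec, K).jwh == 0.0

    def test_rex_shifts_j0_exactly(self):
        """Rex on R2 adds Rex/(d^2/2 + 2c^2/3) to J(0), nothing else."""
        base = reduce_map(_rec(5e-9, 1.2e-10, 5e-12), K)
        rex = 3.0
        shifted = reduce_map(_rec(5e-9, 1.2e-10, 5e-12, rex=rex), K)
        denom = K.d**2 / 2 + 2 * K.c(FIELD) ** 2 / 3
        assert shifted.j0 - base.j0 == pytest.approx(rex / denom, rel=1e-10)
        assert shifted.jwn == pytest.approx(base.jwn, rel=1e-12)
        assert shifted.jwh == pytest.approx(base.jwh, rel=1e-12)

    def test_single_lorentzian_tumbling_recovered(self):
        """Rates from a rigid 12 ns tumbler map back to J(0) = 4.8e-9 s/rad."""
        tau = 12e-9
        freqs = np.array([0.0, K.omega_n(FIELD), K.omega_h(FIELD) - K.omega_n(FIELD),
                          K.omega_h(FIELD), K.omega_h(FIELD) + K.omega_n(FIELD)])
        j = 0.4 * tau / (1 + (freqs * tau) ** 2)
        d2, c2 = K.d**2, K.c(FIELD) ** 2
        r1 = (d2 / 4) * (j[2] + 3 * j[1] + 6 * j[4]) + c2 * j[1]
        r2 = (d2 / 8) * (4 * j[0] + j[2] + 3 * j[1] + 6 * j[3] + 6 * j[4]) \
            + (c2 / 6) * (4 * j[0] + 3 * j[1])
        sigma = (d2 / 4) * (6 * j[4] - j[2])
        noe = 1 + sigma / (r1 * K.gamma_ratio)
        s = reduce_map(RelaxationRecord(1, r1, r2, noe, field_MHz=FIELD), K)
        assert s.j0 == pytest.approx(0.4 * tau, rel=0.02)

    def test_model_free_j0_within_documented_bound(self):
        """Two-time-scale dynamics: J(0) recovered within the 5% mapping bound."""
        cfg = ModelFreeConfig(list(range(1, 11)), s2=0.85, tau_c_ns=12.0,
                              tau_e_ps=50.0, noise_frac_r1=0, noise_frac_r2=0,
                              noise_abs_noe=0, seed=0)
        fix = gen_relaxation(cfg, K)
        for rec in fix.records:
            s = reduce_map(rec, K)
            j0_truth = fix.truth_j[rec.residue_id][0]
            assert abs(s.j0 - j0_truth) / j0_truth <= 0.05
            jwn_truth = fix.truth_j[rec.residue_id][1]
            assert abs(s.jwn - jwn_truth) / jwn_truth <= 0.05

    def test_unphysical_noe_flagged(self):
        rec = RelaxationRecord(1, 1.0, 15.0, 1.2, field_MHz=FIELD)
        assert reduce_map(rec, K).noe_flag

    def test_invalid_rates_rejected(self):
        with pytest.raises(RelaxometryError):
            RelaxationRecord(1, -1.0, 15.0, 0.8)


class TestMcPropagate:
    REC = RelaxationRecord(7, 0.7, 18.0, 0.75, 0.02, 0.5, 0.03, FIELD)

    def test_zero_errors_give_zero_spread(self):
        rec = RelaxationRecord(1, 0.7, 18.0, 0.75, field_MHz=FIELD)
        s = mc_propagate(rec, K, n_mc=200, seed=0)
        assert s.j0_err == s.jwn_err == s.jwh_err == 0.0

    def test_same_seed_bit_identical(self):
        a = mc_propagate(self.REC, K, n_mc=500, seed=3)
        b = mc_propagate(self.REC, K, n_mc=500, seed=3)
        assert (a.j0_err, a.jwn_err, a.jwh_err) == (b.j0_err, b.jwn_err, b.jwh_err)

    def test_error_scaling_is_linear(self):
        """Doubling every input error doubles the output SDs (MC noise aside)."""
        doubled = RelaxationRecord(7, 0.7, 18.0, 0.75, 0.04, 1.0, 0.06, FIELD)
        a = mc_propagate(self.REC, K, n_mc=5000, seed=1)
        b = mc_propagate(doubled, K, n_mc=5000, seed=1)
        assert b.j0_err / a.j0_err == pytest.approx(2.0, rel=0.08)
        assert b.jwh_err / a.jwh_err == pytest.approx(2.0, rel=0.08)

    def test_n_mc_floor(self):
        with pytest.raises(RelaxometryError):
            mc_propagate(self.REC, K, n_mc=10, seed=0)


class TestRegionAverage:
    DOM = DomainDefinition("D", (1, 100), {"core": (10, 20)})

    def _dens(self, res, j0):
        from confsel.relaxometry import SpectralDensities
        return SpectralDensities(res, j0, 1e-10, 1e-12)

    def test_identical_values(self):
        dens = [self._dens(r, 6.0e-9) for r in range(10, 15)]
        avg = region_average(dens, self.DOM, "core")
        assert avg.j0_mean == pytest.approx(6.0e-9, rel=1e-12)
        assert avg.j0_sd == pytest.approx(0.0, abs=1e-20)
        assert avg.n == 5

    def test_two_residue_arithmetic(self):
        avg = region_average([self._dens(10, 5e-9), self._dens(11, 7e-9)],
                             self.DOM, "core")
        assert avg.j0_mean == pytest.approx(6.0e-9)
        assert avg.j0_sd == pytest.approx(1.4142e-9, rel=1e-4)

    def test_missing_residues_skipped(self):
        dens = [self._dens(10, 5e-9), self._dens(12, 7e-9), self._dens(50, 1e-9)]
        avg = region_average(dens, self.DOM, "core")
        assert avg.n == 2

    def test_insufficient_data_is_error(self):
        with pytest.raises(RelaxometryError):
            region_average([self._dens(10, 5e-9)], self.DOM, "core")


class TestIO:
    def test_tsv_round_trip(self):
        recs = [RelaxationRecord(5, 0.7, 18.0, 0.78, 0.01, 0.4, 0.02, FIELD)]
        buf = io.StringIO()
        write_relaxation_tsv(recs, buf)
        back = read_relaxation_tsv(io.StringIO(buf.getvalue()), FIELD)
        assert back[0].residue_id == 5
        assert back[0].r2 == pytest.approx(18.0)

    def test_missing_column_named(self):
        bad = "residue\tR1\tR1_err\tR2\tR2_err\n1\t0.7\t0.01\t18\t0.4\n"
        with pytest.raises(RelaxometryError, match="NOE"):
            read_relaxation_tsv(io.StringIO(bad))


class TestConstants:
    def test_derived_not_hardcoded(self):
        """d and c respond to the fields they are derived from."""
        k2 = PhysicalConstants(rNH_angstrom=1.04)
        assert abs(k2.d) < abs(K.d)  # longer bond, weaker dipolar coupling
        k3 = PhysicalConstants(delta_sigma_ppm=-170.0)
        assert abs(k3.c(FIELD)) > abs(K.c(FIELD))

    def test_high_frequency_convention_switch(self):
        k_sum = PhysicalConstants(high_freq_scale=None)
        assert k_sum.omega_high(FIELD) == pytest.approx(
            K.omega_h(FIELD) + K.omega_n(FIELD)
        )
        assert K.omega_high(FIELD) == pytest.approx(0.87 * K.omega_h(FIELD))
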