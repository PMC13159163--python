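"""Flory-Huggins free energy, binodal construction, and driving forces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import phasekin as pk
from phasekin.exceptions import DomainError
from phasekin.phase_thermo import _df_dphi


def sym_model(chi: float) -> pk.PhaseModel:
    """M = 1 model with chi(300 K) = chi."""
    return pk.PhaseModel(1.0, 0.0, chi * 300.0)


class TestFreeEnergy:
    def test_vanishes_at_pure_phases(self):
        m = sym_model(2.0)
        assert pk.free_energy_density(0.0, 300.0, m) == 0.0
        assert pk.free_energy_density(1.0, 300.0, m) == 0.0

    def test_hand_evaluated_value(self):
        # M=1, chi=2, phi=0.5: ln(0.5) + 0.5
        f = pk.free_energy_density(0.5, 300.0, sym_model(2.0))
        assert f == pytest.approx(np.log(0.5) + 0.5, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        phi=st.floats(1e-6, 1.0 - 1e-6),
        chi=st.floats(0.0, 5.0),
    )
    def test_symmetric_blend_symmetry(self, phi, chi):
        m = sym_model(chi)
        f1 = pk.free_energy_density(phi, 300.0, m)
        f2 = pk.free_energy_density(1.0 - phi, 300.0, m)
        assert f1 == pytest.approx(f2, rel=1e-9, abs=1e-12)

    def test_rejects_out_of_range_phi(self):
        with pytest.raises(DomainError):
            pk.free_energy_density(1.2, 300.0, sym_model(2.0))
        with pytest.raises(DomainError):
            pk.free_energy_density(-0.1, 300.0, sym_model(2.0))

    def test_per_molecule_consistent_with_density(self):
        m = pk.PHASE_PRESETS["m2000"]
        phi = 0.08
        g = pk.per_molecule_free_energy(phi, 310.0, m)
        f = pk.free_energy_density(phi, 310.0, m)
        assert g * phi / m.chain_length == pytest.approx(f, rel=1e-12)

    def test_per_molecule_hand_value_and_pure_limit(self):
        g = pk.per_molecule_free_energy(0.5, 300.0, sym_model(2.0))
        assert g == pytest.approx(2.0 * (np.log(0.5) + 0.5), rel=1e-12)
        # entropy terms vanish toward the pure-solute limit for chi = 0
        g1 = pk.per_molecule_free_energy(1.0 - 1e-9, 300.0, sym_model(0.0))
        assert abs(g1) < 1e-7
        with pytest.raises(DomainError):
            pk.per_molecule_free_energy(0.0, 300.0, sym_model(2.0))


class TestCriticalPoint:
    @pytest.mark.parametrize(
        "M, phi_c, chi_c",
        [(1.0, 0.5, 2.0), (100.0, 1.0 / 11.0, 0.605)],
    )
    def test_closed_forms(self, M, phi_c, chi_c):
        model = pk.PhaseModel(M, 0.0, 300.0)
        pc, Tc = pk.critical_point(model)
        assert pc == pytest.approx(phi_c, rel=1e-12)
        # chi(Tc) = chi_c by construction of Tc
        assert model.chi(Tc) == pytest.approx(chi_c, rel=1e-12)

    def test_poly_ra_critical_temperature(self):
        _, Tc = pk.critical_point(pk.PHASE_PRESETS["m2000"])
        assert pk.kelvin_to_celsius(Tc) == pytest.approx(64.5, abs=0.01)

    def test_no_finite_critical_temperature(self):
        with pytest.raises(DomainError):
            pk.critical_point(pk.PhaseModel(1.0, 2.5, 98.8))  # A > chi_c, B > 0

    def test_binodal_degenerates_at_critical_point(self, m2000):
        phi_c, Tc = pk.critical_point(m2000)
        above = pk.compute_binodal(Tc + 1.0, m2000)
        assert above.phi_minus == above.phi_plus == pytest.approx(phi_c)
        below = pk.compute_binodal(Tc - 0.5, m2000)
        assert below.gap > 0


class TestBinodal:
    def test_symmetric_blend_against_bisection_oracle(self):
        # For M = 1 the coexistence condition reduces to
        # ln(phi/(1-phi)) = chi (2 phi - 1); solve by bisection.
        chi = 2.5
        root = brentq(
            lambda p: np.log(p / (1.0 - p)) - chi * (2.0 * p - 1.0), 1e-8, 0.499999
        )
        b = pk.compute_binodal(300.0, sym_model(chi))
        assert b.phi_minus == pytest.approx(root, rel=1e-8)
        assert b.phi_plus == pytest.approx(1.0 - root, rel=1e-8)
        assert b.phi_minus + b.phi_plus == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("preset", ["m1000", "m2000", "m4000"])
    @pytest.mark.parametrize("t_c_deg", [25.0, 40.0, 55.0])
    def test_equal_tangent_conditions(self, preset, t_c_deg):
        model = pk.PHASE_PRESETS[preset]
        T = pk.celsius_to_kelvin(t_c_deg)
        b = pk.compute_binodal(T, model)
        slope_lo = _df_dphi(b.phi_minus, T, model)
        slope_hi = _df_dphi(b.phi_plus, T, model)
        f_lo = pk.free_energy_density(b.phi_minus, T, model)
        f_hi = pk.free_energy_density(b.phi_plus, T, model)
        assert abs(slope_lo - slope_hi) < 1e-8
        assert abs((f_hi - f_lo) - slope_lo * (b.phi_plus - b.phi_minus)) < 1e-8

    def test_gap_widens_on_cooling(self, m2000):
        temps = pk.celsius_to_kelvin(np.array([20.0, 30.0, 36.0, 45.0, 55.0, 62.0]))
        lo, hi = pk.binodal_curve(temps, m2000)
        gaps = hi - lo
        assert np.all(np.diff(gaps) < 0)  # non-increasing in T
        # dense binodal at 36 C above its 55 C value (widening on cooling)
        assert hi[2] > hi[4]

    def test_curve_matches_pointwise_construction(self, m2000):
        temps = pk.celsius_to_kelvin(np.array([30.0, 40.0, 50.0]))
        lo, hi = pk.binodal_curve(temps, m2000)
        for T, plo, phi in zip(temps, lo, hi):
            b = pk.compute_binodal(float(T), m2000)
            assert plo == pytest.approx(b.phi_minus, rel=1e-9)
            assert phi == pytest.approx(b.phi_plus, rel=1e-9)


class TestConcentrationConversion:
    def test_round_trip_and_limits(self, m2000):
        assert pk.phi_from_conc(0.0, m2000) == 0.0
        assert pk.phi_from_conc(1600.0, m2000) == pytest.approx(1.0)
        assert pk.phi_from_conc(0.82, m2000) == pytest.approx(5.125e-4, rel=1e-12)
        phi = 0.123
        assert pk.phi_from_conc(pk.conc_from_phi(phi, m2000), m2000) == pytest.approx(
            phi, rel=1e-15
        )
        with pytest.raises(DomainError):
            pk.phi_from_conc(1700.0, m2000)


class TestDrivingForces:
    def test_delta_g_plus_sign_convention(self, m2000):
        T = pk.celsius_to_kelvin(40.0)
        b = pk.compute_binodal(T, m2000)
        assert pk.delta_g_plus(b.phi_minus, T, m2000, b) == pytest.approx(0.0, abs=1e-30)
        assert pk.delta_g_plus(np.e * b.phi_minus, T, m2000, b) == pytest.approx(
            -pk.KB * T, rel=1e-12
        )
        undersat = pk.delta_g_plus(b.phi_minus / 2.0, T, m2000, b)
        assert undersat == pytest.approx(pk.KB * T * np.log(2.0), rel=1e-12)

    def test_partition_factor_hand_value_and_limits(self):
        b = pk.Binodal(300.0, 0.1, 0.5)
        assert pk.partition_factor(0.2, b) == pytest.approx(5.0 / 3.0, rel=1e-12)
        assert pk.partition_factor(0.1 + 1e-12, b) < 1e-9
        assert pk.partition_factor(0.5 - 1e-12, b) > 1e9
        with pytest.raises(DomainError):
            pk.partition_factor(0.05, b)

    def test_delta_g_minus_zero_at_binodals_negative_inside(self, m2000):
        T = pk.celsius_to_kelvin(40.0)
        b = pk.compute_binodal(T, m2000)
        assert pk.delta_g_minus(b.phi_minus, T, m2000, b) == 0.0
        assert pk.delta_g_minus(b.phi_plus, T, m2000, b) == 0.0
        mid = 0.5 * (b.phi_minus + b.phi_plus)
        assert pk.delta_g_minus(mid, T, m2000, b) < 0
        with pytest.raises(DomainError):
            pk.delta_g_minus(b.phi_plus * 1.5, T, m2000, b)

    def test_delta_g_minus_single_interior_minimum(self, m2000):
        T = pk.celsius_to_kelvin(40.0)
        b = pk.compute_binodal(T, m2000)
        phi = np.linspace(b.phi_minus, b.phi_plus, 400)[1:-1]
        dg = pk.delta_g_minus(phi, T, m2000, b)
        grad_sign = np.sign(np.diff(dg))
        changes = np.sum(np.abs(np.diff(grad_sign)) > 0)
        assert changes == 1  # decreasing then increasing: one interior minimum
        # approaches zero continuously at both ends
        assert dg[0] > dg.min() and dg[-1] > dg.min()
        assert abs(dg[0]) < 0.05 * abs(dg.min())


class TestTension:
    def test_forms_and_values(self, m2000):
        tc = 337.65
        ising = pk.TensionModel("ising_T", 1.0, Tc=tc)
        assert pk.gamma_at(tc, ising) == 0.0
        assert pk.gamma_at(312.15, ising) == pytest.approx(0.0386, abs=2e-4)
        const = pk.TensionModel("constant", 2.2e-6)
        assert pk.gamma_at(250.0, const) == 2.2e-6
        assert pk.gamma_at(400.0, const) == 2.2e-6
        with pytest.raises(DomainError):
            pk.gamma_at(tc + 1.0, ising)

    def test_binodal_gap_form_vanishes_at_tc(self, m2000):
        gap_form = pk.TensionModel("binodal_gap", 1e-4)
        _, Tc = pk.critical_point(m2000)
        g_low = pk.gamma_at(pk.celsius_to_kelvin(36.0), gap_form, m2000)
        g_high = pk.gamma_at(Tc - 0.2, gap_form, m2000)
        assert 0 < g_high < g_low  # tension collapses approaching criticality


class TestChiFitting:
    def test_zero_noise_recovery(self, m2000):
        import dataclasses

        cfg = dataclasses.replace(pk.SyntheticConfig(), binodal_rel_noise=0.0)
        pts = pk.gen_binodal_points(cfg)
        fit = pk.fit_chi_parameters(pts, 2000.0)
        assert fit.chi_entropic == pytest.approx(0.23, rel=1e-6)
        assert fit.chi_enthalpic == pytest.approx(98.8, rel=1e-6)

    def test_dense_only_weighting_runs(self):
        import dataclasses

        cfg = dataclasses.replace(pk.SyntheticConfig(seed=3), binodal_rel_noise=0.02)
        pts = pk.gen_binodal_points(cfg)
        fit = pk.fit_chi_parameters(pts, 2000.0, weighting="dense")
        _, Tc = pk.critical_point(fit)
        assert pk.kelvin_to_celsius(Tc) == pytest.approx(64.5, abs=5.0)
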