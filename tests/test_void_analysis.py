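"""Void statistics: quadrature, critical size, Poisson model, fitting."""

import numpy as np
import pytest

import phasekin as pk
from phasekin.exceptions import DomainError
from phasekin.void_analysis import integrate_rate_field

from conftest import FAST_TRANSPORT, T0, T_END


class TestRateQuadrature:
    def test_constant_rate_closed_form(self):
        # J = 1e12 in a fixed 20 um radius sphere for 100 s:
        # N = J * (4/3) pi R^3 * t = 3.351
        times = np.linspace(0.0, 100.0, 201)
        r = np.linspace(0.0, 20e-6, 101)
        frames = ((r, np.full_like(r, 1e12)) for _ in times)
        N = integrate_rate_field(times, frames)
        assert N == pytest.approx(1e12 * 4.0 / 3.0 * np.pi * (20e-6) ** 3 * 100.0, rel=1e-4)

    def test_equilibrium_trajectory_has_no_nucleation(self, m2000, kin, truth_tension):
        protocol = pk.CoolingProtocol(T0=T0, T_end=T0, rate=1.0)
        traj = pk.simulate(R0=15e-6, protocol=protocol, model=m2000, D=kin.D_plus, n_r=80)
        assert pk.expected_voids(traj, m2000, truth_tension, kin) == 0.0
        _, K = pk.nucleation_frequency(traj, m2000, truth_tension, kin)
        assert np.all(K == 0.0)

    def test_frequency_integrates_to_expected_voids(self, default_trajectory, m2000, kin, truth_tension):
        N = pk.expected_voids(default_trajectory, m2000, truth_tension, kin)
        times, K = pk.nucleation_frequency(default_trajectory, m2000, truth_tension, kin)
        assert np.all(K >= 0.0)
        assert np.trapezoid(K, times) == pytest.approx(N, rel=1e-9)
        assert N > 0

    def test_frequency_peaks_at_end_of_cooling(self, default_trajectory, m2000, kin, truth_tension):
        times, K = pk.nucleation_frequency(default_trajectory, m2000, truth_tension, kin)
        ramp = default_trajectory.protocol.ramp_duration
        t_peak = times[np.argmax(K)]
        assert 0.7 * ramp <= t_peak <= ramp + 0.25 * (times[-1] - ramp)

    def test_quadrature_resolution_convergence(self, m2000, kin, truth_tension):
        protocol = pk.CoolingProtocol(T0=T0, T_end=T_END, rate=5.0 / 60)
        coarse = pk.simulate(
            R0=15e-6, protocol=protocol, model=m2000, D=kin.D_plus,
            n_r=200, dt=0.2, store_dt=4.0,
        )
        fine = pk.simulate(
            R0=15e-6, protocol=protocol, model=m2000, D=kin.D_plus,
            n_r=400, dt=0.1, store_dt=2.0,
        )
        n_coarse = pk.expected_voids(coarse, m2000, truth_tension, kin)
        n_fine = pk.expected_voids(fine, m2000, truth_tension, kin)
        assert n_coarse == pytest.approx(n_fine, rel=0.02)


class TestPoisson:
    def test_closed_form_values(self):
        assert pk.poisson_void_probability(1.0, 1) == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert pk.poisson_void_probability(0.0, 0) == 1.0
        total = sum(pk.poisson_void_probability(2.3, n) for n in range(60))
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_band_constants(self):
        lo, hi = pk.POISSON_BAND
        assert lo == 0.242 and hi == 5.572


class TestCriticalSize:
    def test_definition_and_band_ordering(self, m2000, kin, truth_tension):
        rate = 5.0 / 60
        res = pk.critical_size(
            rate, m2000, truth_tension, kin, T0, T_END,
            compute_band=True, transport_kwargs=FAST_TRANSPORT,
        )
        assert res.band_low < res.R_crit < res.band_high
        # N evaluated at the returned size is ~ 1
        N = pk.void_expected_number(
            pk.SyntheticConfig(transport_kwargs=FAST_TRANSPORT), rate, res.R_crit
        )
        assert N == pytest.approx(1.0, rel=0.12)

    def test_expected_voids_increase_with_diameter(self, m2000, kin, truth_tension):
        cfg = pk.SyntheticConfig(transport_kwargs=FAST_TRANSPORT)
        ns = [pk.void_expected_number(cfg, 5.0 / 60, d) for d in (14e-6, 22e-6, 36e-6)]
        assert ns[0] < ns[1] < ns[2]

    def test_critical_size_decreases_with_cooling_rate(self, synthetic_critical_sizes):
        rates = sorted(synthetic_critical_sizes)
        sizes = [synthetic_critical_sizes[r] for r in rates]
        assert np.all(np.diff(sizes) < 0)

    def test_small_condensates_form_no_voids_at_slow_cooling(self, m2000, kin, truth_tension):
        cfg = pk.SyntheticConfig(transport_kwargs=FAST_TRANSPORT)
        assert pk.void_expected_number(cfg, 0.5 / 60, 18e-6) < 1e-3


class TestFitting:
    def test_records_reduce_to_mean_single_void_size(self):
        recs = [
            pk.VoidCountRecord(1.0 / 60, 20e-6, 1),
            pk.VoidCountRecord(1.0 / 60, 30e-6, 1),
            pk.VoidCountRecord(1.0 / 60, 50e-6, 3),
            pk.VoidCountRecord(5.0 / 60, 12e-6, 1),
            pk.VoidCountRecord(5.0 / 60, 40e-6, 0),
        ]
        sizes = pk.critical_sizes_from_records(recs)
        assert sizes[1.0 / 60] == pytest.approx(25e-6)
        assert sizes[5.0 / 60] == pytest.approx(12e-6)
        with pytest.raises(DomainError):
            pk.critical_sizes_from_records([pk.VoidCountRecord(1.0, 1e-6, 0)])

    def test_objective_near_zero_at_truth_and_permutation_invariant(
        self, synthetic_critical_sizes, m2000, kin
    ):
        two = dict(list(sorted(synthetic_critical_sizes.items()))[:2])
        fit = pk.fit_parameters(
            two, m2000, "constant", kin, T0, T_END,
            n_starts=3, transport_kwargs=FAST_TRANSPORT,
        )
        assert fit.objective < 0.05
        reversed_sizes = dict(reversed(list(two.items())))
        fit2 = pk.fit_parameters(
            reversed_sizes, m2000, "constant", kin, T0, T_END,
            n_starts=3, transport_kwargs=FAST_TRANSPORT,
        )
        assert fit2.gamma0 == pytest.approx(fit.gamma0, rel=1e-6)

    def test_tension_model_discrimination(self, m2000):
        # generate critical sizes under the Ising temperature scaling and
        # verify the matching form fits better than the binodal-gap scaling
        _, Tc = pk.critical_point(m2000)
        truth = pk.TensionModel("ising_T", 4.0e-5, Tc=Tc)
        kin = pk.KineticParams(theta=1.5e-10, D_plus=1.3e-13, D_minus=1.3e-10, Mw=2500.0)
        # three rates over-determine the two parameters, so only the correct
        # temperature dependence of gamma can drive the objective to zero
        tk = {"n_r": 100}
        sizes = {}
        for rate in (0.5 / 60, 2.0 / 60, 5.0 / 60):
            res = pk.critical_size(
                rate, m2000, truth, kin, T0, T_END,
                compute_band=False, transport_kwargs=tk,
            )
            sizes[rate] = res.R_crit
        fits = pk.compare_tension_forms(
            sizes, m2000, ("ising_T", "binodal_gap"), kin, T0, T_END,
            n_starts=3, transport_kwargs=tk, tension_Tc=Tc,
        )
        assert fits["ising_T"].objective < fits["binodal_gap"].objective
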