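"""Cluster thermodynamics, Zeldovich factor, attachment kinetics, rates."""

import numpy as np
import pytest

import phasekin as pk
from phasekin.constants import KB
from phasekin.exceptions import DomainError, NoBarrierError

CTX = pk.NucleationContext(
    gamma=1.8e-6, delta_g=-4e-22, vm=1.384e-23, c=6e22, T=300.0
)


class TestMolecularVolume:
    def test_hand_values(self):
        assert pk.molecular_volume(300.0, 2500.0) == pytest.approx(1.384e-23, rel=1e-3)
        assert pk.molecular_volume(0.82, 2500.0) == pytest.approx(5.06e-21, rel=1e-3)

    def test_inverse_proportionality(self):
        assert pk.molecular_volume(600.0, 2500.0) == pytest.approx(
            pk.molecular_volume(300.0, 2500.0) / 2.0, rel=1e-12
        )

    def test_zero_concentration_rejected(self):
        with pytest.raises(DomainError):
            pk.molecular_volume(0.0, 2500.0)


class TestClusterWork:
    def test_zero_at_zero_size(self):
        assert pk.cluster_work(0.0, CTX) == 0.0

    def test_argmax_is_critical_number(self):
        n_c = pk.critical_number(CTX)
        n = np.linspace(0.25 * n_c, 4.0 * n_c, 20001)
        w = pk.cluster_work(n, CTX)
        assert n[np.argmax(w)] == pytest.approx(n_c, rel=1e-3)
        # n_c also equals (4/3) pi r_c^3 / vm through the critical radius
        r_c = pk.critical_radius(CTX)
        assert 4.0 / 3.0 * np.pi * r_c**3 / CTX.vm == pytest.approx(n_c, rel=1e-12)

    def test_value_at_critical_size_is_barrier(self):
        n_c = pk.critical_number(CTX)
        assert pk.cluster_work(n_c, CTX) == pytest.approx(
            pk.critical_work(CTX), rel=1e-10
        )

    def test_no_barrier_signalled(self):
        flat = pk.NucleationContext(gamma=1.8e-6, delta_g=1e-22, vm=1e-23, c=1e22, T=300.0)
        with pytest.raises(NoBarrierError):
            pk.cluster_work(10.0, flat)


class TestBarrier:
    def test_hand_value(self):
        # gamma=1.8e-6, vm=1.38e-23, |dg|=4e-22: Wc ~ 1.16e-19 J ~ 28 kBT at 300 K
        ctx = pk.NucleationContext(1.8e-6, -4e-22, 1.38e-23, 1e22, 300.0)
        w_c = pk.critical_work(ctx)
        assert w_c == pytest.approx(1.16e-19, rel=5e-3)
        assert w_c / (KB * 300.0) == pytest.approx(28.0, abs=0.5)

    def test_scaling_in_gamma_and_delta_g(self):
        base = pk.critical_work(CTX)
        double_gamma = pk.NucleationContext(2 * CTX.gamma, CTX.delta_g, CTX.vm, CTX.c, CTX.T)
        double_dg = pk.NucleationContext(CTX.gamma, 2 * CTX.delta_g, CTX.vm, CTX.c, CTX.T)
        assert pk.critical_work(double_gamma) == pytest.approx(8 * base, rel=1e-12)
        assert pk.critical_work(double_dg) == pytest.approx(base / 4, rel=1e-12)

    def test_critical_radius(self):
        ctx = pk.NucleationContext(1.8e-6, -1e-21, 1.38e-23, 1e22, 300.0)
        assert pk.critical_radius(ctx) == pytest.approx(4.97e-8, rel=1e-2)
        # diverges as the driving force vanishes
        weak = pk.NucleationContext(1.8e-6, -1e-30, 1.38e-23, 1e22, 300.0)
        assert pk.critical_radius(weak) > 1.0

    def test_radius_in_printed_range_for_study_conditions(self):
        # gamma ~ 1.8 uJ/m^2 and |dg|/vm ~ 1e2 J/m^3 put r_c in 10-100 nm
        for dg_over_vm in (50.0, 100.0, 300.0):
            r_c = 2.0 * 1.8e-6 / dg_over_vm
            assert 1e-8 <= r_c <= 1e-7


class TestZeldovich:
    def test_matches_finite_difference_of_cluster_work(self):
        n_c = pk.critical_number(CTX)
        h = n_c * 1e-4
        w = lambda n: pk.cluster_work(n, CTX)
        d2 = (w(n_c + h) - 2.0 * w(n_c) + w(n_c - h)) / h**2
        z_fd = np.sqrt(-d2 / (2.0 * np.pi * KB * CTX.T))
        assert pk.zeldovich(CTX) == pytest.approx(z_fd, rel=1e-6)

    def test_decreases_with_gamma(self):
        z1 = pk.zeldovich(CTX)
        z2 = pk.zeldovich(
            pk.NucleationContext(2 * CTX.gamma, CTX.delta_g, CTX.vm, CTX.c, CTX.T)
        )
        assert z2 < z1


class TestAttachment:
    def test_dual_formula_identity(self):
        # (48 pi^2 vm)^(1/3) c D n_c^(1/3)  ==  8 pi c D gamma vm / |dg|
        D = 1.3e-10
        ctx = pk.NucleationContext(1.8e-6, -4e-22, 5.06e-21, 1.98e20, 300.0)
        f_c = pk.attachment_frequency(ctx, D)
        explicit = (
            (48.0 * np.pi**2 * ctx.vm) ** (1.0 / 3.0)
            * ctx.c
            * D
            * pk.critical_number(ctx) ** (1.0 / 3.0)
        )
        collapsed = 8.0 * np.pi * ctx.c * D * ctx.gamma * ctx.vm / abs(ctx.delta_g)
        assert f_c == pytest.approx(explicit, rel=1e-12)
        assert f_c == pytest.approx(collapsed, rel=1e-10)

    def test_linear_in_concentration(self):
        D = 1e-10
        double_c = pk.NucleationContext(CTX.gamma, CTX.delta_g, CTX.vm, 2 * CTX.c, CTX.T)
        assert pk.attachment_frequency(double_c, D) == pytest.approx(
            2.0 * pk.attachment_frequency(CTX, D), rel=1e-12
        )


class TestNucleationRate:
    KIN = pk.KineticParams(theta=1.0, D_plus=1.3e-13, D_minus=1.3e-10)

    def test_zero_without_driving_force(self):
        ctx = pk.NucleationContext(1.8e-6, 1e-22, 1e-23, 1e22, 300.0)
        assert pk.nucleation_rate(ctx, self.KIN, "void") == 0.0
        ctx0 = pk.NucleationContext(1.8e-6, 0.0, 1e-23, 1e22, 300.0)
        assert pk.nucleation_rate(ctx0, self.KIN, "condensate") == 0.0

    def test_product_equals_collapsed_form(self):
        # theta z f_c rho_m exp(-Wc/kT) == theta D c sqrt(dg^2/(vm^2 gamma kT)) exp(-Wc/kT)
        ctx = CTX
        D = self.KIN.D_plus
        kT = KB * ctx.T
        product = (
            pk.zeldovich(ctx)
            * pk.attachment_frequency(ctx, D)
            / ctx.vm
            * np.exp(-pk.critical_work(ctx) / kT)
        )
        collapsed = (
            D
            * ctx.c
            * np.sqrt(ctx.delta_g**2 / (ctx.vm**2 * ctx.gamma * kT))
            * np.exp(-pk.critical_work(ctx) / kT)
        )
        assert product == pytest.approx(collapsed, rel=1e-10)
        assert pk.nucleation_rate(ctx, self.KIN, "void") == pytest.approx(
            product, rel=1e-10
        )

    def test_collapsed_identity_over_random_sweep(self):
        rng = np.random.default_rng(42)
        n = 10_000
        gamma = 10 ** rng.uniform(-7, -2, n)
        dg = -(10 ** rng.uniform(-23, -19, n))
        vm = 10 ** rng.uniform(-27, -21, n)
        c = 10 ** rng.uniform(18, 25, n)
        T = rng.uniform(270.0, 370.0, n)
        kT = KB * T
        w_c = 16.0 * np.pi / 3.0 * gamma**3 * vm**2 / dg**2
        ln_collapsed = (
            np.log(1.0 * 1e-10 * c) + np.log(-dg / vm) - 0.5 * np.log(gamma * kT) - w_c / kT
        )
        ln_j = pk.log_nucleation_rate(gamma, dg, vm, c, T, 1e-10, 1.0)
        assert np.allclose(ln_j, ln_collapsed, rtol=1e-10, atol=1e-8)

    def test_length_rescaling_scales_rate_as_inverse_volume(self):
        # multiplying all lengths by lambda: vm -> l^3 vm, c -> c/l^3,
        # D -> l^2 D, gamma -> gamma/l^2  =>  J -> J / l^3
        lam = 3.7
        ctx = CTX
        base = pk.log_nucleation_rate(
            ctx.gamma, ctx.delta_g, ctx.vm, ctx.c, ctx.T, 1.3e-13, 1.0
        )
        scaled = pk.log_nucleation_rate(
            ctx.gamma / lam**2,
            ctx.delta_g,
            ctx.vm * lam**3,
            ctx.c / lam**3,
            ctx.T,
            1.3e-13 * lam**2,
            1.0,
        )
        assert float(scaled - base) == pytest.approx(-3.0 * np.log(lam), rel=1e-9)

    def test_monotone_in_driving_force_and_tension(self):
        dg = -np.geomspace(1e-22, 1e-20, 50)
        ln_j = pk.log_nucleation_rate(1.8e-6, dg, 1.4e-23, 1e22, 300.0, 1e-13, 1.0)
        assert np.all(np.diff(ln_j) > 0)  # increasing in |dg|
        gam = np.geomspace(1e-7, 1e-4, 50)
        ln_j2 = pk.log_nucleation_rate(gam, -4e-22, 1.4e-23, 1e22, 300.0, 1e-13, 1.0)
        assert np.all(np.diff(ln_j2) < 0)  # decreasing in gamma

    def test_negative_tension_rejected(self):
        with pytest.raises(DomainError):
            pk.log_nucleation_rate(-1e-6, -4e-22, 1e-23, 1e22, 300.0, 1e-13, 1.0)
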