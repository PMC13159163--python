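"""Shared fixtures: study-condition models and the heavier simulations.

Session-scoped fixtures hold the objects several test modules reuse, in
particular the synthetic critical-size study (four cooling rates, truth
parameters gamma0 = 1.8 uJ/m^2 and theta = 1.5e-10) that both the
end-to-end recovery and the monotonicity checks consume.
"""

from __future__ import annotations

import pytest

import phasekin as pk

#: Reduced transport resolution for tests that run many simulations; the
#: same settings are used for generation and fitting so recovery checks are
#: self-consistent.
FAST_TRANSPORT = {"n_r": 120}

TRUTH_GAMMA0 = 1.8e-6
TRUTH_THETA = 1.5e-10
D_PLUS = 1.3e-13
T0 = pk.celsius_to_kelvin(55.0)
T_END = pk.celsius_to_kelvin(36.0)
COOLING_RATES = (0.5 / 60, 1.0 / 60, 2.0 / 60, 5.0 / 60)  # K/s


@pytest.fixture(scope="session")
def m2000() -> pk.PhaseModel:
    return pk.PHASE_PRESETS["m2000"]


@pytest.fixture(scope="session")
def kin() -> pk.KineticParams:
    return pk.KineticParams(
        theta=TRUTH_THETA, D_plus=D_PLUS, D_minus=1000.0 * D_PLUS, Mw=2500.0
    )


@pytest.fixture(scope="session")
def truth_tension() -> pk.TensionModel:
    return pk.TensionModel("constant", TRUTH_GAMMA0)


@pytest.fixture(scope="session")
def default_trajectory(m2000) -> pk.CondensateTrajectory:
    """20 um condensate cooled 55 -> 36 C at 5 K/min, default resolution."""
    protocol = pk.CoolingProtocol(T0=T0, T_end=T_END, rate=5.0 / 60)
    return pk.simulate(R0=20e-6, protocol=protocol, model=m2000, D=D_PLUS)


@pytest.fixture(scope="session")
def synthetic_critical_sizes(m2000, kin, truth_tension) -> dict[float, float]:
    """Critical diameters per cooling rate generated from the truth parameters."""
    sizes = {}
    for rate in COOLING_RATES:
        res = pk.critical_size(
            rate,
            m2000,
            truth_tension,
            kin,
            T0,
            T_END,
            compute_band=False,
            transport_kwargs=FAST_TRANSPORT,
        )
        sizes[rate] = res.R_crit
    return sizes
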