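"""Condensate-nucleation predictions from interfacial tension.

Covers four uses of the condensate nucleation rate J_cond:

* a lower bound on the experimental rate from microdroplet condensate
  counts (nuclei per volume formed within a known time window);
* the supercooling sweep J_cond(Delta T) for a solution of fixed
  composition cooled below the temperature at which it sits exactly on
  the dilute binodal;
* the minimum driving force Delta g_min at which a system with tension
  gamma nucleates at the rapid rate J = 1e12 m^-3 s^-1, evaluated across a
  tension atlas of condensate and solid systems;
* the expected number of nuclei in a cell-sized volume and the
  surface-area consequences of changing the nucleus number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cnt_rates import KineticParams, log_nucleation_rate, molecular_volume
from .constants import KB, N_A, RAPID_NUCLEATION_RATE
from .exceptions import BracketError, DomainError
from .phase_thermo import (
    PhaseModel,
    TensionModel,
    binodal_curve,
    critical_point,
    gamma_at,
)

__all__ = [
    "DropletCount",
    "AtlasEntry",
    "CellScenario",
    "ATLAS_DEFAULTS",
    "droplet_rate_lower_bound",
    "supercooling_curve",
    "first_crossing",
    "delta_g_min",
    "atlas_delta_g_min",
    "cell_nuclei",
    "surface_area_factor",
]


@dataclass(frozen=True)
class DropletCount:
    """Condensate count density (m^-3) observed within a formation window (s)."""

    count_density: float
    window: float

    def __post_init__(self) -> None:
        if self.count_density < 0 or self.window <= 0:
            raise DomainError("count density must be >= 0 and window > 0")


@dataclass(frozen=True)
class AtlasEntry:
    """One system of the interfacial-tension atlas.

    ``klass`` is 'condensate' or 'solid'; ``phi`` is the dense-phase volume
    fraction used for the molecular volume (0.2 for condensates, 0.5 for
    solids by default).
    """

    system: str
    gamma_low: float  # J m^-2
    gamma_high: float  # J m^-2
    Mw: float  # kg mol^-1
    klass: str
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.gamma_low > self.gamma_high:
            raise DomainError("gamma_low must not exceed gamma_high")
        if self.klass not in ("condensate", "solid"):
            raise DomainError("klass must be 'condensate' or 'solid'")

    @property
    def phi_used(self) -> float:
        if self.phi is not None:
            return self.phi
        return 0.2 if self.klass == "condensate" else 0.5


@dataclass(frozen=True)
class CellScenario:
    """Cell-scale nucleation scenario: diameter, solute diffusivity, tension."""

    d_cell: float  # m
    D: float  # m^2 s^-1
    gamma: float  # J m^-2

    @property
    def V(self) -> float:
        """Cell volume assuming spherical geometry, (pi/6) d^3."""
        return np.pi / 6.0 * self.d_cell**3

    @property
    def dt(self) -> float:
        """Driving-force depletion time d^2 / (6 D)."""
        return self.d_cell**2 / (6.0 * self.D)


#: Single shared parameter set used for every atlas system: dilute mass
#: concentration 1 mg/mL, T = 300 K, solute density 1.5 g/mL, D = 1e-10
#: m^2/s, theta = 1 (homogeneous, diffusion-limited nucleation).
ATLAS_DEFAULTS = {
    "mass_conc": 1.0,  # kg m^-3
    "T": 300.0,  # K
    "rho_solute": 1500.0,  # kg m^-3
    "D": 1e-10,  # m^2 s^-1
    "theta": 1.0,
}


def droplet_rate_lower_bound(dc: DropletCount) -> float:
    """Nucleation-rate lower bound J >= count_density / window (m^-3 s^-1).

    A lower bound because growth of the first nuclei depletes the solution
    and slows later nucleation, and nuclei may coalesce before counting.
    """
    return dc.count_density / dc.window


def supercooling_curve(
    model: PhaseModel,
    tension: TensionModel,
    kin: KineticParams,
    c0: float,
    T_ref: float,
    dT_max: float = 6.0,
    resolution: float = 0.003,
    phi0: float | None = None,
) -> pd.DataFrame:
    """Condensate nucleation rate versus supercooling Delta T below T_ref.

    Models a solution of constant composition cooled from the reference
    temperature: by default the composition sits exactly on the dilute
    binodal at T_ref (phi0 = phi_-(T_ref)), so Delta T = 0 is the binodal
    crossing and the supersaturation at T = T_ref - Delta T is
    S = phi0 / phi_-(T) with Delta g_+ = -kB T ln S. The measured dilute
    mass concentration ``c0`` (kg m^-3) enters the rate prefactor only; an
    explicit ``phi0`` overrides the binodal-referenced composition. The
    dense molecular volume v_m,+ and gamma(T) are recomputed at each grid
    temperature.

    Returns a DataFrame with columns delta_T_C, T_K, phi_minus, S,
    delta_g_J (per molecule), delta_g_kJ_per_mol, and J_cond (m^-3 s^-1).
    """
    _, Tc = critical_point(model)
    if T_ref >= Tc:
        raise DomainError("reference temperature must lie below Tc")
    if c0 <= 0:
        raise DomainError("c0 must be positive")
    dT = np.arange(0.0, dT_max + 0.5 * resolution, resolution)
    T = T_ref - dT
    lo, hi = binodal_curve(T, model)
    if phi0 is None:
        phi0 = float(lo[0])  # composition pinned to the binodal at T_ref
    S = phi0 / lo
    delta_g = -KB * T * np.log(S)
    vm_plus = molecular_volume(hi * model.rho_solute, kin.Mw)
    gamma = np.asarray(gamma_at(T, tension, model), dtype=float)
    c_num = c0 * N_A / kin.Mw
    ln_j = log_nucleation_rate(gamma, delta_g, vm_plus, c_num, T, kin.D_minus, kin.theta)
    J = np.where(np.isfinite(ln_j), np.exp(np.clip(ln_j, -700.0, 700.0)), 0.0)
    return pd.DataFrame(
        {
            "delta_T_C": dT,
            "T_K": T,
            "phi_minus": lo,
            "S": S,
            "delta_g_J": delta_g,
            "delta_g_kJ_per_mol": delta_g * N_A / 1e3,
            "J_cond": J,
        }
    )


def first_crossing(
    curve: pd.DataFrame, threshold: float = RAPID_NUCLEATION_RATE
) -> float:
    """Smallest supercooling (deg C) at which J_cond reaches ``threshold``."""
    mask = curve["J_cond"].to_numpy() >= threshold
    if not mask.any():
        raise BracketError(
            f"J_cond never reaches {threshold:.3g} m^-3 s^-1 on the sweep"
        )
    return float(curve["delta_T_C"].to_numpy()[np.argmax(mask)])


def delta_g_min(
    gamma: float,
    Mw: float,
    phi: float = 0.2,
    mass_conc: float = ATLAS_DEFAULTS["mass_conc"],
    T: float = ATLAS_DEFAULTS["T"],
    rho_solute: float = ATLAS_DEFAULTS["rho_solute"],
    D: float = ATLAS_DEFAULTS["D"],
    theta: float = ATLAS_DEFAULTS["theta"],
    rate_threshold: float = RAPID_NUCLEATION_RATE,
) -> float:
    """Driving force magnitude (J mol^-1) at which J(gamma, dg) = rate_threshold.

    Bracketed root finding on ln J, which is strictly increasing in |dg|;
    v_m comes from the dense-phase concentration phi * rho_solute and the
    parent-phase number concentration from ``mass_conc``.
    """
    if gamma <= 0:
        raise DomainError("gamma must be positive")
    vm = molecular_volume(phi * rho_solute, Mw)
    c_num = mass_conc * N_A / Mw

    def f(dg_mag: float) -> float:
        return float(
            log_nucleation_rate(gamma, -dg_mag, vm, c_num, T, D, theta)
        ) - np.log(rate_threshold)

    lo, hi = 1e-26, 1e-17
    f_lo, f_hi = f(lo), f(hi)
    for _ in range(10):
        if f_lo < 0:
            break
        lo *= 1e-2
        f_lo = f(lo)
    for _ in range(10):
        if f_hi > 0:
            break
        hi *= 10.0
        f_hi = f(hi)
    if not (f_lo < 0 < f_hi):
        raise BracketError("could not bracket the rapid-nucleation driving force")
    root = brentq(f, lo, hi, xtol=1e-30, rtol=1e-12)
    return float(root * N_A)


def atlas_delta_g_min(
    entries: list[AtlasEntry] | pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Delta g_min per atlas system, at the low and high ends of its gamma range.

    Accepts a list of ``AtlasEntry`` or a DataFrame with columns system,
    gamma_low, gamma_high, Mw, klass (and optional phi). Returns a DataFrame
    with delta_g_min in kJ/mol; ``kwargs`` override the atlas defaults.
    """
    if isinstance(entries, pd.DataFrame):
        entries = [
            AtlasEntry(
                system=row["system"],
                gamma_low=row["gamma_low"],
                gamma_high=row["gamma_high"],
                Mw=row["Mw"],
                klass=row["klass"],
                phi=row.get("phi") if isinstance(row.get("phi"), float) else None,
            )
            for _, row in entries.iterrows()
        ]
    rows = []
    for e in entries:
        lo = delta_g_min(e.gamma_low, e.Mw, phi=e.phi_used, **kwargs)
        hi = delta_g_min(e.gamma_high, e.Mw, phi=e.phi_used, **kwargs)
        rows.append(
            {
                "system": e.system,
                "klass": e.klass,
                "Mw_kg_per_mol": e.Mw,
                "gamma_low_J_per_m2": e.gamma_low,
                "gamma_high_J_per_m2": e.gamma_high,
                "delta_g_min_low_kJ_per_mol": lo / 1e3,
                "delta_g_min_high_kJ_per_mol": hi / 1e3,
            }
        )
    return pd.DataFrame(rows)


def cell_nuclei(
    scn: CellScenario,
    delta_g: float,
    Mw: float,
    phi: float = 0.2,
    mass_conc: float = ATLAS_DEFAULTS["mass_conc"],
    T: float = ATLAS_DEFAULTS["T"],
    rho_solute: float = ATLAS_DEFAULTS["rho_solute"],
    theta: float = ATLAS_DEFAULTS["theta"],
) -> float:
    """Expected nuclei in a cell, N = J(gamma, delta_g) * V * Delta t.

    ``delta_g`` is the signed per-molecule driving force (J); Delta t is the
    diffusive depletion time d^2/(6 D) of the scenario. In the
    barrier-dominated regime N is extremely sensitive to gamma.
    """
    if delta_g >= 0:
        return 0.0
    vm = molecular_volume(phi * rho_solute, Mw)
    c_num = mass_conc * N_A / Mw
    ln_j = float(
        log_nucleation_rate(scn.gamma, delta_g, vm, c_num, T, scn.D, theta)
    )
    if not np.isfinite(ln_j) or ln_j < -700.0:
        return 0.0
    return float(np.exp(ln_j) * scn.V * scn.dt)


def surface_area_factor(n_ratio: float) -> float:
    """Total surface-area ratio when the nucleus count changes at fixed mass.

    n-fold more condensates of the same total mass are n^(1/3)-fold smaller
    in diameter and expose n^(1/3)-fold more total surface area.
    """
    if n_ratio <= 0:
        raise DomainError("count ratio must be positive")
    return float(n_ratio ** (1.0 / 3.0))
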