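"""Flory-Huggins thermodynamics of a binary polymer-solvent mixture.

This module owns the mean-field free energy of a polymer solution,

    f(phi, T) / (kB T) = phi ln(phi) / M + (1 - phi) ln(1 - phi)
                         + chi(T) phi (1 - phi),

with an upper-critical-solution-temperature interaction parameter
chi(T) = A + B/T, the coexistence (binodal) compositions obtained by the
common-tangent construction, the closed-form critical point, conversions
between volume fraction and mass concentration, the per-molecule nucleation
driving forces for condensate formation (Delta g_plus) and for void
formation inside a condensate (Delta g_minus), and the interfacial-tension
models used by the nucleation-rate machinery.

All quantities are strict SI internally (K, kg, m, J); degrees Celsius
appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import KB
from .exceptions import ConvergenceError, DomainError

__all__ = [
    "PhaseModel",
    "Binodal",
    "TensionModel",
    "BinodalPoint",
    "free_energy_density",
    "per_molecule_free_energy",
    "compute_binodal",
    "binodal_curve",
    "critical_point",
    "phi_from_conc",
    "conc_from_phi",
    "delta_g_plus",
    "partition_factor",
    "delta_g_minus",
    "gamma_at",
    "fit_chi_parameters",
]

#: Critical exponent of the Ising-universality interfacial-tension scaling
#: gamma(T) = gamma0 ((Tc - T)/Tc)^1.26.
ISING_TENSION_EXPONENT = 1.26

#: Exponent of the binodal-gap tension scaling gamma = gamma0 (phi_+ - phi_-)^3.9.
BINODAL_GAP_EXPONENT = 3.9


@dataclass(frozen=True)
class PhaseModel:
    """Flory-Huggins parameterization of one polymer-solvent system.

    Parameters
    ----------
    chain_length :
        Effective chain length M (number of lattice segments per polymer).
    chi_entropic :
        Temperature-independent (entropic) part A of chi(T) = A + B/T.
    chi_enthalpic :
        Enthalpic coefficient B (kelvin) of chi(T) = A + B/T.
    rho_solute :
        Solute mass density (kg m^-3) used to convert volume fractions to
        mass concentrations; 1600 kg m^-3 is a standard RNA density.
    """

    chain_length: float
    chi_entropic: float
    chi_enthalpic: float
    rho_solute: float = 1600.0

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise DomainError(f"chain length must be >= 1, got {self.chain_length}")
        if self.rho_solute <= 0:
            raise DomainError("solute density must be positive")

    def chi(self, T):
        """Interaction parameter chi(T) = A + B/T (T in kelvin)."""
        T = np.asarray(T, dtype=float)
        if np.any(T <= 0):
            raise DomainError("temperature must be positive (kelvin)")
        return self.chi_entropic + self.chi_enthalpic / T


@dataclass(frozen=True)
class Binodal:
    """Coexisting compositions at one temperature: dilute phi_- <= dense phi_+."""

    T: float
    phi_minus: float
    phi_plus: float

    @property
    def gap(self) -> float:
        return self.phi_plus - self.phi_minus


@dataclass(frozen=True)
class TensionModel:
    """Interfacial tension gamma(T) between the dense and dilute phases.

    ``form`` selects between a temperature-independent tension, the Ising
    temperature scaling gamma0 ((Tc-T)/Tc)^1.26, and the binodal-gap scaling
    gamma0 (phi_+(T) - phi_-(T))^3.9.
    """

    form: str  # {"constant", "ising_T", "binodal_gap"}
    gamma0: float
    Tc: float | None = None
    exponent: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.form not in ("constant", "ising_T", "binodal_gap"):
            raise DomainError(f"unknown tension form {self.form!r}")
        if self.gamma0 < 0:
            raise DomainError("gamma0 must be non-negative")
        if self.exponent is None:
            default = {
                "constant": 0.0,
                "ising_T": ISING_TENSION_EXPONENT,
                "binodal_gap": BINODAL_GAP_EXPONENT,
            }[self.form]
            object.__setattr__(self, "exponent", default)
        if self.form == "ising_T" and self.Tc is None:
            raise DomainError("ising_T tension requires a critical temperature Tc")


@dataclass(frozen=True)
class BinodalPoint:
    """One experimental (or synthetic) coexistence measurement."""

    T: float  # kelvin
    phase: str  # {"dense", "dilute"}
    conc: float  # mass concentration, kg m^-3
    sigma: float = 0.0  # measurement noise scale, kg m^-3

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise DomainError("concentration must be positive")
        if self.phase not in ("dense", "dilute"):
            raise DomainError(f"phase must be 'dense' or 'dilute', got {self.phase!r}")


# ----------------------------------------------------------------------------
# Free energy and derivatives
# ----------------------------------------------------------------------------


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x ln x with the limit value 0 at x = 0 (shape-preserving)."""
    safe = np.where(x > 0, x, 1.0)
    return np.where(x > 0, x * np.log(safe), 0.0)


def free_energy_density(phi, T, model: PhaseModel):
    """Mixing free energy per lattice site, in units of kB T.

    Both entropy terms take their limit value 0 at phi = 0 and phi = 1.
    Accepts scalars or arrays; phi must lie in [0, 1].
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise DomainError("volume fraction must lie in [0, 1]")
    chi = model.chi(T)
    f = (
        _xlogx(phi) / model.chain_length
        + _xlogx(1.0 - phi)
        + chi * phi * (1.0 - phi)
    )
    return f if f.ndim else float(f)


def _df_dphi(phi, T, model: PhaseModel):
    """d f / d phi in kB T units (valid for 0 < phi < 1)."""
    phi = np.asarray(phi, dtype=float)
    chi = model.chi(T)
    M = model.chain_length
    return (np.log(phi) + 1.0) / M - np.log(1.0 - phi) - 1.0 + chi * (1.0 - 2.0 * phi)


def _d2f_dphi2(phi, T, model: PhaseModel):
    """d^2 f / d phi^2 in kB T units."""
    phi = np.asarray(phi, dtype=float)
    chi = model.chi(T)
    return 1.0 / (model.chain_length * phi) + 1.0 / (1.0 - phi) - 2.0 * chi


def per_molecule_free_energy(phi, T, model: PhaseModel):
    """Free energy per solute molecule, g = f M / phi (kB T units).

    Diverges only logarithmically as phi -> 0; phi = 0 itself is rejected.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise DomainError("per-molecule free energy requires phi > 0")
    g = free_energy_density(phi, T, model) * model.chain_length / phi
    return g if np.ndim(g) else float(g)


# ----------------------------------------------------------------------------
# Critical point and binodal construction
# ----------------------------------------------------------------------------


def critical_point(model: PhaseModel) -> tuple[float, float]:
    """Closed-form Flory-Huggins critical point (phi_c, T_c).

    phi_c = 1/(1 + sqrt(M)), chi_c = (1 + 1/sqrt(M))^2 / 2, and T_c solves
    A + B/T = chi_c. Raises if chi(T) never reaches chi_c at positive T.
    """
    if model.chi_enthalpic == 0:
        raise DomainError("B = 0: chi is temperature independent, no critical point")
    sqrt_m = np.sqrt(model.chain_length)
    phi_c = 1.0 / (1.0 + sqrt_m)
    chi_c = 0.5 * (1.0 + 1.0 / sqrt_m) ** 2
    T_c = model.chi_enthalpic / (chi_c - model.chi_entropic)
    if T_c <= 0:
        raise DomainError(
            "no finite critical temperature: chi(T) never reaches chi_c "
            f"(A={model.chi_entropic}, B={model.chi_enthalpic}, chi_c={chi_c:.4f})"
        )
    return float(phi_c), float(T_c)


def _composition_grid(phi_c: float, n: int = 4000) -> np.ndarray:
    """Grid for the convex-hull construction.

    Logarithmic in phi near zero (down to 1e-12) so the tiny dilute binodal
    of long chains is resolved, linear from phi_c to 1.
    """
    n_log = n // 2
    log_part = np.geomspace(1e-12, phi_c, n_log, endpoint=False)
    lin_part = np.linspace(phi_c, 1.0 - 1e-9, n - n_log)
    return np.concatenate([log_part, lin_part])


def _lower_hull_gap(phi: np.ndarray, f: np.ndarray) -> tuple[float, float] | None:
    """Endpoints of the widest lower-convex-hull facet that skips grid points.

    Monotone-chain lower hull of the (phi, f) graph; the common-tangent
    facet is the hull edge spanning the concave (two-phase) region.
    """
    hull: list[int] = []
    for i in range(len(phi)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (phi[b] - phi[a]) * (f[i] - f[a]) - (f[b] - f[a]) * (phi[i] - phi[a])
            if cross <= 0:  # b is above (or on) segment a-i: not lower-convex
                hull.pop()
            else:
                break
        hull.append(i)
    best = None
    best_gap = 0.0
    for a, b in zip(hull[:-1], hull[1:]):
        if b - a > 1:  # facet skips interior grid points -> miscibility gap
            gap = phi[b] - phi[a]
            if gap > best_gap:
                best_gap = gap
                best = (float(phi[a]), float(phi[b]))
    return best


def _tangent_residual(x: np.ndarray, T: float, model: PhaseModel) -> np.ndarray:
    lo, hi = x
    f_lo = free_energy_density(lo, T, model)
    f_hi = free_energy_density(hi, T, model)
    d_lo = _df_dphi(lo, T, model)
    d_hi = _df_dphi(hi, T, model)
    return np.array([d_lo - d_hi, f_hi - f_lo - d_lo * (hi - lo)])


def _newton_tangent(
    model: PhaseModel, T: float, guess: tuple[float, float], max_iter: int = 80
) -> tuple[float, float] | None:
    """Newton refinement of the equal-chemical-potential / equal-tangent system."""
    lo, hi = guess
    for _ in range(max_iter):
        F = _tangent_residual(np.array([lo, hi]), T, model)
        d2_lo = float(_d2f_dphi2(lo, T, model))
        d2_hi = float(_d2f_dphi2(hi, T, model))
        d_lo = float(_df_dphi(lo, T, model))
        d_hi = float(_df_dphi(hi, T, model))
        J = np.array(
            [
                [d2_lo, -d2_hi],
                [-d2_lo * (hi - lo), d_hi - d_lo],
            ]
        )
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        scale = 1.0
        for _damp in range(60):
            new_lo = lo + scale * step[0]
            new_hi = hi + scale * step[1]
            if 0.0 < new_lo < new_hi < 1.0:
                break
            scale *= 0.5
        else:
            return None
        lo, hi = new_lo, new_hi
        if np.max(np.abs(F)) < 1e-14 and scale * np.max(np.abs(step)) < 1e-13:
            break
    F = _tangent_residual(np.array([lo, hi]), T, model)
    if np.max(np.abs(F)) > 1e-9:
        return None
    return float(lo), float(hi)


def compute_binodal(T: float, model: PhaseModel, grid_size: int = 4000) -> Binodal:
    """Coexisting compositions at temperature T by the common-tangent rule.

    The initial bracket comes from the convex hull (lower envelope) of the
    free energy evaluated on a composition grid; the facet endpoints are then
    refined by Newton iteration on the equal-tangent conditions. At and above
    the critical temperature the degenerate binodal (phi_c, phi_c) is
    returned so that temperature sweeps are loop-safe.
    """
    phi_c, T_c = critical_point(model)
    if T >= T_c:
        return Binodal(float(T), phi_c, phi_c)
    grid = _composition_grid(phi_c, grid_size)
    f = free_energy_density(grid, T, model)
    guess = _lower_hull_gap(grid, np.asarray(f))
    if guess is None:
        # Gap narrower than the grid: perturb around phi_c instead.
        guess = (phi_c * 0.5, phi_c + 0.5 * (1.0 - phi_c) * 1e-2)
    refined = _newton_tangent(model, T, guess)
    if refined is None:
        refined = _newton_tangent(model, T, guess, max_iter=200)
    if refined is None:
        raise ConvergenceError(f"binodal refinement failed at T={T} K")
    lo, hi = refined
    return Binodal(float(T), lo, hi)


def binodal_curve(
    temperatures, model: PhaseModel, grid_size: int = 4000
) -> tuple[np.ndarray, np.ndarray]:
    """Binodal compositions along a temperature array, by Newton continuation.

    The coldest temperature is solved from scratch (convex hull), and each
    subsequent temperature is warm-started from the previous solution, which
    makes dense temperature sweeps cheap. Returns (phi_minus, phi_plus)
    arrays aligned with ``temperatures``.
    """
    T_arr = np.atleast_1d(np.asarray(temperatures, dtype=float))
    order = np.argsort(T_arr)
    phi_c, T_c = critical_point(model)
    lo_out = np.empty_like(T_arr)
    hi_out = np.empty_like(T_arr)
    prev: tuple[float, float] | None = None
    for idx in order:
        T = T_arr[idx]
        if T >= T_c:
            lo_out[idx] = hi_out[idx] = phi_c
            prev = None
            continue
        sol = _newton_tangent(model, T, prev) if prev is not None else None
        if sol is None or not (0.0 < sol[0] < sol[1] < 1.0):
            b = compute_binodal(T, model, grid_size)
            sol = (b.phi_minus, b.phi_plus)
        lo_out[idx], hi_out[idx] = sol
        prev = sol
    return lo_out, hi_out


# ----------------------------------------------------------------------------
# Concentration conversions
# ----------------------------------------------------------------------------


def phi_from_conc(conc, model: PhaseModel):
    """Volume fraction from mass concentration (kg m^-3): phi = c / rho."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or np.any(conc > model.rho_solute):
        raise DomainError("mass concentration must lie in [0, rho_solute]")
    phi = conc / model.rho_solute
    return phi if phi.ndim else float(phi)


def conc_from_phi(phi, model: PhaseModel):
    """Mass concentration (kg m^-3) from volume fraction: c = phi rho."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise DomainError("volume fraction must lie in [0, 1]")
    conc = phi * model.rho_solute
    return conc if conc.ndim else float(conc)


# ----------------------------------------------------------------------------
# Nucleation driving forces
# ----------------------------------------------------------------------------


def delta_g_plus(phi, T: float, model: PhaseModel, binodal: Binodal | None = None):
    """Driving force for condensate nucleation from dilute solution (J/molecule).

    Delta g_+ = -kB T ln(phi / phi_-(T)); negative iff the solution is
    supersaturated (phi > phi_-). Pass a precomputed ``binodal`` to avoid
    reconstructing it in sweeps.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise DomainError("delta_g_plus requires phi > 0")
    if binodal is None:
        binodal = compute_binodal(T, model)
    out = -KB * T * np.log(phi / binodal.phi_minus)
    return out if out.ndim else float(out)


def partition_factor(phi, binodal: Binodal):
    """Partition factor K = (1/phi - 1/phi_-) / (1/phi_+ - 1/phi).

    Ratio of dense-phase to void-phase molecule counts that conserves both
    solute and solvent in the control volume; defined for phi strictly
    between the binodal compositions.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= binodal.phi_minus) or np.any(phi >= binodal.phi_plus):
        raise DomainError("partition factor requires phi_- < phi < phi_+")
    K = (1.0 / phi - 1.0 / binodal.phi_minus) / (1.0 / binodal.phi_plus - 1.0 / phi)
    return K if K.ndim else float(K)


def delta_g_minus(phi, T: float, model: PhaseModel, binodal: Binodal | None = None):
    """Driving force for void nucleation inside a condensate (J/molecule).

    Delta g_- = [g(phi_-) - g(phi)] + K(phi) [g(phi_+) - g(phi)], converted
    from kB T units to joules. It vanishes at both binodal compositions and
    is negative in between (phase separation favorable). phi outside
    [phi_-, phi_+] is a domain error.
    """
    phi = np.asarray(phi, dtype=float)
    if binodal is None:
        binodal = compute_binodal(T, model)
    lo, hi = binodal.phi_minus, binodal.phi_plus
    span = hi - lo
    tol = 1e-9 * max(span, 1e-30) + 1e-15
    if np.any(phi < lo - tol) or np.any(phi > hi + tol):
        raise DomainError("delta_g_minus requires phi within [phi_-, phi_+]")
    phi_cl = np.clip(phi, lo, hi)
    scalar = phi_cl.ndim == 0
    phi_cl = np.atleast_1d(phi_cl)
    out = np.zeros_like(phi_cl)
    interior = (phi_cl - lo > tol) & (hi - phi_cl > tol)
    if np.any(interior):
        p = phi_cl[interior]
        g_p = per_molecule_free_energy(p, T, model)
        g_lo = per_molecule_free_energy(lo, T, model)
        g_hi = per_molecule_free_energy(hi, T, model)
        K = (1.0 / p - 1.0 / lo) / (1.0 / hi - 1.0 / p)
        out[interior] = ((g_lo - g_p) + K * (g_hi - g_p)) * KB * T
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------------------
# Interfacial tension models
# ----------------------------------------------------------------------------


def gamma_at(T, tension: TensionModel, model: PhaseModel | None = None):
    """Interfacial tension gamma(T) in J m^-2 for the selected model form.

    The scaling forms vanish at the critical temperature and are undefined
    above it (domain error); the constant form ignores temperature. The
    binodal-gap form needs the phase model to evaluate phi_+(T) - phi_-(T).
    """
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    scalar = np.ndim(T) == 0
    if tension.form == "constant":
        out = np.full_like(T_arr, tension.gamma0)
        return float(out[0]) if scalar else out
    if tension.form == "ising_T":
        Tc = tension.Tc
        if Tc is None and model is not None:
            Tc = critical_point(model)[1]
        if np.any(T_arr > Tc):
            raise DomainError("ising_T tension is undefined above Tc")
        out = tension.gamma0 * ((Tc - T_arr) / Tc) ** tension.exponent
        return float(out[0]) if scalar else out
    # binodal_gap
    if model is None:
        raise DomainError("binodal_gap tension requires a PhaseModel")
    _, Tc = critical_point(model)
    if tension.Tc is not None and np.any(T_arr > tension.Tc):
        raise DomainError("binodal_gap tension is undefined above Tc")
    lo, hi = binodal_curve(T_arr, model)
    out = tension.gamma0 * (hi - lo) ** tension.exponent
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------------------
# Fitting chi(T) to coexistence measurements
# ----------------------------------------------------------------------------

#: Printed chi(T) parameterizations (chain length fixed by inspection).
PHASE_PRESETS: dict[str, PhaseModel] = {
    "m1000": PhaseModel(1000.0, 0.31, 75.0, 1600.0),
    "m2000": PhaseModel(2000.0, 0.23, 98.8, 1600.0),
    "m4000": PhaseModel(4000.0, 0.19, 110.0, 1600.0),
}


def fit_chi_parameters(
    points: list[BinodalPoint],
    chain_length: float,
    rho_solute: float = 1600.0,
    weighting: str = "equal",
    x0: tuple[float, float] = (0.2, 100.0),
) -> PhaseModel:
    """Least-squares fit of (A, B) in chi(T) = A + B/T to coexistence data.

    The chain length M is fixed by the caller (it is chosen by inspection,
    not fitted). Residuals are relative concentration errors (or scaled by
    the point's sigma when given), so dense and dilute branches contribute
    comparably. ``weighting='dense'`` fits the dense branch only.
    """
    if weighting not in ("equal", "dense"):
        raise DomainError("weighting must be 'equal' or 'dense'")
    pts = [p for p in points if weighting == "equal" or p.phase == "dense"]
    if len(pts) < 2:
        raise DomainError("need at least two usable coexistence points")
    temps = np.array([p.T for p in pts])
    obs = np.array([p.conc for p in pts])
    dense_mask = np.array([p.phase == "dense" for p in pts])
    sigma = np.array([p.sigma if p.sigma > 0 else p.conc for p in pts])
    uniq_T, inv = np.unique(temps, return_inverse=True)

    def residuals(x: np.ndarray) -> np.ndarray:
        A, B = x
        model = PhaseModel(chain_length, A, B, rho_solute)
        try:
            _, T_c = critical_point(model)
        except DomainError:
            return np.full(len(pts), 1e3)
        if T_c <= uniq_T.max():
            # All measured temperatures must sit below the candidate Tc.
            return np.full(len(pts), 1e3 * (1.0 + uniq_T.max() - T_c))
        lo, hi = binodal_curve(uniq_T, model)
        pred_phi = np.where(dense_mask, hi[inv], lo[inv])
        pred = pred_phi * rho_solute
        return (pred - obs) / sigma

    result = least_squares(
        residuals,
        x0=np.asarray(x0, dtype=float),
        bounds=((-2.0, 1.0), (2.0, 2000.0)),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not result.success:
        raise ConvergenceError(f"chi(T) fit failed: {result.message}")
    A, B = result.x
    return PhaseModel(chain_length, float(A), float(B), rho_solute)
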