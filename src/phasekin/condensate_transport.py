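"""Radial diffusion in a single cooling condensate with a moving interface.

A spherical condensate of initial radius R0 is cooled at a constant rate.
Its interface stays in local equilibrium with the dilute phase, so the
boundary concentration follows the dense binodal c*_+(T(t)); no polymer is
exchanged with the dilute phase, so the total solute mass is conserved and
the condensate shrinks as it densifies. Inside the condensate the solute
obeys spherical diffusion,

    dc/dt = D (1/r^2) d/dr (r^2 dc/dr),        0 <= r <= R(t),

with symmetry at the center. Shrinkage follows a discrete rule matched to
the grid: whenever the solute mass computed without the outermost grid
point exceeds the initial mass, that point is removed.

The solver is a method-of-lines finite-difference scheme on a fixed
grid spacing, backward-Euler (implicit) by default with an explicit option;
temperature is spatially uniform and D temperature-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.linalg import solve_banded

from .exceptions import CFLViolationError, ConvergenceError, DomainError
from .phase_thermo import PhaseModel, binodal_curve, critical_point

__all__ = [
    "CoolingProtocol",
    "CondensateTrajectory",
    "simulate",
    "characteristic_time",
    "saturation_ratio",
    "trajectory_mass",
]


@dataclass(frozen=True)
class CoolingProtocol:
    """Linear cooling ramp T(t) = T0 - rate * t down to T_end, then hold.

    ``hold=True`` keeps the condensate at T_end until its concentration
    profile has equilibrated; ``hold=False`` stops at the end of the ramp.
    """

    T0: float  # K
    T_end: float  # K
    rate: float  # K s^-1
    hold: bool = True

    def __post_init__(self) -> None:
        if self.T_end > self.T0:
            raise DomainError("T_end must not exceed T0")
        if self.T0 != self.T_end and self.rate <= 0:
            raise DomainError("cooling rate must be positive")

    @property
    def ramp_duration(self) -> float:
        if self.T0 == self.T_end:
            return 0.0
        return (self.T0 - self.T_end) / self.rate

    def temperature(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        T = np.maximum(self.T0 - self.rate * t, self.T_end) if self.rate > 0 else np.full_like(t, self.T0)
        return T if T.ndim else float(T)


@dataclass
class CondensateTrajectory:
    """Stored time series of one transport simulation.

    ``conc`` is (n_times, n_grid) with NaN beyond the instantaneous radius;
    ``r`` is the fixed radial grid; ``n_active[k]`` counts grid points inside
    (and on) the interface at time k, so ``radii[k] = r[n_active[k]-1]``.
    """

    times: np.ndarray  # s
    temperatures: np.ndarray  # K
    radii: np.ndarray  # m
    r: np.ndarray  # m, fixed grid
    conc: np.ndarray  # kg m^-3, NaN-padded
    n_active: np.ndarray
    dr: float
    D: float
    protocol: CoolingProtocol

    def frame(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(r, c) arrays of the active region at stored time index k."""
        m = self.n_active[k]
        return self.r[:m], self.conc[k, :m]


def characteristic_time(r: float, D: float) -> float:
    """Diffusive equilibration time scale r^2 / (6 D) for a sphere (s)."""
    if r <= 0 or D <= 0:
        raise DomainError("radius and diffusivity must be positive")
    return r * r / (6.0 * D)


def _dense_binodal_conc_interp(
    protocol: CoolingProtocol, model: PhaseModel, resolution: float = 0.05
):
    """Interpolator for the dense binodal mass concentration over the ramp."""
    T_lo, T_hi = protocol.T_end, protocol.T0
    if T_hi - T_lo < resolution:
        lo, hi = binodal_curve([T_lo], model)
        c_val = float(hi[0]) * model.rho_solute
        return lambda T: np.full_like(np.asarray(T, dtype=float), c_val)
    n = max(3, int(np.ceil((T_hi - T_lo) / resolution)) + 1)
    Ts = np.linspace(T_lo, T_hi, n)
    _, hi = binodal_curve(Ts, model)
    return interp1d(Ts, hi * model.rho_solute, kind="cubic", assume_sorted=True)


def _mass(r: np.ndarray, c: np.ndarray) -> float:
    """Solute mass 4 pi int r^2 c dr by the trapezoid rule."""
    return 4.0 * np.pi * float(np.trapezoid(r * r * c, r))


def simulate(
    R0: float,
    protocol: CoolingProtocol,
    model: PhaseModel,
    D: float,
    c0: float | None = None,
    n_r: int = 500,
    dt: float | None = None,
    scheme: str = "implicit",
    equil_tol: float = 1e-3,
    store_dt: float | None = None,
    max_hold_factor: float = 60.0,
) -> CondensateTrajectory:
    """Simulate one condensate through a cooling protocol.

    Parameters
    ----------
    R0 : initial radius (m).
    protocol : cooling ramp and hold behavior.
    model : Flory-Huggins model supplying the dense binodal boundary value.
    D : dense-phase diffusivity (m^2 s^-1).
    c0 : initial uniform concentration (kg m^-3); defaults to the dense
        binodal value at T0 (the condensate starts at equilibrium).
    n_r : number of grid intervals spanning R0 (>= 200 recommended so the
        discrete shrinkage rule keeps the mass error below ~1%).
    dt : time step (s); a ramp- and diffusion-aware default is chosen.
    scheme : 'implicit' (backward Euler, default) or 'explicit' (CFL-checked).
    equil_tol : relative deviation from the final binodal value below which
        the profile counts as equilibrated (ends the hold phase).
    store_dt : interval between stored frames (s); default ~1/400 of the run.
    max_hold_factor : abort threshold, in units of r^2/(6D), for the hold.
    """
    if R0 <= 0:
        raise DomainError("R0 must be positive")
    if D <= 0:
        raise DomainError("diffusivity must be positive")
    if n_r < 4:
        raise DomainError("n_r too small")
    _, T_c = critical_point(model)
    if protocol.T0 >= T_c:
        raise DomainError("protocol starts above the critical temperature")

    c_star = _dense_binodal_conc_interp(protocol, model)
    if c0 is None:
        c0 = float(c_star(protocol.T0))

    dr = R0 / n_r
    r = np.arange(n_r + 1) * dr
    tau = characteristic_time(R0, D)
    ramp = protocol.ramp_duration
    if dt is None:
        candidates = [tau / 100.0]
        if ramp > 0:
            candidates.append(ramp / 1200.0)
        dt = float(np.clip(min(candidates), 1e-4, 2.0))
    if scheme not in ("implicit", "explicit"):
        raise DomainError("scheme must be 'implicit' or 'explicit'")
    if scheme == "explicit" and D * dt / dr**2 > 0.5:
        raise CFLViolationError(
            f"explicit step unstable: D*dt/dr^2 = {D * dt / dr ** 2:.3g} > 0.5 "
            f"(dt={dt:.3g} s, dr={dr:.3g} m)"
        )

    t_max = ramp + max_hold_factor * tau if protocol.hold else ramp
    horizon = max(t_max, dt)
    if store_dt is None:
        # resolve both the cooling ramp and the subsequent diffusive decay
        store_dt = max((ramp + 2.0 * tau) / 400.0, dt)

    m = n_r + 1  # active grid points
    c = np.full(n_r + 1, float(c0))
    c[m - 1] = float(c_star(protocol.T0))
    M0 = _mass(r[:m], c[:m])
    c_end = float(c_star(protocol.T_end))

    times = [0.0]
    temps = [protocol.T0]
    radii = [r[m - 1]]
    actives = [m]
    frames = [np.concatenate([c[:m].copy(), np.full(n_r + 1 - m, np.nan)])]

    lam = D * dt / dr**2

    def step_implicit(c_act: np.ndarray, n_pts: int, c_bound: float) -> np.ndarray:
        idx = np.arange(n_pts, dtype=float)
        ab = np.zeros((3, n_pts))
        rhs = c_act.copy()
        # center (i = 0): dc/dt = 6 D (c1 - c0) / dr^2 by symmetry
        ab[1, 0] = 1.0 + 6.0 * lam
        ab[0, 1] = -6.0 * lam
        # interior 1..n-2
        i = idx[1:-1]
        ab[2, 0:-2] = -lam * (1.0 - 1.0 / i)  # sub-diagonal entries for rows 1..n-2
        ab[1, 1:-1] = 1.0 + 2.0 * lam
        ab[0, 2:] = -lam * (1.0 + 1.0 / i)
        # boundary row: pinned to binodal
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        rhs[-1] = c_bound
        return solve_banded((1, 1), ab, rhs)

    def step_explicit(c_act: np.ndarray, n_pts: int, c_bound: float) -> np.ndarray:
        new = c_act.copy()
        new[0] = c_act[0] + 6.0 * lam * (c_act[1] - c_act[0])
        i = np.arange(1, n_pts - 1, dtype=float)
        new[1:-1] = c_act[1:-1] + lam * (
            (1.0 - 1.0 / i) * c_act[:-2]
            - 2.0 * c_act[1:-1]
            + (1.0 + 1.0 / i) * c_act[2:]
        )
        new[-1] = c_bound
        return new

    stepper = step_implicit if scheme == "implicit" else step_explicit

    t = 0.0
    next_store = store_dt
    n_steps = 0
    while True:
        t_new = t + dt
        T_new = float(protocol.temperature(t_new))
        c_bound = float(c_star(T_new))
        c[:m] = stepper(c[:m], m, c_bound)
        # discrete shrinkage: drop the outermost point while the mass
        # computed without it already exceeds the initial mass
        while m > 4 and _mass(r[: m - 1], c[: m - 1]) > M0:
            m -= 1
            c[m - 1] = c_bound
        c[m:] = np.nan
        t = t_new
        n_steps += 1

        done = False
        if t >= ramp:
            if not protocol.hold:
                done = True
            else:
                dev = float(np.max(np.abs(c[:m] - c_end))) / c_end
                done = dev < equil_tol
        if t >= next_store or done:
            times.append(t)
            temps.append(T_new)
            radii.append(r[m - 1])
            actives.append(m)
            frames.append(np.concatenate([c[:m].copy(), np.full(n_r + 1 - m, np.nan)]))
            next_store = t + store_dt
        if done:
            break
        if t > horizon + dt:
            raise ConvergenceError(
                f"condensate failed to equilibrate within {horizon:.1f} s "
                f"(relative deviation {dev:.3g})"
            )

    return CondensateTrajectory(
        times=np.asarray(times),
        temperatures=np.asarray(temps),
        radii=np.asarray(radii),
        r=r,
        conc=np.vstack(frames),
        n_active=np.asarray(actives, dtype=int),
        dr=dr,
        D=D,
        protocol=protocol,
    )


def trajectory_mass(traj: CondensateTrajectory) -> np.ndarray:
    """Total solute mass (kg) at each stored frame; flat when mass-conserving."""
    out = np.empty(len(traj.times))
    for k in range(len(traj.times)):
        rr, cc = traj.frame(k)
        out[k] = _mass(rr, cc)
    return out


def saturation_ratio(traj: CondensateTrajectory, model: PhaseModel) -> np.ndarray:
    """Field c(r, t) / c*_+(T(t)): 1 at the interface, < 1 in a lagging core.

    Returned with the same NaN padding as ``traj.conc``.
    """
    uniq_T, inv = np.unique(np.round(traj.temperatures, 9), return_inverse=True)
    _, hi = binodal_curve(uniq_T, model)
    c_star = (hi * model.rho_solute)[inv]
    return traj.conc / c_star[:, None]
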