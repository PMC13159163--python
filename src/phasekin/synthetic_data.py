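"""Synthetic experiment generators with known ground truth.

Every observable the pipeline consumes can be generated here from a known
parameterization, so each stage — binodal fitting, transport, void-count
fitting, FRAP/fusion reduction — is testable end-to-end without external
data. All generators are pure functions of (config, seed): the same
configuration always produces the same draws.

The default configuration mirrors the study conditions of the poly-rA
model system: the M = 2000 Flory-Huggins parameterization, a constant
interfacial tension of 1.8 uJ m^-2 with kinetic prefactor 1.5e-10, dense
diffusivity 1.3e-13 m^2 s^-1, cooling from 55 to 36 degrees C at rates of
0.5-5 K/min, condensate diameters log-uniform over 10-100 um, Gaussian
relative noise on concentration-like channels and Poisson noise on counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .biophys_measurements import FrapTrace, FusionEvent
from .cnt_rates import KineticParams
from .constants import MW_POLY_RA, celsius_to_kelvin
from .exceptions import DomainError
from .phase_thermo import (
    PHASE_PRESETS,
    BinodalPoint,
    PhaseModel,
    TensionModel,
    binodal_curve,
)
from .void_analysis import VoidRateTable, _simulate_for_diameter

__all__ = [
    "SyntheticConfig",
    "gen_binodal_points",
    "gen_void_experiment",
    "void_expected_number",
    "gen_frap_traces",
    "gen_fusion_events",
    "write_synthetic_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and experimental design for all generators.

    ``seed`` fixes every random draw. Temperatures and rates are stored in
    SI (K, K/s); the CSV writers convert to the experimental units.
    """

    seed: int = 0
    phase: PhaseModel = PHASE_PRESETS["m2000"]
    tension: TensionModel = TensionModel("constant", 1.8e-6)
    theta: float = 1.5e-10
    D_plus: float = 1.3e-13  # m^2 s^-1
    Mw: float = MW_POLY_RA  # kg mol^-1

    # binodal experiment
    binodal_temps: tuple = tuple(celsius_to_kelvin(t) for t in (25, 30, 35, 40, 45, 50, 55, 60))
    binodal_rel_noise: float = 0.05

    # void-count experiment
    cooling_rates: tuple = (0.5 / 60, 1.0 / 60, 2.0 / 60, 5.0 / 60)  # K s^-1
    T0: float = celsius_to_kelvin(55.0)
    T_end: float = celsius_to_kelvin(36.0)
    n_condensates_per_rate: int = 30
    diameter_range: tuple = (10e-6, 100e-6)  # log-uniform draws
    n_interp_diameters: int = 9
    transport_kwargs: dict = field(default_factory=dict)

    # FRAP traces
    frap_tau_range: tuple = (10.0, 60.0)  # s
    frap_spot_range: tuple = (5e-6, 15e-6)  # m
    n_frap_traces: int = 3
    n_frap_points: int = 60
    frap_rel_noise: float = 0.02

    # fusion events
    fusion_tau_range: tuple = (1.0, 5.0)  # s
    fusion_diameter_range: tuple = (8e-6, 15e-6)  # m
    fusion_A0: float = 1.4
    n_fusion_events: int = 3
    n_fusion_points: int = 60
    fusion_rel_noise: float = 0.02

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def kinetics(self) -> KineticParams:
        return KineticParams(
            theta=self.theta,
            D_plus=self.D_plus,
            D_minus=1000.0 * self.D_plus,
            Mw=self.Mw,
        )


# ----------------------------------------------------------------------------
# Binodal points
# ----------------------------------------------------------------------------


def gen_binodal_points(cfg: SyntheticConfig) -> list[BinodalPoint]:
    """Noisy coexistence measurements of both phases at the configured temperatures.

    True binodal concentrations from the ground-truth phase model plus
    multiplicative Gaussian noise at the configured relative scale.
    """
    rng = cfg.rng(salt=1)
    temps = np.asarray(cfg.binodal_temps, dtype=float)
    lo, hi = binodal_curve(temps, cfg.phase)
    points = []
    for T, p_lo, p_hi in zip(temps, lo, hi):
        for phase, phi in (("dilute", p_lo), ("dense", p_hi)):
            true_conc = phi * cfg.phase.rho_solute
            noisy = true_conc * (1.0 + cfg.binodal_rel_noise * rng.standard_normal())
            noisy = max(noisy, 1e-6 * true_conc)
            points.append(
                BinodalPoint(
                    T=float(T),
                    phase=phase,
                    conc=float(noisy),
                    sigma=float(cfg.binodal_rel_noise * true_conc),
                )
            )
    return points


# ----------------------------------------------------------------------------
# Void-count experiment
# ----------------------------------------------------------------------------


def void_expected_number(cfg: SyntheticConfig, cooling_rate: float, diameter: float) -> float:
    """Exact expected void count N for one condensate under the truth parameters."""
    tk = {"D": cfg.D_plus, **cfg.transport_kwargs}
    traj = _simulate_for_diameter(
        diameter, cooling_rate, cfg.phase, cfg.T0, cfg.T_end, tk
    )
    table = VoidRateTable(
        traj, cfg.phase, cfg.tension.form, cfg.Mw, cfg.tension.exponent
    )
    return table.expected_voids(cfg.tension.gamma0, cfg.theta, cfg.D_plus)


def _log_n_interpolator(cfg: SyntheticConfig, cooling_rate: float):
    """Monotone interpolant of ln N(ln d) over the configured diameter range."""
    d_grid = np.geomspace(*cfg.diameter_range, cfg.n_interp_diameters)
    n_vals = np.array([void_expected_number(cfg, cooling_rate, d) for d in d_grid])
    n_vals = np.maximum(n_vals, 1e-300)
    return PchipInterpolator(np.log(d_grid), np.log(n_vals))


def gen_void_experiment(
    cfg: SyntheticConfig, sizes: np.ndarray | None = None
) -> pd.DataFrame:
    """Simulated void-count experiment: one row per condensate.

    For each cooling rate, condensate diameters are drawn log-uniform over
    the configured range (or taken from ``sizes``, in meters, applied to
    every rate), the expected count N is computed from the truth parameters,
    and the observed count is drawn as Poisson(N). When the set of unique
    diameters is small the transport model is run exactly per diameter;
    otherwise N is interpolated from a monotone grid in ln d.

    Returns a DataFrame with columns cooling_rate (K/s), diameter (m),
    n_voids, expected_N.
    """
    if cfg.theta < 0:
        raise DomainError("theta truth must be non-negative")
    rng = cfg.rng(salt=2)
    rows = []
    for rate in cfg.cooling_rates:
        if sizes is None:
            lo, hi = np.log(cfg.diameter_range[0]), np.log(cfg.diameter_range[1])
            draws = np.exp(rng.uniform(lo, hi, cfg.n_condensates_per_rate))
        else:
            draws = np.asarray(sizes, dtype=float)
        if cfg.theta == 0:
            n_exp = np.zeros_like(draws)
        elif len(np.unique(draws)) <= cfg.n_interp_diameters:
            by_d = {d: void_expected_number(cfg, rate, d) for d in np.unique(draws)}
            n_exp = np.array([by_d[d] for d in draws])
        else:
            interp = _log_n_interpolator(cfg, rate)
            n_exp = np.exp(interp(np.log(draws)))
        counts = rng.poisson(n_exp)
        for d, n, ne in zip(draws, counts, n_exp):
            rows.append(
                {
                    "cooling_rate": rate,
                    "diameter": float(d),
                    "n_voids": int(n),
                    "expected_N": float(ne),
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# FRAP and fusion
# ----------------------------------------------------------------------------


def gen_frap_traces(
    cfg: SyntheticConfig,
) -> tuple[list[FrapTrace], pd.DataFrame]:
    """FRAP recovery traces plus a truth table of (tau, D) per trace."""
    rng = cfg.rng(salt=3)
    traces = []
    truth_rows = []
    for i in range(cfg.n_frap_traces):
        tau = rng.uniform(*cfg.frap_tau_range)
        d = rng.uniform(*cfg.frap_spot_range)
        t = np.linspace(0.0, 5.0 * tau, cfg.n_frap_points)
        i_start, i_final = 0.2, 1.0
        intensity = i_final - (i_final - i_start) * np.exp(-t / tau)
        if cfg.frap_rel_noise > 0:
            intensity = intensity * (
                1.0 + cfg.frap_rel_noise * rng.standard_normal(len(t))
            )
        traces.append(FrapTrace(spot_diameter=d, times=t, intensities=intensity))
        truth_rows.append(
            {"trace": i, "tau_s": tau, "spot_diameter_m": d, "D_m2_per_s": d * d / (16.0 * tau)}
        )
    return traces, pd.DataFrame(truth_rows)


def gen_fusion_events(
    cfg: SyntheticConfig,
) -> tuple[list[FusionEvent], pd.DataFrame]:
    """Fusion aspect-ratio relaxations plus a truth table of (tau, v) per event."""
    rng = cfg.rng(salt=4)
    events = []
    truth_rows = []
    for i in range(cfg.n_fusion_events):
        tau = rng.uniform(*cfg.fusion_tau_range)
        d1 = rng.uniform(*cfg.fusion_diameter_range)
        d2 = rng.uniform(*cfg.fusion_diameter_range)
        t = np.linspace(0.0, 5.0 * tau, cfg.n_fusion_points)
        aspect = 1.0 + (cfg.fusion_A0 - 1.0) * np.exp(-t / tau)
        if cfg.fusion_rel_noise > 0:
            noisy_excess = (aspect - 1.0) * (
                1.0 + cfg.fusion_rel_noise * rng.standard_normal(len(t))
            )
            aspect = 1.0 + np.maximum(noisy_excess, 0.0)
        events.append(FusionEvent(d1=d1, d2=d2, times=t, aspect_ratios=aspect))
        truth_rows.append(
            {
                "event": i,
                "tau_fusion_s": tau,
                "d1_m": d1,
                "d2_m": d2,
                "v_m_per_s": (d1 + d2) / (2.0 * tau),
            }
        )
    return events, pd.DataFrame(truth_rows)


# ----------------------------------------------------------------------------
# Study writer
# ----------------------------------------------------------------------------


def write_synthetic_study(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic dataset as CSV plus a truth.json sidecar.

    Deterministic for a fixed configuration: re-running with the same seed
    reproduces byte-identical files.
    """
    from . import io as pk_io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    points = gen_binodal_points(cfg)
    paths["binodal"] = outdir / "binodal.csv"
    pk_io.write_binodal_points(points, paths["binodal"])

    voids = gen_void_experiment(cfg)
    paths["voids"] = outdir / "voids.csv"
    pk_io.write_void_counts(voids, paths["voids"])

    frap, frap_truth = gen_frap_traces(cfg)
    paths["frap"] = outdir / "frap.csv"
    pk_io.write_frap_traces(frap, paths["frap"])

    fusion, fusion_truth = gen_fusion_events(cfg)
    paths["fusion"] = outdir / "fusion.csv"
    pk_io.write_fusion_events(fusion, paths["fusion"])

    truth = {
        "seed": cfg.seed,
        "phase": {
            "chain_length": cfg.phase.chain_length,
            "chi_entropic": cfg.phase.chi_entropic,
            "chi_enthalpic_K": cfg.phase.chi_enthalpic,
            "rho_solute_kg_per_m3": cfg.phase.rho_solute,
        },
        "tension": {"form": cfg.tension.form, "gamma0_J_per_m2": cfg.tension.gamma0},
        "theta": cfg.theta,
        "D_plus_m2_per_s": cfg.D_plus,
        "Mw_kg_per_mol": cfg.Mw,
        "frap_truth": frap_truth.to_dict(orient="records"),
        "fusion_truth": fusion_truth.to_dict(orient="records"),
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
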