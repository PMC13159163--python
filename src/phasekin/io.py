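"""CSV schemas for experimental inputs, and preset loading.

CSV columns use the experimental units (degrees Celsius, mg/mL, um,
K/min); the readers convert to strict SI on the way in and the writers
convert back on the way out. Note 1 mg/mL = 1 kg/m^3.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .biophys_measurements import FrapTrace, FusionEvent
from .constants import celsius_to_kelvin, kelvin_to_celsius
from .nucleation_prediction import AtlasEntry
from .phase_thermo import BinodalPoint, PhaseModel, TensionModel

__all__ = [
    "read_binodal_points",
    "write_binodal_points",
    "read_void_counts",
    "write_void_counts",
    "read_frap_traces",
    "write_frap_traces",
    "read_fusion_events",
    "write_fusion_events",
    "read_tension_atlas",
    "load_presets",
]

_FLOAT_FMT = "%.10g"


def read_binodal_points(path: str | Path) -> list[BinodalPoint]:
    """Read coexistence points: temperature_C, phase, concentration_mg_per_ml."""
    df = pd.read_csv(path)
    pts = []
    for _, row in df.iterrows():
        pts.append(
            BinodalPoint(
                T=celsius_to_kelvin(float(row["temperature_C"])),
                phase=str(row["phase"]),
                conc=float(row["concentration_mg_per_ml"]),
                sigma=float(row.get("sigma_mg_per_ml", 0.0) or 0.0)
                if "sigma_mg_per_ml" in df.columns
                else 0.0,
            )
        )
    return pts


def write_binodal_points(points: list[BinodalPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "temperature_C": [kelvin_to_celsius(p.T) for p in points],
            "phase": [p.phase for p in points],
            "concentration_mg_per_ml": [p.conc for p in points],
            "sigma_mg_per_ml": [p.sigma for p in points],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_void_counts(path: str | Path) -> pd.DataFrame:
    """Read void counts into SI columns cooling_rate (K/s), diameter (m), n_voids."""
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "cooling_rate": df["cooling_rate_K_per_min"] / 60.0,
            "diameter": df["condensate_diameter_um"] * 1e-6,
            "n_voids": df["n_voids"].astype(int),
        }
    )


def write_void_counts(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "cooling_rate_K_per_min": df["cooling_rate"] * 60.0,
            "condensate_diameter_um": df["diameter"] * 1e6,
            "n_voids": df["n_voids"].astype(int),
        }
    )
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_frap_traces(path: str | Path) -> list[FrapTrace]:
    """Read FRAP traces: spot_diameter_um, time_s, intensity (+ optional trace id)."""
    df = pd.read_csv(path)
    key = "trace" if "trace" in df.columns else "spot_diameter_um"
    traces = []
    for _, grp in df.groupby(key, sort=True):
        traces.append(
            FrapTrace(
                spot_diameter=float(grp["spot_diameter_um"].iloc[0]) * 1e-6,
                times=grp["time_s"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return traces


def write_frap_traces(traces: list[FrapTrace], path: str | Path) -> None:
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {
                    "trace": i,
                    "spot_diameter_um": tr.spot_diameter * 1e6,
                    "time_s": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_fusion_events(path: str | Path) -> list[FusionEvent]:
    """Read fusion events: d1_um, d2_um, time_s, aspect_ratio (+ optional event id)."""
    df = pd.read_csv(path)
    key = "event" if "event" in df.columns else "d1_um"
    events = []
    for _, grp in df.groupby(key, sort=True):
        events.append(
            FusionEvent(
                d1=float(grp["d1_um"].iloc[0]) * 1e-6,
                d2=float(grp["d2_um"].iloc[0]) * 1e-6,
                times=grp["time_s"].to_numpy(dtype=float),
                aspect_ratios=grp["aspect_ratio"].to_numpy(dtype=float),
            )
        )
    return events


def write_fusion_events(events: list[FusionEvent], path: str | Path) -> None:
    frames = []
    for i, ev in enumerate(events):
        frames.append(
            pd.DataFrame(
                {
                    "event": i,
                    "d1_um": ev.d1 * 1e6,
                    "d2_um": ev.d2 * 1e6,
                    "time_s": ev.times,
                    "aspect_ratio": ev.aspect_ratios,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_tension_atlas(path: str | Path | None = None) -> list[AtlasEntry]:
    """Read a tension atlas CSV; defaults to the packaged representative table.

    Columns: system, gamma_low_uJ_per_m2, gamma_high_uJ_per_m2,
    Mw_kg_per_mol, class (condensate|solid), optional phi.
    """
    if path is None:
        ref = resources.files("phasekin").joinpath("data/tension_atlas_synthetic.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        phi = row.get("phi")
        entries.append(
            AtlasEntry(
                system=str(row["system"]),
                gamma_low=float(row["gamma_low_uJ_per_m2"]) * 1e-6,
                gamma_high=float(row["gamma_high_uJ_per_m2"]) * 1e-6,
                Mw=float(row["Mw_kg_per_mol"]),
                klass=str(row["class"]),
                phi=float(phi) if phi is not None and pd.notna(phi) else None,
            )
        )
    return entries


def load_presets(path: str | Path | None = None) -> dict:
    """Load named PhaseModel / TensionModel parameter sets from YAML.

    Defaults to the packaged presets file holding the three chi(T)
    parameterizations (M = 1000, 2000, 4000).
    """
    if path is None:
        ref = resources.files("phasekin").joinpath("data/presets.yaml")
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, dict] = {"phase": {}, "tension": {}}
    for name, spec in (raw.get("phase") or {}).items():
        out["phase"][name] = PhaseModel(
            chain_length=float(spec["chain_length"]),
            chi_entropic=float(spec["chi_entropic"]),
            chi_enthalpic=float(spec["chi_enthalpic_K"]),
            rho_solute=float(spec.get("rho_solute_kg_per_m3", 1600.0)),
        )
    for name, spec in (raw.get("tension") or {}).items():
        out["tension"][name] = TensionModel(
            form=str(spec["form"]),
            gamma0=float(spec["gamma0_J_per_m2"]),
            Tc=float(spec["Tc_K"]) if spec.get("Tc_K") is not None else None,
        )
    return out
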