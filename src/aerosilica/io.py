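"""CSV readers and writers for the plain-text instrument-export formats.

All files are UTF-8 with a header row and dot decimal separators; the
column layouts are fixed per format and validated on read.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .apsd import ALL_LOCATIONS, ImpactorRun
from .kinetics import DissolutionSeries, ReleaseSeries
from .physisorption import SorptionIsotherm
from .saxs_model import ScatteringCurve
from .tga import Thermogram


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_isotherm(path) -> SorptionIsotherm:
    """Read ``branch,p_rel,q_cm3stp_g`` (branch ∈ {ads, des})."""
    df = pd.read_csv(path)
    _require(df, ["branch", "p_rel", "q_cm3stp_g"], path)
    return SorptionIsotherm(p_rel=df["p_rel"].to_numpy(float),
                            q_ads=df["q_cm3stp_g"].to_numpy(float),
                            branch=df["branch"].astype(str).to_numpy(object))


def write_isotherm(iso: SorptionIsotherm, path) -> None:
    pd.DataFrame({"branch": iso.branch, "p_rel": iso.p_rel,
                  "q_cm3stp_g": iso.q_ads}).to_csv(path, index=False)


def read_adsorption(path) -> pd.DataFrame:
    """Read ``c0_mg_g,ceq_mg_g,solution_mass_g,sorbent_mass_mg,ionic_strength_mM``."""
    df = pd.read_csv(path)
    _require(df, ["c0_mg_g", "ceq_mg_g", "solution_mass_g", "sorbent_mass_mg"], path)
    return df


def read_saxs(path) -> ScatteringCurve:
    """Read ``q_nm_inv,I[,sigma]``."""
    df = pd.read_csv(path)
    _require(df, ["q_nm_inv", "I"], path)
    sigma = df["sigma"].to_numpy(float) if "sigma" in df.columns else None
    return ScatteringCurve(q=df["q_nm_inv"].to_numpy(float),
                           intensity=df["I"].to_numpy(float), sigma=sigma)


def write_saxs(curve: ScatteringCurve, path) -> None:
    data = {"q_nm_inv": curve.q, "I": curve.intensity}
    if curve.sigma is not None:
        data["sigma"] = curve.sigma
    pd.DataFrame(data).to_csv(path, index=False)


def read_impactor_run(path, flow_rate: float, total_loaded_dose: float,
                      recovery_factor: float = 1.0) -> ImpactorRun:
    """Read ``location,mass_ug`` with the full set of NGI locations."""
    df = pd.read_csv(path)
    _require(df, ["location", "mass_ug"], path)
    masses = dict(zip(df["location"].astype(str), df["mass_ug"].astype(float)))
    unknown = set(masses) - set(ALL_LOCATIONS)
    if unknown:
        raise ValueError(f"{path}: unknown locations {sorted(unknown)}")
    return ImpactorRun(flow_rate=flow_rate, total_loaded_dose=total_loaded_dose,
                       masses=masses, recovery_factor=recovery_factor)


def write_impactor_run(run: ImpactorRun, path) -> None:
    pd.DataFrame({"location": list(run.masses),
                  "mass_ug": list(run.masses.values())}).to_csv(path, index=False)


def read_release(path, sample_mass: float, protein_weight_fraction: float,
                 vessel_mass: float) -> ReleaseSeries:
    """Read ``time_h,conc_mg_g,withdrawn_g,replaced_g``."""
    df = pd.read_csv(path)
    _require(df, ["time_h", "conc_mg_g", "withdrawn_g", "replaced_g"], path)
    return ReleaseSeries(sample_mass=sample_mass,
                         protein_weight_fraction=protein_weight_fraction,
                         vessel_mass=vessel_mass,
                         times=df["time_h"].to_numpy(float),
                         concentrations=df["conc_mg_g"].to_numpy(float),
                         withdrawn=df["withdrawn_g"].to_numpy(float),
                         replaced=df["replaced_g"].to_numpy(float))


def write_release(series: ReleaseSeries, path) -> None:
    pd.DataFrame({"time_h": series.times, "conc_mg_g": series.concentrations,
                  "withdrawn_g": series.withdrawn,
                  "replaced_g": series.replaced}).to_csv(path, index=False)


def read_dissolution(path, dose_mg_L: float,
                     si_mass_fraction: float | None = None) -> DissolutionSeries:
    """Read ``time_h,si_mg_L``."""
    df = pd.read_csv(path)
    _require(df, ["time_h", "si_mg_L"], path)
    kwargs = {}
    if si_mass_fraction is not None:
        kwargs["si_mass_fraction"] = si_mass_fraction
    return DissolutionSeries(dose_mg_L=dose_mg_L,
                             times=df["time_h"].to_numpy(float),
                             si_mg_L=df["si_mg_L"].to_numpy(float), **kwargs)


def read_mtt(path) -> pd.DataFrame:
    """Read ``conc_mg_ml,absorbance,role`` (role ∈ {sample, untreated,
    positive, blank})."""
    df = pd.read_csv(path)
    _require(df, ["conc_mg_ml", "absorbance", "role"], path)
    bad = set(df["role"].astype(str)) - {"sample", "untreated", "positive", "blank"}
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return df


def read_thermogram(path) -> Thermogram:
    """Read ``temp_C,weight_pct``."""
    df = pd.read_csv(path)
    _require(df, ["temp_C", "weight_pct"], path)
    return Thermogram(temperature=df["temp_C"].to_numpy(float),
                      weight_pct=df["weight_pct"].to_numpy(float))


def write_thermogram(tg: Thermogram, path) -> None:
    pd.DataFrame({"temp_C": tg.temperature,
                  "weight_pct": tg.weight_pct}).to_csv(path, index=False)


def to_json(obj, path=None) -> str:
    """Serialize result dataclasses (and nested numpy types) to JSON."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    text = json.dumps(obj, default=default, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
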