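"""Forward generators for every input the pipeline consumes.

Each generator simulates one instrument export from known ground truth and
returns ``(data, truth)`` where *truth* is a plain dict of the parameters
used, so tests never re-derive the truth from the data. Noise is
multiplicative Gaussian with a per-generator σ; the same seed always
produces the same output.

The isotherm generator shares the Kelvin and film-thickness constants with
the physisorption module, so BJH analysis of a generated isotherm
round-trips to the generating pore-size distribution up to discretization
error.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from . import constants as K
from .apsd import ImpactorRun, StageTable, NGI_TABLE, scale_cutoffs, SIZING_LOCATIONS
from .kinetics import DissolutionSeries, ReleaseSeries
from .physisorption import SorptionIsotherm
from .saxs_model import CorrelationLengthParams, ScatteringCurve, evaluate_model
from .tga import Thermogram


# ---------------------------------------------------------------------------
# N2 sorption
# ---------------------------------------------------------------------------

def gen_isotherm(median_diameter_A: float = 80.0,
                 geometric_sigma: float = 1.25,
                 total_volume: float = 0.70,
                 external_area: float = 5.0,
                 n_points: int = 80,
                 p_min: float = 0.02,
                 p_max: float = 0.995,
                 noise: float = 0.0,
                 seed: int = 0):
    """Forward Kelvin+film sorption isotherm from a log-normal pore-volume
    distribution.

    Pores are cylinders. On adsorption a pore of diameter d condenses when
    d ≤ r_K(p) + 2t(p) (cylindrical meniscus, delayed condensation); on
    desorption it empties below d = 2(r_K(p) + t(p)) (hemispherical
    meniscus) — exactly the criterion BJH inverts. Unfilled pores carry an
    annular film of thickness t(p) on their cylindrical walls (volume
    fraction 1 − (1 − 2t/d)², the geometry BJH assumes); the external
    surface carries a planar film.

    Returns (SorptionIsotherm, truth dict with the discretized
    distribution, its modal diameter and total volume).
    """
    rng = np.random.default_rng(seed)
    # discretized log-normal pore-volume distribution
    d = np.logspace(np.log10(10.0), np.log10(1000.0), 400)
    ln_d = np.log(d)
    s = np.log(geometric_sigma)
    w = np.exp(-0.5 * ((ln_d - np.log(median_diameter_A)) / s) ** 2)
    widths = np.gradient(ln_d)
    v_bins = total_volume * (w * widths) / np.sum(w * widths)
    a_bins = 4.0e4 * v_bins / d  # m²/g, cylindrical

    p_grid = np.linspace(p_min, p_max, n_points)

    def uptake(p, branch):
        t = K.harkins_jura_thickness(p)
        r_k = K.kelvin_radius(p)
        if branch == "ads":
            fill_d = r_k + 2.0 * t
        else:
            fill_d = 2.0 * (r_k + t)
        filled = d <= fill_d
        v_liq = v_bins[filled].sum()
        # annular film in open cylindrical pores, capped at full pores
        open_frac = np.clip(1.0 - 2.0 * t / d[~filled], 0.0, 1.0)
        film = (v_bins[~filled] * (1.0 - open_frac ** 2)).sum()
        v_liq += film + external_area * t * 1.0e-4
        return v_liq / K.N2_GAS_TO_LIQUID  # cm³ STP/g

    q_ads = np.array([uptake(p, "ads") for p in p_grid])
    q_des = np.array([uptake(p, "des") for p in p_grid])[::-1]
    if noise > 0.0:
        q_ads = q_ads * (1.0 + noise * rng.standard_normal(q_ads.size))
        q_des = q_des * (1.0 + noise * rng.standard_normal(q_des.size))
        q_ads, q_des = np.abs(q_ads), np.abs(q_des)

    iso = SorptionIsotherm(
        p_rel=np.concatenate([p_grid, p_grid[::-1]]),
        q_ads=np.concatenate([q_ads, q_des]),
        branch=np.array(["ads"] * n_points + ["des"] * n_points, dtype=object),
        hysteresis_tol=max(1e-6, 6.0 * noise),
    )
    dv_dd = v_bins / np.gradient(d)
    truth = {
        "median_diameter_A": median_diameter_A,
        "geometric_sigma": geometric_sigma,
        "total_volume": total_volume,
        "modal_diameter_A": float(d[int(np.argmax(dv_dd))]),
        "pore_surface_area": float(a_bins.sum()),
        "external_area": external_area,
        "diameters_A": d, "volumes": v_bins,
    }
    return iso, truth


def gen_bet_isotherm(monolayer_capacity: float, c_constant: float,
                     p_grid=None):
    """Adsorption-only isotherm generated exactly from the multilayer (BET)
    equation — the closed-form oracle for the BET regression."""
    if p_grid is None:
        p_grid = np.linspace(0.01, 0.35, 40)
    p = np.asarray(p_grid, dtype=float)
    q = (monolayer_capacity * c_constant * p
         / ((1.0 - p) * (1.0 + (c_constant - 1.0) * p)))
    return SorptionIsotherm(p_rel=p, q_ads=q,
                            branch=np.array(["ads"] * p.size, dtype=object))


# ---------------------------------------------------------------------------
# impactor deposition
# ---------------------------------------------------------------------------

def gen_impactor_run(mmad: float = 2.0, gsd: float = 1.8,
                     total_dose: float = 10000.0,
                     device_retention_frac: float = 0.05,
                     extrathoracic_frac: float = 0.10,
                     table: StageTable = NGI_TABLE,
                     flow_rate: float = 64.0,
                     noise: float = 0.0,
                     seed: int = 0):
    """Log-normal aerosol deposited across scaled NGI cut-offs.

    The device and extrathoracic (inlet + pre-separator) fractions are
    removed first; the remaining sized mass is partitioned between
    consecutive effective cut-offs by the log-normal CDF, so the sized
    distribution is exactly log-normal(MMAD, GSD).
    """
    if gsd <= 1.0:
        raise ValueError("GSD must exceed 1")
    rng = np.random.default_rng(seed)
    cutoffs = scale_cutoffs(table, flow_rate)
    device = device_retention_frac * total_dose
    extra = extrathoracic_frac * total_dose
    sized = total_dose - device - extra

    cdf = norm.cdf(np.log(cutoffs / mmad) / np.log(gsd))
    fracs = np.empty(len(cutoffs) + 1)
    fracs[0] = 1.0 - cdf[0]                     # stage 1: above its cut-off
    fracs[1:-1] = cdf[:-1] - cdf[1:]            # stages 2..7
    fracs[-1] = cdf[-1]                         # MOC: below the finest cut-off
    masses = {"device": device, "inlet": 0.6 * extra, "preseparator": 0.4 * extra}
    for loc, f in zip(SIZING_LOCATIONS, fracs):
        masses[loc] = sized * f
    if noise > 0.0:
        for loc in masses:
            masses[loc] = abs(masses[loc] * (1.0 + noise * rng.standard_normal()))
    run = ImpactorRun(flow_rate=flow_rate, total_loaded_dose=total_dose,
                      masses=masses)
    truth = {"mmad": mmad, "gsd": gsd, "total_dose": total_dose,
             "device_retention_frac": device_retention_frac,
             "extrathoracic_frac": extrathoracic_frac,
             "fine_fraction_lt": lambda dcut: float(
                 norm.cdf(np.log(dcut / mmad) / np.log(gsd)))}
    return run, truth


# ---------------------------------------------------------------------------
# release / dissolution
# ---------------------------------------------------------------------------

DEFAULT_SCHEDULE_H = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0)


def gen_release_series(plateau_frac: float = 0.703,
                       rate_per_h: float = 0.15,
                       times=DEFAULT_SCHEDULE_H,
                       vessel_mass: float = 5.0,
                       protein_weight_fraction: float = 0.078,
                       sample_mass: float = 10.0,
                       withdrawn_mass: float = 2.0,
                       noise: float = 0.0,
                       seed: int = 0):
    """First-order protein release sampled with withdrawal/replacement.

    Released mass follows m(t) = m_loaded·plateau·(1 − exp(−k·t)). At each
    sampling time the concentration is recorded, *withdrawn_mass* g of
    medium is removed and replaced with fresh, diluting what remains —
    the exact bookkeeping the carryover-corrected release mode inverts.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    m_loaded = protein_weight_fraction * sample_mass  # mg
    release_curve = plateau_frac * (1.0 - np.exp(-rate_per_h * t))
    conc = np.empty_like(t)
    dissolved = 0.0  # mg currently in the vessel
    prev_released = 0.0
    for i, ti in enumerate(t):
        newly = m_loaded * (release_curve[i] - prev_released)
        prev_released = release_curve[i]
        dissolved += newly
        c = dissolved / vessel_mass
        conc[i] = c
        dissolved = c * (vessel_mass - withdrawn_mass)  # aliquot removed
    if noise > 0.0:
        conc = np.abs(conc * (1.0 + noise * rng.standard_normal(conc.size)))
    series = ReleaseSeries(sample_mass=sample_mass,
                           protein_weight_fraction=protein_weight_fraction,
                           vessel_mass=vessel_mass,
                           times=t, concentrations=conc,
                           withdrawn=np.full_like(t, withdrawn_mass),
                           replaced=np.full_like(t, withdrawn_mass))
    truth = {"plateau_frac": plateau_frac, "rate_per_h": rate_per_h,
             "released_frac_at": dict(zip(t.tolist(), release_curve.tolist()))}
    return series, truth


def gen_dissolution_series(dose_mg_L: float = 30.0,
                           rate_per_h: float = 0.112,
                           max_frac: float = 1.0,
                           times=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0),
                           si_mass_fraction: float = K.SI_MASS_FRACTION_SIO2,
                           noise: float = 0.0,
                           seed: int = 0):
    """First-order silica dissolution: dissolved fraction
    f(t) = max_frac·(1 − exp(−k·t)), converted to Si mg/L."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    frac = max_frac * (1.0 - np.exp(-rate_per_h * t))
    si = frac * dose_mg_L * si_mass_fraction
    if noise > 0.0:
        si = np.abs(si * (1.0 + noise * rng.standard_normal(si.size)))
    series = DissolutionSeries(dose_mg_L=dose_mg_L, times=t, si_mg_L=si,
                               si_mass_fraction=si_mass_fraction)
    truth = {"rate_per_h": rate_per_h, "max_frac": max_frac,
             "pct_at": dict(zip(t.tolist(), (100.0 * frac).tolist()))}
    return series, truth


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def gen_scattering(params: CorrelationLengthParams,
                   q_grid=None, noise: float = 0.01, seed: int = 0):
    """Correlation-length model curve with multiplicative noise; σ column
    set to the noise level so fits are weighted consistently."""
    rng = np.random.default_rng(seed)
    if q_grid is None:
        q_grid = np.logspace(np.log10(0.05), np.log10(10.0), 120)
    q = np.asarray(q_grid, dtype=float)
    i_true = evaluate_model(params, q)
    if noise > 0.0:
        i_obs = np.abs(i_true * (1.0 + noise * rng.standard_normal(q.size)))
        sigma = noise * i_true
    else:
        i_obs, sigma = i_true, None
    curve = ScatteringCurve(q, i_obs, sigma=sigma, label="synthetic")
    return curve, {"params": params, "noise": noise}


# ---------------------------------------------------------------------------
# TGA
# ---------------------------------------------------------------------------

def _step(t, center, width):
    return 1.0 / (1.0 + np.exp(-(t - center) / width))


def gen_thermogram(water_pct: float = 2.7, protein_pct: float = 14.2,
                   salt_pct: float = 21.0,
                   silanol_wt: float = 2.2,
                   step_params=((62.0, 5.0), (450.0, 35.0), (900.0, 12.0)),
                   n_points: int = 391,
                   noise: float = 0.0,
                   seed: int = 0):
    """Multi-step sigmoidal thermogram with known composition.

    One logistic mass-loss step per component, centred inside its
    temperature window with a width small enough that the step is complete
    within the window. The silanol condensation loss (*silanol_wt*) is
    added to the protein step, as it falls in the same window; the
    segmentation must subtract it to recover ``protein_pct``.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(25.0, 1000.0, n_points)
    (wc, ww), (pc, pw), (sc, sw) = step_params
    w = (100.0
         - water_pct * _step(t, wc, ww)
         - (protein_pct + silanol_wt) * _step(t, pc, pw)
         - salt_pct * _step(t, sc, sw))
    # re-anchor so the trace starts exactly at 100%
    w = w + (100.0 - w[0])
    noise_tol = 0.2
    if noise > 0.0:
        w = w + noise * rng.standard_normal(t.size)
        w[0] = 100.0
        noise_tol = max(0.2, 6.0 * noise)
    tg = Thermogram(temperature=t, weight_pct=w, noise_tol=noise_tol)
    truth = {"water_pct": water_pct, "protein_pct": protein_pct,
             "salt_pct": salt_pct, "silanol_wt": silanol_wt}
    return tg, truth


# ---------------------------------------------------------------------------
# adsorption records & dose-response
# ---------------------------------------------------------------------------

def gen_adsorption_records(q_max: float = 0.35, affinity_K: float = 2.0,
                           equilibrium_concentrations=None,
                           solution_mass: float = 5.0,
                           sorbent_mass: float = 10.0,
                           noise: float = 0.0,
                           seed: int = 0):
    """Equilibrium adsorption records on a Langmuir curve.

    Loadings are q_max·K·c/(1+K·c) (mg/mg) with optional multiplicative
    noise; initial concentrations back-computed from the mass balance so
    every record is self-consistent.
    """
    from .protein_loading import AdsorptionRecord
    rng = np.random.default_rng(seed)
    if equilibrium_concentrations is None:
        equilibrium_concentrations = np.logspace(-2, np.log10(5.0), 9)
    c_eq = np.asarray(equilibrium_concentrations, dtype=float)
    q = q_max * affinity_K * c_eq / (1.0 + affinity_K * c_eq)
    if noise > 0.0:
        q = np.abs(q * (1.0 + noise * rng.standard_normal(q.size)))
    records = []
    for c, qi in zip(c_eq, q):
        c0 = c + qi * sorbent_mass / solution_mass
        records.append(AdsorptionRecord(
            initial_concentration=c0, equilibrium_concentration=c,
            solution_mass=solution_mass, sorbent_mass=sorbent_mass,
            loading=qi))
    return records, {"q_max": q_max, "affinity_K": affinity_K, "noise": noise}


def gen_dose_response(upper: float = 100.0, lower: float = 0.0,
                      inflection: float = 0.5, hill: float = 2.0,
                      levels=None, noise: float = 0.0, seed: int = 0):
    """4PL viability responses over a concentration dilution series."""
    rng = np.random.default_rng(seed)
    if levels is None:
        levels = 1.0 / 2.0 ** np.arange(8)[::-1]  # 0.0078 .. 1.0 mg/mL
    x = np.asarray(levels, dtype=float)
    y = lower + (upper - lower) / (1.0 + (x / inflection) ** hill)
    if noise > 0.0:
        y = y * (1.0 + noise * rng.standard_normal(x.size))
    truth = {"upper": upper, "lower": lower, "inflection": inflection,
             "hill": hill, "noise": noise}
    return x, y, truth
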