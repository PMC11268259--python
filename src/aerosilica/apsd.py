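"""Cascade-impactor (NGI) aerodynamic particle size data reduction.

Per-location deposited drug masses from one aerosolization are reduced to
emitted/delivered dose, fine particle fraction (FPF), mass median
aerodynamic diameter (MMAD) and geometric standard deviation (GSD). Stage
cut-off diameters are the archival calibration at 60 L/min scaled to the
run's flow rate by D50(Q) = D50,60 × (60/Q)^x.

MMAD and GSD come from the cumulative undersize distribution of the
impactor-sized mass (stages 1–7 + micro-orifice collector), interpolated
linearly in (probit, ln d) space between bracketing stages — the classic
log-probability plot construction: MMAD is the diameter at 50% cumulative
mass, GSD = sqrt(d84.13 / d15.87).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


class ApsdError(ValueError):
    pass


SIZING_LOCATIONS = ("stage1", "stage2", "stage3", "stage4",
                    "stage5", "stage6", "stage7", "moc")
NON_SIZING_LOCATIONS = ("device", "inlet", "preseparator")
ALL_LOCATIONS = NON_SIZING_LOCATIONS + SIZING_LOCATIONS


@dataclass(frozen=True)
class StageTable:
    """NGI stage cut-off calibration: archival D50 at 60 L/min and the
    per-stage flow-scaling exponents."""

    names: tuple = SIZING_LOCATIONS[:-1]  # stages 1..7 (MOC has no cut-off)
    cutoffs_60lpm: tuple = (8.06, 4.46, 2.82, 1.66, 0.94, 0.55, 0.34)
    flow_exponents: tuple = (0.54, 0.52, 0.50, 0.47, 0.53, 0.60, 0.67)

    def __post_init__(self):
        if not (len(self.names) == len(self.cutoffs_60lpm) == len(self.flow_exponents)):
            raise ApsdError("stage table columns must align")
        if np.any(np.diff(self.cutoffs_60lpm) >= 0.0):
            raise ApsdError("cut-offs must be strictly decreasing down the stages")
        if any(not 0.0 < x <= 1.0 for x in self.flow_exponents):
            raise ApsdError("flow exponents must lie in (0, 1]")


NGI_TABLE = StageTable()


@dataclass(frozen=True)
class ImpactorRun:
    """Recovered drug masses (µg) for one aerosolization."""

    flow_rate: float                 # L/min
    total_loaded_dose: float         # µg
    masses: dict                     # location -> µg
    recovery_factor: float = 1.0     # internal-standard correction
    mass_balance_tol: tuple = (75.0, 125.0)  # % of loaded dose

    def __post_init__(self):
        missing = set(ALL_LOCATIONS) - set(self.masses)
        if missing:
            raise ApsdError(f"missing locations: {sorted(missing)}")
        if any(m < 0.0 for m in self.masses.values()):
            raise ApsdError("masses must be >= 0")
        if self.flow_rate <= 0.0:
            raise ApsdError("flow rate must be positive")

    def corrected_mass(self, location: str) -> float:
        return self.masses[location] * self.recovery_factor

    @property
    def total_recovered(self) -> float:
        return sum(self.corrected_mass(loc) for loc in ALL_LOCATIONS)

    @property
    def mass_balance_pct(self) -> float:
        if self.total_loaded_dose <= 0.0:
            return float("nan")
        return 100.0 * self.total_recovered / self.total_loaded_dose

    @property
    def mass_balance_ok(self) -> bool:
        lo, hi = self.mass_balance_tol
        return lo <= self.mass_balance_pct <= hi


@dataclass(frozen=True)
class APSDResult:
    emitted_dose_ug: float
    emitted_dose_pct_of_loaded: float
    delivered_dose_pct: float
    device_retention_pct: float
    fpf_pct: float                  # of emitted dose, < fpf_diameter
    mmad_um: float
    gsd: float
    undersize: tuple                # ((diameter µm, % undersize), ...) ascending d
    mmad_extrapolated: bool = False
    gsd_extrapolated: bool = False
    mass_balance_pct: float = float("nan")
    flags: tuple = field(default=())


def scale_cutoffs(table: StageTable, flow_rate: float) -> np.ndarray:
    """Effective stage cut-off diameters (µm) at *flow_rate* L/min."""
    if flow_rate <= 0.0:
        raise ApsdError("flow rate must be positive")
    cut = np.asarray(table.cutoffs_60lpm, dtype=float)
    exp = np.asarray(table.flow_exponents, dtype=float)
    return cut * (60.0 / flow_rate) ** exp


def cumulative_undersize(run: ImpactorRun, cutoffs: np.ndarray):
    """Cumulative % of impactor-sized mass finer than each stage cut-off.

    Returns (diameters ascending, % undersize), both arrays. The sized mass
    basis is stages 1–7 plus the MOC; undersize at cut-off d_i is the mass
    on all collection surfaces below stage i.
    """
    stage_masses = np.array([run.corrected_mass(s) for s in SIZING_LOCATIONS[:-1]])
    moc = run.corrected_mass("moc")
    sized_total = stage_masses.sum() + moc
    if sized_total <= 0.0:
        raise ApsdError("zero impactor-sized mass")
    if np.count_nonzero(stage_masses > 0.0) < 2:
        raise ApsdError("need positive mass on at least two sizing stages")
    # undersize at cutoff i: everything collected after stage i
    under = np.empty_like(stage_masses)
    below = moc
    for i in range(len(stage_masses) - 1, -1, -1):
        under[i] = below
        below += stage_masses[i]
    pct = 100.0 * under / sized_total
    order = np.argsort(cutoffs)
    return cutoffs[order], pct[order]


def _probit_interp(diam: np.ndarray, pct: np.ndarray, z_target: float):
    """Diameter at probit *z_target*, linear in (probit, ln d) between
    bracketing points; returns (diameter, extrapolated_flag)."""
    frac = np.asarray(pct, dtype=float) / 100.0
    ok = (frac > 0.0) & (frac < 1.0)
    if np.count_nonzero(ok) < 2:
        raise ApsdError("undersize table too degenerate for probit interpolation")
    z = norm.ppf(frac[ok])
    ln_d = np.log(np.asarray(diam, dtype=float)[ok])
    order = np.argsort(z)
    z, ln_d = z[order], ln_d[order]
    extrapolated = not (z[0] <= z_target <= z[-1])
    if extrapolated:
        # extend the nearest segment
        if z_target < z[0]:
            i0, i1 = 0, 1
        else:
            i0, i1 = len(z) - 2, len(z) - 1
    else:
        i1 = int(np.searchsorted(z, z_target))
        i1 = min(max(i1, 1), len(z) - 1)
        i0 = i1 - 1
    slope = (ln_d[i1] - ln_d[i0]) / (z[i1] - z[i0])
    return float(np.exp(ln_d[i0] + slope * (z_target - z[i0]))), extrapolated


def mmad_gsd(diameters: np.ndarray, undersize_pct: np.ndarray,
             global_regression: bool = False):
    """MMAD (µm) and GSD from a cumulative undersize table.

    Default: local linear interpolation in (probit, ln d) between the
    bracketing stages. ``global_regression=True`` instead fits one line
    through all interior points of the log-probability plot.

    Returns (mmad, gsd, mmad_extrapolated, gsd_extrapolated).
    """
    if global_regression:
        frac = np.asarray(undersize_pct, dtype=float) / 100.0
        ok = (frac > 0.0) & (frac < 1.0)
        if np.count_nonzero(ok) < 2:
            raise ApsdError("undersize table too degenerate for regression")
        z = norm.ppf(frac[ok])
        ln_d = np.log(np.asarray(diameters, dtype=float)[ok])
        slope, intercept = np.polyfit(z, ln_d, 1)
        mmad = float(np.exp(intercept))
        gsd = float(np.exp(abs(slope)))
        ex = not (z.min() <= 0.0 <= z.max())
        return mmad, gsd, ex, ex
    mmad, ex50 = _probit_interp(diameters, undersize_pct, 0.0)
    d84, ex84 = _probit_interp(diameters, undersize_pct, 1.0)
    d16, ex16 = _probit_interp(diameters, undersize_pct, -1.0)
    gsd = float(np.sqrt(d84 / d16))
    return mmad, gsd, ex50, (ex84 or ex16)


def reduce(run: ImpactorRun, table: StageTable = NGI_TABLE,
           fpf_diameter: float = 5.0, override_mass_balance: bool = False) -> APSDResult:
    """Full reduction of one impactor run to the headline aerodynamic metrics.

    Emitted dose is everything recovered outside the device; FPF is the
    impactor-sized mass with aerodynamic diameter below *fpf_diameter*
    (undersize curve interpolated at exactly that diameter) expressed as a
    percentage of the emitted dose.
    """
    flags = []
    if not (30.0 <= run.flow_rate <= 100.0):
        flags.append("flow outside calibrated 30-100 L/min range")
    if not run.mass_balance_ok:
        if not override_mass_balance:
            flags.append("mass balance outside tolerance")
    total = run.total_recovered
    device = run.corrected_mass("device")
    emitted = total - device
    if emitted <= 0.0:
        raise ApsdError("emitted dose is zero: all mass retained in device")
    device_pct = 100.0 * device / total
    delivered_pct = 100.0 - device_pct

    cutoffs = scale_cutoffs(table, run.flow_rate)
    diam, under = cumulative_undersize(run, cutoffs)
    mmad, gsd, ex50, ex_gsd = mmad_gsd(diam, under)

    sized_total = sum(run.corrected_mass(s) for s in SIZING_LOCATIONS)
    if diam.min() <= fpf_diameter <= diam.max():
        # interpolate undersize at the FPF diameter on the probit-ln scale
        ln_d = np.log(diam)
        frac = under / 100.0
        okm = (frac > 0.0) & (frac < 1.0)
        if np.count_nonzero(okm) >= 2:
            z = norm.ppf(frac[okm])
            x = ln_d[okm]
            zi = np.interp(np.log(fpf_diameter), x, z)
            frac_fine = float(norm.cdf(zi))
        else:
            frac_fine = float(np.interp(np.log(fpf_diameter), ln_d, frac))
    else:
        frac_fine = float(np.clip(np.interp(fpf_diameter, diam, under / 100.0), 0.0, 1.0))
        flags.append("FPF diameter outside stage cut-off span")
    fpf = 100.0 * frac_fine * sized_total / emitted

    if not (diam.min() <= mmad <= diam.max()):
        flags.append("MMAD outside stage cut-off span")
    return APSDResult(
        emitted_dose_ug=emitted,
        emitted_dose_pct_of_loaded=(100.0 * emitted / run.total_loaded_dose
                                    if run.total_loaded_dose > 0 else float("nan")),
        delivered_dose_pct=delivered_pct,
        device_retention_pct=device_pct,
        fpf_pct=fpf,
        mmad_um=mmad,
        gsd=gsd,
        undersize=tuple(zip(diam.tolist(), under.tolist())),
        mmad_extrapolated=ex50,
        gsd_extrapolated=ex_gsd,
        mass_balance_pct=run.mass_balance_pct,
        flags=tuple(flags),
    )
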