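"""Release, dissolution and viability kinetics.

Covers: interval and cumulative protein-release fractions under a
withdrawal/replacement sampling schedule; silica dissolution percentages
and the T50% time from the early linear region; remaining enzymatic
activity ratios; and four-parameter logistic (4PL) dose-response fits for
MTT viability data.

Release bookkeeping has two modes. ``as_printed`` evaluates the interval
fraction literally as ω_i = C_i·m_i/(ω_lys·m_sample) at every sampling
time. ``carryover_corrected`` reconstructs the mass newly released in each
interval, m_i = C_i·m_vessel − C_{i−1}·(m_vessel − withdrawn_{i−1}),
accounting for the dilution caused by replacing each withdrawn aliquot
with fresh medium; its cumulative sum recovers the true released fraction
exactly on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import stats

from . import constants as K


class KineticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# protein release
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseSeries:
    """Timed supernatant concentrations with withdrawal/replacement bookkeeping.

    Concentrations are mass fractions (mg protein per g of solution);
    ``vessel_mass`` is the total solution mass in g, held constant by
    replacing each withdrawn aliquot with fresh medium.
    """

    sample_mass: float        # mg of dry formulation
    protein_weight_fraction: float  # ω_lys of the dry powder
    vessel_mass: float        # g of release medium
    times: np.ndarray         # h
    concentrations: np.ndarray  # mg/g at each time
    withdrawn: np.ndarray     # g withdrawn at each sampling
    replaced: np.ndarray      # g replaced after each sampling

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        w = np.asarray(self.withdrawn, dtype=float)
        r = np.asarray(self.replaced, dtype=float)
        for name, arr in (("times", t), ("concentrations", c),
                          ("withdrawn", w), ("replaced", r)):
            object.__setattr__(self, name, arr)
        if not (t.shape == c.shape == w.shape == r.shape):
            raise KineticsError("schedule columns must align")
        if np.any(np.diff(t) <= 0.0):
            raise KineticsError("sampling times must be strictly increasing")
        if np.any(c < 0.0):
            raise KineticsError("concentrations must be >= 0")
        if np.any(w > self.vessel_mass):
            raise KineticsError("cannot withdraw more than the vessel holds")
        if not 0.0 < self.protein_weight_fraction < 1.0:
            raise KineticsError("protein weight fraction must be in (0,1)")
        if self.sample_mass <= 0.0:
            raise KineticsError("sample mass must be positive")

    @property
    def loaded_mass(self) -> float:
        """mg of protein in the dosed sample."""
        return self.protein_weight_fraction * self.sample_mass


@dataclass(frozen=True)
class ReleaseResult:
    interval_fractions: np.ndarray
    cumulative_fractions: np.ndarray
    mode: str
    floored_intervals: int = 0


def interval_release(series: ReleaseSeries, mode: str = "as_printed") -> ReleaseResult:
    """Per-interval released fractions of the loaded protein dose."""
    c = series.concentrations
    m_loaded = series.loaded_mass  # mg
    floored = 0
    if mode == "as_printed":
        # ω_i = C_i (mg/g) × m_solution (g) / (ω_lys × m_sample (mg))
        frac = c * series.vessel_mass / m_loaded
    elif mode == "carryover_corrected":
        m_v = series.vessel_mass
        released = np.empty_like(c)
        prev_c = 0.0
        prev_w = 0.0
        for i, ci in enumerate(c):
            m_i = ci * m_v - prev_c * (m_v - prev_w)  # mg newly in solution
            if m_i < 0.0:
                m_i = 0.0
                floored += 1
            released[i] = m_i
            prev_c, prev_w = ci, series.withdrawn[i]
        frac = released / m_loaded
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result = cumulative_release(frac)
    return ReleaseResult(frac, result, mode=mode, floored_intervals=floored)


def cumulative_release(interval_fractions) -> np.ndarray:
    """Running sum of interval release fractions."""
    f = np.asarray(interval_fractions, dtype=float)
    if not np.all(np.isfinite(f)):
        raise KineticsError("interval fractions must be finite")
    return np.cumsum(f)


# ---------------------------------------------------------------------------
# silica dissolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissolutionSeries:
    """Timed dissolved-Si concentrations for a known particle dose."""

    dose_mg_L: float
    times: np.ndarray           # h
    si_mg_L: np.ndarray
    si_mass_fraction: float = K.SI_MASS_FRACTION_SIO2
    temperature_C: float = 37.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.si_mg_L, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "si_mg_L", s)
        if self.dose_mg_L <= 0.0:
            raise KineticsError("particle dose must be positive")
        if np.any(s < 0.0):
            raise KineticsError("Si concentrations must be >= 0")


def si_percent_dissolved(series: DissolutionSeries) -> np.ndarray:
    """Percent of the theoretical Si inventory dissolved at each time.

    The theoretical Si concentration is the particle dose times the Si
    mass fraction of the carrier (0.4674 for stoichiometric SiO2).
    """
    si_total = series.dose_mg_L * series.si_mass_fraction
    return 100.0 * series.si_mg_L / si_total


def t50_interpolate(times, percentages, window=(0.0, 8.0)) -> float:
    """T50%: time at which 50% has dissolved, from an OLS line through the
    points inside the early linear *window* (h)."""
    t = np.asarray(times, dtype=float)
    p = np.asarray(percentages, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if np.count_nonzero(mask) < 2:
        raise KineticsError("need >= 2 points inside the linear window")
    res = stats.linregress(t[mask], p[mask])
    if res.slope <= 0.0:
        raise KineticsError("no dissolution trend: non-positive slope")
    return float((50.0 - res.intercept) / res.slope)


def activity_ratio(sample_activity: float, reference_activity: float) -> float:
    """Remaining enzymatic activity, % of the untreated reference."""
    if reference_activity <= 0.0:
        raise KineticsError("reference activity must be positive")
    return 100.0 * sample_activity / reference_activity


# ---------------------------------------------------------------------------
# MTT viability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourPLFit:
    lower_asymptote: float
    upper_asymptote: float
    inflection_concentration: float
    hill_slope: float
    residual_sum_squares: float
    stderr: dict
    ic50_beyond_range: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        a, d = self.upper_asymptote, self.lower_asymptote
        c, b = self.inflection_concentration, self.hill_slope
        return d + (a - d) / (1.0 + (x / c) ** b)


def normalize_viability(raw_absorbance, untreated_absorbance, blank_absorbance=0.0):
    """Viability % = 100 × (raw − blank)/(untreated − blank)."""
    if untreated_absorbance <= blank_absorbance:
        raise KineticsError("untreated absorbance must exceed the blank")
    raw = np.asarray(raw_absorbance, dtype=float)
    out = 100.0 * (raw - blank_absorbance) / (untreated_absorbance - blank_absorbance)
    return float(out) if np.isscalar(raw_absorbance) else out


def fit_4pl(concentrations, responses, flat_tolerance_pct: float = 10.0) -> FourPLFit:
    """4PL dose-response fit: y = d + (a − d)/(1 + (x/c)^b).

    If the response stays within *flat_tolerance_pct* of the upper
    asymptote across the whole tested range, the half-effect concentration
    is not identifiable and ``ic50_beyond_range`` is flagged.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 5:
        raise KineticsError("need >= 5 concentration levels for a 4PL fit")
    if np.any(x <= 0.0):
        raise KineticsError("concentrations must be strictly positive")

    a0 = float(y.max())
    d0 = float(min(y.min(), 0.0)) if y.min() < 0 else float(y.min() * 0.5)
    span = a0 - y.min()
    if span <= flat_tolerance_pct / 100.0 * max(a0, 1.0):
        # response never departs from the top plateau within the tested range
        return FourPLFit(lower_asymptote=0.0, upper_asymptote=float(np.mean(y)),
                         inflection_concentration=float(x.max()),
                         hill_slope=1.0,
                         residual_sum_squares=float(np.sum((y - np.mean(y)) ** 2)),
                         stderr={}, ic50_beyond_range=True)

    def model(x, a, d, c, b):
        return d + (a - d) / (1.0 + (x / c) ** b)

    m = lmfit.Model(model, independent_vars=["x"])
    params = m.make_params(a=a0, d=d0, c=float(np.sqrt(x.min() * x.max())), b=1.0)
    params["c"].min = 1e-12
    try:
        out = m.fit(y, params, x=x)
    except Exception as exc:  # noqa: BLE001
        raise KineticsError(f"fit failed: {exc}") from exc
    if not out.success:
        raise KineticsError(f"fit failed: {out.message}")
    v = out.params.valuesdict()
    beyond = not (x.min() <= v["c"] <= x.max())
    stderr = {k: (out.params[k].stderr if out.params[k].stderr is not None
                  else float("nan")) for k in out.params}
    return FourPLFit(lower_asymptote=float(v["d"]), upper_asymptote=float(v["a"]),
                     inflection_concentration=float(v["c"]),
                     hill_slope=float(v["b"]),
                     residual_sum_squares=float(np.sum(out.residual ** 2)),
                     stderr=stderr, ic50_beyond_range=beyond)
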