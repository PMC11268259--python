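"""Correlation-length model for 1-D small-angle X-ray scattering curves.

The intensity is modelled as a low-q Porod power law plus a Lorentzian
term with correlation length ξ:

    I(q) = A / q**n + C / (1 + (q·ξ)**m) + background

with q in nm⁻¹ and ξ reported in Å (converted to nm at the model
boundary). For a porous solid the Porod exponent n reflects the roughness
of the pore–solid interface (n = 4 for a smooth interface) and ξ tracks
the average pore-wall thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

XI_A_TO_NM = 0.1  # ξ is carried in Å, the model works in nm


class SaxsError(ValueError):
    pass


@dataclass(frozen=True)
class ScatteringCurve:
    """1-D background-subtracted scattering curve (q in nm⁻¹)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray = None
    label: str = ""
    n_floored: int = 0  # points clipped to zero by background subtraction

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if np.any(q <= 0.0):
            raise SaxsError("q values must be strictly positive")
        if np.any(np.diff(q) <= 0.0):
            raise SaxsError("q values must be strictly increasing")
        if np.any(i < 0.0):
            raise SaxsError("negative intensities (background over-subtracted?)")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if np.any(s <= 0.0):
                raise SaxsError("sigma must be strictly positive")
            object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class CorrelationLengthParams:
    """Parameters of the Porod + Lorentzian intensity model."""

    porod_scale: float          # A, intensity·nm⁻ⁿ
    porod_exponent: float       # n
    lorentzian_scale: float     # C, intensity
    lorentzian_exponent: float  # m
    correlation_length: float   # ξ, Å
    background: float = 0.0

    def __post_init__(self):
        if self.porod_scale < 0 or self.lorentzian_scale < 0 or self.background < 0:
            raise SaxsError("scale factors and background must be >= 0")
        if not 2.0 <= self.porod_exponent <= 5.0:
            raise SaxsError("Porod exponent must lie in [2, 5]")
        if self.lorentzian_exponent <= 0:
            raise SaxsError("Lorentzian exponent must be positive")
        if self.correlation_length <= 0:
            raise SaxsError("correlation length must be positive")


@dataclass(frozen=True)
class CorrelationLengthFit:
    params: CorrelationLengthParams
    stderr: dict
    chi_square: float
    reduced_chi_square: float
    at_bounds: tuple = ()


def evaluate_model(params: CorrelationLengthParams, q_values) -> np.ndarray:
    """Pointwise model intensity at *q_values* (nm⁻¹)."""
    q = np.asarray(q_values, dtype=float)
    if np.any(q <= 0.0):
        raise SaxsError("q values must be strictly positive")
    xi_nm = params.correlation_length * XI_A_TO_NM
    return (params.porod_scale / q ** params.porod_exponent
            + params.lorentzian_scale / (1.0 + (q * xi_nm) ** params.lorentzian_exponent)
            + params.background)


def subtract_background(sample: ScatteringCurve, blank: ScatteringCurve) -> ScatteringCurve:
    """Subtract the blank (interpolated onto the sample grid) pointwise.

    Negative differences are floored at zero; the number of floored points
    is carried on the returned curve.
    """
    lo, hi = blank.q.min(), blank.q.max()
    mask = (sample.q >= lo) & (sample.q <= hi)
    if not np.any(mask):
        raise SaxsError("disjoint q ranges between sample and blank")
    q = sample.q[mask]
    blank_i = np.interp(q, blank.q, blank.intensity)
    diff = sample.intensity[mask] - blank_i
    n_floor = int(np.sum(diff < 0.0))
    diff = np.clip(diff, 0.0, None)
    sigma = sample.sigma[mask] if sample.sigma is not None else None
    return ScatteringCurve(q, diff, sigma=sigma, label=sample.label,
                           n_floored=n_floor)


def _auto_init(curve: ScatteringCurve) -> CorrelationLengthParams:
    """Heuristic starting point: Porod slope from the low-q decade,
    background from the high-q tail, Lorentzian scale from the residual."""
    q, i = curve.q, np.maximum(curve.intensity, 1e-30)
    n_lo = max(5, q.size // 5)
    slope, intercept = np.polyfit(np.log(q[:n_lo]), np.log(i[:n_lo]), 1)
    n0 = float(np.clip(-slope, 2.0, 5.0))
    a0 = float(np.exp(intercept))
    bkg0 = float(np.median(i[-max(3, q.size // 10):]))
    mid = i[q.size // 2]
    c0 = max(float(mid - a0 / q[q.size // 2] ** n0 - bkg0), 1e-6 * i.max())
    return CorrelationLengthParams(porod_scale=a0, porod_exponent=n0,
                                   lorentzian_scale=c0, lorentzian_exponent=2.0,
                                   correlation_length=20.0,
                                   background=max(bkg0, 0.0))


def fit_correlation_length(curve: ScatteringCurve,
                           init: CorrelationLengthParams | None = None,
                           vary_background: bool = True) -> CorrelationLengthFit:
    """Weighted nonlinear least-squares fit of the correlation-length model.

    Residuals are taken in linear intensity space, weighted by 1/σ when
    uncertainties are present. Bounds: n ∈ [2,5], m ∈ [0.5,4], ξ ∈ [1,500] Å.
    With automatic initialization the Porod exponent is multi-started over
    a small grid and the lowest-χ² solution kept, since the two power-law
    terms can trap a single local search.
    """
    if curve.q.size < 20:
        raise SaxsError("need >= 20 points for a correlation-length fit")
    if curve.q.max() / curve.q.min() < 10.0:
        raise SaxsError("q range must span at least one decade")
    p0 = init or _auto_init(curve)

    q, i = curve.q, curve.intensity
    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(i)

    def resid(p):
        model = (p["a"] / q ** p["n"]
                 + p["c"] / (1.0 + (q * p["xi"] * XI_A_TO_NM) ** p["m"])
                 + p["bkg"])
        return (model - i) * w

    def run(n_start):
        pars = lmfit.Parameters()
        a_start = max(p0.porod_scale, 1e-12)
        if n_start != p0.porod_exponent:
            # keep the low-q intensity level when re-slanting the start
            a_start = a_start * q.min() ** (n_start - p0.porod_exponent)
        pars.add("a", value=a_start, min=0.0)
        pars.add("n", value=n_start, min=2.0, max=5.0)
        pars.add("c", value=max(p0.lorentzian_scale, 1e-12), min=0.0)
        pars.add("m", value=p0.lorentzian_exponent, min=0.5, max=4.0)
        pars.add("xi", value=p0.correlation_length, min=1.0, max=500.0)
        pars.add("bkg", value=p0.background, min=0.0, vary=vary_background)
        return lmfit.minimize(resid, pars, method="leastsq")

    starts = [p0.porod_exponent] if init is not None else sorted(
        {p0.porod_exponent, 2.5, 3.0, 3.5, 4.0, 4.5})
    results = [r for r in (run(s) for s in starts) if r.success]
    if not results:
        raise SaxsError("fit failed: no start converged")
    out = min(results, key=lambda r: r.chisqr)
    v = out.params.valuesdict()
    fitted = CorrelationLengthParams(
        porod_scale=v["a"], porod_exponent=v["n"], lorentzian_scale=v["c"],
        lorentzian_exponent=v["m"], correlation_length=v["xi"],
        background=v["bkg"])
    at_bounds = tuple(
        name for name in ("n", "m", "xi")
        for par in [out.params[name]]
        if par.min is not None and (abs(par.value - par.min) < 1e-9
                                    or abs(par.value - par.max) < 1e-9))
    stderr = {name: (out.params[name].stderr if out.params[name].stderr is not None
                     else float("nan"))
              for name in out.params}
    return CorrelationLengthFit(params=fitted, stderr=stderr,
                                chi_square=float(out.chisqr),
                                reduced_chi_square=float(out.redchi),
                                at_bounds=at_bounds)
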