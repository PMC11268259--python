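"""Protein loading quantification: supernatant mass balance, Langmuir
isotherm fits, and the pore-filling capacity model.

Loading is measured indirectly: the protein that disappeared from the
supernatant is assigned to the sorbent. Equilibrium loadings as a function
of equilibrium concentration follow a Langmuir isotherm
q = q_max·K·c/(1+K·c). Independently, the drop in N2-accessible pore volume
between the unloaded and loaded carrier yields the achieved loading via a
volume balance (protein of density ρ occupying pore space at packing
fraction φ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from . import constants as K


class LoadingError(ValueError):
    pass


@dataclass(frozen=True)
class AdsorptionRecord:
    """One equilibrium adsorption experiment (mass-fraction concentrations).

    Concentrations are mg protein per g solution; ``loading`` is mg protein
    per mg sorbent.
    """

    initial_concentration: float
    equilibrium_concentration: float
    solution_mass: float      # g
    sorbent_mass: float       # mg
    loading: float            # mg/mg
    ionic_strength: float = 50.0  # mM
    ph: float = 7.4
    below_loq: bool = False

    def __post_init__(self):
        if self.equilibrium_concentration > self.initial_concentration + 1e-12:
            raise LoadingError("negative adsorption: c_eq exceeds c0")
        if self.loading < 0.0:
            raise LoadingError("loading must be >= 0")


@dataclass(frozen=True)
class LangmuirFit:
    q_max: float            # mg/mg
    affinity_K: float       # g/mg
    q_max_stderr: float
    affinity_K_stderr: float
    residual_sum_squares: float
    plateau_sampled: bool

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        return self.q_max * self.affinity_K * c / (1.0 + self.affinity_K * c)


@dataclass(frozen=True)
class PoreFillingParams:
    """Inputs of the geometric pore-filling capacity model."""

    pore_volume_unloaded: float                      # cm³/g carrier
    pore_volume_loaded: float = None                 # cm³/g composite
    lysozyme_density: float = K.LYSOZYME_DENSITY     # g/cm³
    packing_fraction: float = K.ELLIPSOID_PACKING_FRACTION

    def __post_init__(self):
        if not 0.0 < self.packing_fraction <= 1.0:
            raise LoadingError("packing fraction must be in (0,1]")
        if self.lysozyme_density <= 0.0:
            raise LoadingError("protein density must be positive")
        if self.pore_volume_unloaded < 0.0:
            raise LoadingError("pore volumes must be >= 0")
        if self.pore_volume_loaded is not None:
            if self.pore_volume_loaded < 0.0:
                raise LoadingError("pore volumes must be >= 0")


def loading_from_supernatant(c0: float, c_eq: float, solution_mass: float,
                             sorbent_mass: float,
                             loq: float = 0.0) -> AdsorptionRecord:
    """Mass-balance loading: (c0 − c_eq) × m_solution / m_sorbent (mg/mg).

    A concentration drop below *loq* (same mg/g units) is reported as zero
    loading with the ``below_loq`` flag rather than dropped.
    """
    if sorbent_mass <= 0.0:
        raise LoadingError("sorbent mass must be positive")
    delta = c0 - c_eq
    if delta < -max(loq, 1e-12):
        raise LoadingError("negative adsorption: c_eq exceeds c0 beyond tolerance")
    below = abs(delta) < loq or delta < 0.0
    loading = 0.0 if below else delta * solution_mass / sorbent_mass
    return AdsorptionRecord(initial_concentration=c0,
                            equilibrium_concentration=min(c_eq, c0),
                            solution_mass=solution_mass,
                            sorbent_mass=sorbent_mass,
                            loading=loading,
                            below_loq=below)


def fit_langmuir(records, weighting: str = "relative") -> LangmuirFit:
    """Nonlinear least-squares Langmuir fit to (c_eq, loading) records.

    Initialized from the maximum observed loading and the half-max
    concentration; fitting is done in the nonlinear form so the error
    structure of the raw loadings is preserved. ``weighting="relative"``
    (default) weights residuals by 1/loading, matching the multiplicative
    error typical of spectrophotometric quantification; ``"none"`` uses
    absolute residuals.
    """
    records = list(records)
    if len(records) < 4:
        raise LoadingError("need >= 4 adsorption records for a Langmuir fit")
    c = np.array([r.equilibrium_concentration for r in records], dtype=float)
    q = np.array([r.loading for r in records], dtype=float)
    if np.all(q <= 0.0):
        raise LoadingError("fit failed: no positive loadings")

    q_max0 = float(q.max())
    half = q_max0 / 2.0
    above = c[q >= half]
    c_half = float(above.min()) if above.size else float(np.median(c[c > 0]) or 1.0)
    k0 = 1.0 / max(c_half, 1e-9)

    model = lmfit.Model(lambda x, q_max, k: q_max * k * x / (1.0 + k * x),
                        independent_vars=["x"])
    params = model.make_params(q_max=dict(value=q_max0 * 1.2, min=1e-12),
                               k=dict(value=k0, min=1e-12))
    if weighting == "relative":
        weights = 1.0 / np.maximum(q, 1e-3 * q_max0)
    elif weighting == "none":
        weights = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    try:
        out = model.fit(q, params, x=c, weights=weights)
    except Exception as exc:  # noqa: BLE001 - surfaced as domain error
        raise LoadingError(f"fit failed: {exc}") from exc
    if not out.success:
        raise LoadingError(f"fit failed: {out.message}")
    q_max = float(out.params["q_max"].value)
    k = float(out.params["k"].value)
    # plateau considered sampled if the largest concentration reaches
    # at least 80% of the fitted saturation loading
    plateau = bool(k * c.max() / (1.0 + k * c.max()) >= 0.8)
    return LangmuirFit(
        q_max=q_max,
        affinity_K=k,
        q_max_stderr=float(out.params["q_max"].stderr or np.nan),
        affinity_K_stderr=float(out.params["k"].stderr or np.nan),
        residual_sum_squares=float(np.sum(out.residual ** 2)),
        plateau_sampled=plateau,
    )


def max_loading_capacity(p: PoreFillingParams) -> float:
    """Geometric maximum loading m_lys = ρ × φ × V_pore (g protein/g carrier)."""
    return p.lysozyme_density * p.packing_fraction * p.pore_volume_unloaded


def loading_from_pore_reduction(v_unloaded: float, v_loaded: float,
                                rho_lys: float = K.LYSOZYME_DENSITY) -> float:
    """Achieved loading from the measured pore-volume reduction.

    The loaded-composite pore volume (per gram of composite) relates to the
    per-gram-of-carrier quantities by
    v_loaded = (v_unloaded − m_lys/ρ) / (1 + m_lys); solving for m_lys:
    m_lys = (v_unloaded − v_loaded) / (v_loaded + 1/ρ), in g protein per g
    of unloaded carrier.
    """
    if rho_lys <= 0.0:
        raise LoadingError("protein density must be positive")
    if v_loaded > v_unloaded + 1e-12:
        raise LoadingError("negative apparent loading: loaded pore volume exceeds unloaded")
    return (v_unloaded - v_loaded) / (v_loaded + 1.0 / rho_lys)
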