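"""N2 physisorption analysis: BET surface area, BJH pore-size distribution,
total pore volume and pairwise pore-metric reductions.

The isotherm is the branch-labelled relative-pressure vs quantity-adsorbed
curve exported by a volumetric sorption instrument. BET surface areas are
obtained from the linearized multilayer-adsorption model on the adsorption
branch; mesopore size distributions follow the classic Barrett–Joyner–Halenda
stepwise desorption accounting (Kelvin core + statistical film thinning,
cylindrical pore geometry); total pore volume is the single-point liquid
volume at high relative pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants as K


class PhysisorptionError(ValueError):
    """Raised for invalid isotherms or fit ranges."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SorptionIsotherm:
    """Branch-labelled N2 sorption isotherm.

    Parameters
    ----------
    p_rel, q_ads : arrays of relative pressure (0,1) and quantity adsorbed
        (cm³ STP/g), one entry per measured point.
    branch : array of ``"ads"`` / ``"des"`` labels, one per point.
    temperature : bath temperature in K (77.35 for liquid N2).
    adsorbate : adsorptive gas identity.
    """

    p_rel: np.ndarray
    q_ads: np.ndarray
    branch: np.ndarray
    temperature: float = 77.35
    adsorbate: str = "nitrogen"
    hysteresis_tol: float = 1e-6

    def __post_init__(self):
        p = np.asarray(self.p_rel, dtype=float)
        q = np.asarray(self.q_ads, dtype=float)
        b = np.asarray(self.branch, dtype=object)
        if not (p.shape == q.shape == b.shape):
            raise PhysisorptionError("p_rel, q_ads and branch must align")
        object.__setattr__(self, "p_rel", p)
        object.__setattr__(self, "q_ads", q)
        object.__setattr__(self, "branch", b)
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise PhysisorptionError("relative pressures must lie in (0,1)")
        if np.any(q < 0.0):
            raise PhysisorptionError("quantity adsorbed must be >= 0")
        unknown = set(np.unique(b)) - {"ads", "des"}
        if unknown:
            raise PhysisorptionError(f"unknown branch labels: {unknown}")
        pa = self.pressures("ads")
        if pa.size > 1 and np.any(np.diff(pa) <= 0.0):
            raise PhysisorptionError("adsorption branch must have strictly increasing pressures")
        pd = self.pressures("des")
        if pd.size > 1 and np.any(np.diff(pd) >= 0.0):
            raise PhysisorptionError("desorption branch must have strictly decreasing pressures")
        self._check_hysteresis()

    def _check_hysteresis(self):
        """Desorption uptake must not fall below adsorption uptake at equal p."""
        pa, qa = self.pressures("ads"), self.quantities("ads")
        pd, qd = self.pressures("des"), self.quantities("des")
        if pa.size < 2 or pd.size < 2:
            return
        order = np.argsort(pd)
        lo, hi = max(pa.min(), pd.min()), min(pa.max(), pd.max())
        mask = (pa >= lo) & (pa <= hi)
        if not np.any(mask):
            return
        qd_at = np.interp(pa[mask], pd[order], qd[order])
        if np.any(qd_at < qa[mask] - self.hysteresis_tol * np.maximum(qa[mask], 1.0) - 1e-9):
            raise PhysisorptionError("hysteresis inverted: desorption uptake below adsorption")

    def pressures(self, branch: str) -> np.ndarray:
        return self.p_rel[self.branch == branch]

    def quantities(self, branch: str) -> np.ndarray:
        return self.q_ads[self.branch == branch]


@dataclass(frozen=True)
class BETResult:
    surface_area: float          # m²/g
    monolayer_capacity: float    # cm³ STP/g
    bet_constant_C: float
    fit_range: tuple
    r_squared: float
    n_points_used: int


@dataclass(frozen=True)
class PoreSizeDistribution:
    """BJH pore-size distribution: ordered diameter bins with incremental
    pore volumes and the derived differential dV/dD."""

    diameters: np.ndarray            # Å, strictly monotone
    incremental_volumes: np.ndarray  # cm³/g per bin, >= 0
    bin_widths: np.ndarray           # Å
    surface_areas: np.ndarray = None  # m²/g per bin (cylindrical)

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        v = np.asarray(self.incremental_volumes, dtype=float)
        w = np.asarray(self.bin_widths, dtype=float)
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "incremental_volumes", v)
        object.__setattr__(self, "bin_widths", w)
        if self.surface_areas is None:
            object.__setattr__(self, "surface_areas", 2.0e4 * v / (d / 2.0))
        else:
            object.__setattr__(self, "surface_areas",
                               np.asarray(self.surface_areas, dtype=float))
        if np.any(d <= 0.0):
            raise PhysisorptionError("pore diameters must be positive")
        diffs = np.diff(d)
        if d.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise PhysisorptionError("pore diameters must be strictly monotone")
        if np.any(v < -1e-15):
            raise PhysisorptionError("incremental volumes must be >= 0")

    @property
    def total_volume(self) -> float:
        return float(self.incremental_volumes.sum())

    @property
    def total_area(self) -> float:
        return float(self.surface_areas.sum())

    @property
    def dv_dd(self) -> np.ndarray:
        """Differential pore volume, cm³/(g·Å)."""
        return self.incremental_volumes / self.bin_widths

    @property
    def modal_diameter(self) -> float:
        """Diameter of the bin with the largest dV/dD."""
        if self.total_volume <= 0.0:
            raise PhysisorptionError("empty distribution")
        return float(self.diameters[int(np.argmax(self.dv_dd))])


@dataclass(frozen=True)
class PoreMetrics:
    """The three headline pore-structure numbers for one sample."""

    surface_area: float        # m²/g
    total_pore_volume: float   # cm³/g
    average_pore_diameter: float  # Å

    def __post_init__(self):
        if min(self.surface_area, self.total_pore_volume,
               self.average_pore_diameter) <= 0.0:
            raise PhysisorptionError("pore metrics must be strictly positive")

    def consistency_factor(self) -> float:
        """Ratio of 4V/A (in Å) to the stated average diameter.

        4 × V(cm³/g) / A(m²/g) = 4e4 × V / A Å for cylindrical pores;
        values far from 1 indicate inconsistent metrics.
        """
        return (4.0e4 * self.total_pore_volume / self.surface_area
                / self.average_pore_diameter)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bet_surface_area(iso: SorptionIsotherm,
                     fit_range: tuple = (0.05, 0.30),
                     conversion: float = K.BET_SURFACE_CONVERSION) -> BETResult:
    """Linearized BET regression over *fit_range* of the adsorption branch.

    Regresses p/(q(1-p)) on p; monolayer capacity q_m = 1/(slope+intercept),
    C = slope/intercept + 1, surface area = q_m × *conversion*.
    """
    p_min, p_max = fit_range
    p = iso.pressures("ads")
    q = iso.quantities("ads")
    mask = (p >= p_min) & (p <= p_max)
    p, q = p[mask], q[mask]
    if p.size < 3:
        raise PhysisorptionError(
            f"insufficient points: need >= 3 adsorption points in {fit_range}, got {p.size}")
    if np.any(q <= 0.0):
        raise PhysisorptionError("BET fit invalid in this range: zero uptake in fit range")
    y = p / (q * (1.0 - p))
    res = stats.linregress(p, y)
    denom = res.slope + res.intercept
    if denom <= 0.0 or res.intercept <= 0.0:
        raise PhysisorptionError("BET fit invalid in this range: negative monolayer capacity or C")
    q_m = 1.0 / denom
    c = res.slope / res.intercept + 1.0
    if c <= 0.0:
        raise PhysisorptionError("BET fit invalid in this range: C <= 0")
    return BETResult(surface_area=q_m * conversion,
                     monolayer_capacity=q_m,
                     bet_constant_C=c,
                     fit_range=(p_min, p_max),
                     r_squared=float(res.rvalue ** 2),
                     n_points_used=int(p.size))


def total_pore_volume(iso: SorptionIsotherm,
                      threshold: float = 0.98,
                      gas_to_liquid: float = K.N2_GAS_TO_LIQUID) -> float:
    """Single-point total pore volume (cm³ liquid/g) at P/P0 > *threshold*.

    Uses the adsorption-branch uptake at the highest relative pressure above
    the threshold, converted from cm³ STP gas to liquid volume.
    """
    p = iso.pressures("ads")
    q = iso.quantities("ads")
    mask = p > threshold
    if not np.any(mask):
        raise PhysisorptionError(
            f"isotherm does not reach threshold P/P0 > {threshold}")
    idx = np.argmax(p)  # adsorption branch is increasing; top point
    return float(q[idx] * gas_to_liquid)


def bjh_distribution(iso: SorptionIsotherm,
                     branch: str = "des",
                     gas_to_liquid: float = K.N2_GAS_TO_LIQUID,
                     min_diameter: float = 17.0,
                     external_area: float = 0.0) -> PoreSizeDistribution:
    """Classic BJH stepwise accounting on the chosen branch (desorption default).

    Walks the branch from high to low pressure. At each step the liquid
    volume released is split into (a) capillary cores emptying via the
    Kelvin equation and (b) film thinning on the walls of pores already
    emptied, using the configured Harkins–Jura thickness law. Cylindrical
    geometry converts core volumes to pore volumes and wall areas; each bin
    is reported at pore diameter = 2 × (Kelvin radius + film thickness).

    Steps whose pore diameter falls below *min_diameter* (Å) are outside
    the mesopore range where the Kelvin equation holds and are skipped,
    as in conventional BJH reductions.

    *external_area* (m²/g), when known independently (geometric particle
    area, t-plot of a nonporous reference), is treated as a planar surface
    whose film thinning is subtracted before any volume is assigned to
    pores; without it, a high-area nonporous sample shows a spurious
    distribution, as any BJH reduction does.
    """
    p = iso.pressures(branch)
    q = iso.quantities(branch)
    if p.size == 0:
        raise PhysisorptionError(f"branch missing: no '{branch}' points")
    if p.size < 5:
        raise PhysisorptionError("insufficient points: need >= 5 on branch")
    order = np.argsort(p)[::-1]  # descending pressure
    p, q = p[order], q[order]
    # along decreasing pressure the quantity must not increase
    if np.any(np.diff(q) > 1e-9 * np.maximum(q[:-1], 1.0)):
        raise PhysisorptionError("isotherm not physical: uptake increases as pressure falls")

    t = K.harkins_jura_thickness(p)        # Å
    r_k = K.kelvin_radius(p)               # Å
    r_p = r_k + t                          # pore radius, Å

    diameters, volumes, widths, areas = [], [], [], []
    emptied = []  # (wall area m²/g, pore radius Å) of pores already emptied
    for i in range(p.size - 1):
        dv_liq = (q[i] - q[i + 1]) * gas_to_liquid  # cm³/g released this step
        dt = t[i] - t[i + 1]                        # Å of film thinned
        t_avg = 0.5 * (t[i] + t[i + 1])
        # annular film area in emptied cylinders: wall area × (r - t)/r
        film_area = external_area + sum(
            a * max(r - t_avg, 0.0) / r for a, r in emptied)
        film = dt * film_area * 1.0e-4              # cm³/g (Å·m²/g → cm³/g)
        core = dv_liq - film
        r_p_avg = 0.5 * (r_p[i] + r_p[i + 1])
        r_k_avg = 0.5 * (r_k[i] + r_k[i + 1])
        if 2.0 * r_p_avg < min_diameter:
            break
        if core <= 0.0:
            v_p = 0.0
        else:
            # cylindrical conversion from core to full pore volume
            ratio = (r_p_avg / (r_k_avg + 0.5 * dt)) ** 2
            v_p = core * ratio
        a_p = 2.0e4 * v_p / r_p_avg  # m²/g
        if a_p > 0.0:
            emptied.append((a_p, r_p_avg))
        diameters.append(2.0 * r_p_avg)
        volumes.append(v_p)
        widths.append(abs(2.0 * (r_p[i] - r_p[i + 1])))
        areas.append(a_p)
    return PoreSizeDistribution(np.array(diameters), np.array(volumes),
                                np.array(widths), np.array(areas))


def average_pore_diameter(psd: PoreSizeDistribution,
                          method: str = "volume_weighted") -> float:
    """Average pore diameter (Å): volume-weighted mean or 4V/A."""
    v_tot = psd.total_volume
    if v_tot <= 0.0:
        raise PhysisorptionError("empty distribution")
    if method == "volume_weighted":
        return float(np.sum(psd.diameters * psd.incremental_volumes) / v_tot)
    if method == "four_v_over_a":
        a_tot = psd.total_area
        if a_tot <= 0.0:
            raise PhysisorptionError("empty distribution")
        return float(4.0e4 * v_tot / a_tot)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PoreMetricsDelta:
    surface_area_reduction_pct: float
    pore_volume_reduction_pct: float
    increased: bool = field(default=False)  # any negative reduction (growth)


def pore_metrics_delta(reference: PoreMetrics, sample: PoreMetrics) -> PoreMetricsDelta:
    """Percent reductions 100 × (ref − sample)/ref for area and volume.

    Negative values (the sample grew) are allowed and flagged.
    """
    if reference.surface_area <= 0.0 or reference.total_pore_volume <= 0.0:
        raise PhysisorptionError("undefined reduction: zero reference")
    dsa = 100.0 * (reference.surface_area - sample.surface_area) / reference.surface_area
    dpv = 100.0 * (reference.total_pore_volume - sample.total_pore_volume) / reference.total_pore_volume
    return PoreMetricsDelta(dsa, dpv, increased=(dsa < 0.0 or dpv < 0.0))
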