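"""Thermogravimetric compositional segmentation.

A thermogram (residual weight % vs temperature, 25–1000 °C) is split into
water (25–100 °C loss), protein (200–800 °C loss minus a constant silanol
condensation correction), buffer salts (800–1000 °C loss) and silica
carrier (the remainder). Boundary weights are linearly interpolated
between the two nearest recorded temperatures. The silanol correction
accounts for water formed by condensation of surface silanol groups of
the bare carrier over the same 200–800 °C range, a contribution that would
otherwise be misattributed to protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TgaError(ValueError):
    pass


WINDOWS = {"water": (25.0, 100.0), "protein": (200.0, 800.0),
           "salts": (800.0, 1000.0)}

DEFAULT_SILANOL_WT = 2.2  # wt%; an alternative convention of 2.5 exists
ALTERNATE_SILANOL_WT = 2.5


@dataclass(frozen=True)
class Thermogram:
    """Residual weight (% of initial) vs temperature (°C), increasing T."""

    temperature: np.ndarray
    weight_pct: np.ndarray
    heating_rate: float = 10.0  # °C/min
    noise_tol: float = 0.2      # wt% allowed uphill wiggle

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        w = np.asarray(self.weight_pct, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "weight_pct", w)
        if np.any(np.diff(t) <= 0.0):
            raise TgaError("temperatures must be strictly increasing")
        if abs(w[0] - 100.0) > 1.0:
            raise TgaError("residual weight must start at 100%")
        if np.any(np.diff(w) > self.noise_tol):
            raise TgaError("residual weight must be nonincreasing (within noise)")

    def weight_at(self, temp: float) -> float:
        """Residual weight at *temp*, linearly interpolated."""
        if not self.temperature[0] <= temp <= self.temperature[-1]:
            raise TgaError(f"thermogram does not span {temp} °C")
        return float(np.interp(temp, self.temperature, self.weight_pct))


@dataclass(frozen=True)
class CompositionResult:
    water_pct: float
    protein_pct: float
    salt_pct: float
    carrier_pct: float
    silanol_correction_used: float
    uncounted_loss_pct: float = 0.0  # 100-200 °C loss, assigned to carrier
    floored: tuple = field(default=())
    note: str = ""

    @property
    def total(self) -> float:
        return self.water_pct + self.protein_pct + self.salt_pct + self.carrier_pct


def segment_composition(tg: Thermogram,
                        silanol_correction: float = DEFAULT_SILANOL_WT) -> CompositionResult:
    """Apportion a thermogram into water / protein / salts / carrier wt%.

    water = w(25) − w(100); protein = [w(200) − w(800)] − silanol
    correction; salts = w(800) − w(1000); carrier takes the remainder,
    including the 100–200 °C loss that belongs to no named window (reported
    separately for the audit trail). Negative corrected components are
    floored at zero and flagged.
    """
    bounds = {T: tg.weight_at(T) for T in (25.0, 100.0, 200.0, 800.0, 1000.0)}
    water = bounds[25.0] - bounds[100.0]
    protein_raw = bounds[200.0] - bounds[800.0]
    protein = protein_raw - silanol_correction
    salts = bounds[800.0] - bounds[1000.0]
    uncounted = bounds[100.0] - bounds[200.0]

    floored = []
    for name in ("water", "protein", "salts"):
        val = {"water": water, "protein": protein, "salts": salts}[name]
        if val < 0.0:
            floored.append(name)
    water, protein, salts = (max(v, 0.0) for v in (water, protein, salts))
    carrier = 100.0 - water - protein - salts
    note = ""
    if silanol_correction not in (DEFAULT_SILANOL_WT,):
        note = (f"silanol correction {silanol_correction} wt% differs from the "
                f"default {DEFAULT_SILANOL_WT} wt%; an alternative convention "
                f"of {ALTERNATE_SILANOL_WT} wt% is also in circulation")
    return CompositionResult(water_pct=water, protein_pct=protein,
                             salt_pct=salts, carrier_pct=carrier,
                             silanol_correction_used=silanol_correction,
                             uncounted_loss_pct=uncounted,
                             floored=tuple(floored), note=note)


def washed_away_fraction(loaded_pct: float, washed_pct: float) -> float:
    """Protein lost to washing, in percentage points of formulation weight.

    Difference of the TGA protein contents before and after the washing
    step.
    """
    if loaded_pct < 0.0 or washed_pct < 0.0:
        raise TgaError("protein contents must be >= 0")
    return loaded_pct - washed_pct
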