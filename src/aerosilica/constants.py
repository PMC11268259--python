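"""Physical constants shared by the analysis and synthetic-data modules.

Keeping every unit-conversion factor in one table guarantees that the
forward models in :mod:`aerosilica.synthetic_data` and the inverse
analyses (BET, BJH, pore volume) agree exactly, so round-trip tests
close up to discretization error only.
"""

from __future__ import annotations

import numpy as np

AVOGADRO = 6.02214076e23
"""Avogadro constant, 1/mol."""

N2_CROSS_SECTION_A2 = 16.2
"""Cross-sectional area of an adsorbed N2 molecule at 77 K, Å²."""

STP_MOLAR_VOLUME_CM3 = 22414.0
"""Molar volume of an ideal gas at STP, cm³/mol."""

BET_SURFACE_CONVERSION = 4.3525
"""m² of surface per cm³ STP of N2 monolayer, per gram of sorbent.

Equals N2_CROSS_SECTION_A2 × 1e-20 × AVOGADRO / STP_MOLAR_VOLUME_CM3,
fixed to the conventional four-decimal value used by sorption software.
"""

N2_GAS_TO_LIQUID = 0.0015468
"""cm³ of liquid N2 per cm³ STP of N2 gas (density ratio at 77 K)."""

KELVIN_CONSTANT_A = 4.14
"""Hemispherical-meniscus Kelvin constant for N2 at 77 K:
r_K(Å) = 4.14 / log10(P0/P)."""

HARKINS_JURA = (13.99, 0.034)
"""(numerator, offset) of the Harkins–Jura film thickness law:
t(Å) = sqrt(13.99 / (0.034 − log10(P/P0)))."""

SI_MOLAR_MASS = 28.08
"""Molar mass of silicon, g/mol."""

SIO2_MOLAR_MASS = 60.08
"""Standard molar mass of SiO2, g/mol."""

SI_MASS_FRACTION_SIO2 = SI_MOLAR_MASS / SIO2_MOLAR_MASS  # 0.4674
"""Mass fraction of Si in stoichiometric silica."""

LYSOZYME_DENSITY = 1.4
"""Density of lysozyme, g/cm³."""

ELLIPSOID_PACKING_FRACTION = 0.74
"""Random close packing fraction for ellipsoids."""


def harkins_jura_thickness(p_rel):
    """Adsorbed N2 film thickness t(P/P0) in Å (Harkins–Jura).

    Accepts scalars or arrays of relative pressure in (0, 1).
    """
    p = np.asarray(p_rel, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("relative pressure must be in (0,1)")
    num, off = HARKINS_JURA
    t = np.sqrt(num / (off - np.log10(p)))
    return float(t) if np.isscalar(p_rel) else t


def kelvin_radius(p_rel):
    """Kelvin core radius r_K(P/P0) in Å for a hemispherical meniscus.

    Accepts scalars or arrays of relative pressure in (0, 1).
    """
    p = np.asarray(p_rel, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("relative pressure must be in (0,1)")
    r = KELVIN_CONSTANT_A / np.log10(1.0 / p)
    return float(r) if np.isscalar(p_rel) else r
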