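# Methods

This note records the models implemented, their assumptions, the defaults
chosen where the underlying procedure admits choices, and what the
synthetic-data generators do and do not emulate.

## N₂ physisorption

**BET.** The specific surface area comes from the linearized multilayer
regression of p/(q(1−p)) on p over the adsorption branch. The default fit
range is P/P₀ = 0.05–0.30, the conventional linear window for mesoporous
silica; it is exposed as a parameter and the regression r² is reported so
the range can be audited. Monolayer capacity converts to area through a
single configured constant, 4.3525 m² g⁻¹ per cm³ STP g⁻¹ (N₂
cross-section 16.2 Å², molar volume 22 414 cm³/mol).

**Total pore volume** is the single-point uptake at the highest relative
pressure above 0.98, converted to liquid volume with the N₂ gas-to-liquid
factor 0.0015468.

**BJH.** The pore-size distribution uses the classic stepwise desorption
accounting with cylindrical geometry: per pressure step, the liquid
volume released is split into Kelvin cores (r_K = 4.14/log₁₀(P₀/P) Å,
hemispherical meniscus) and film thinning (Harkins–Jura
t = √(13.99/(0.034 − log₁₀p)) Å). The film-thinning term uses the annular
area of already-emptied cylinders, a·(r̄−t)/r̄ — without this correction
the recovered total volume is biased low by several percent for pores
below ~60 Å. Steps mapping to pore diameters below 17 Å are skipped (the
Kelvin picture does not apply there), and a known external (geometric)
surface area can be supplied so its planar film is subtracted before any
volume is attributed to pores; this is what keeps a high-area nonporous
sample from showing a spurious distribution, a limitation shared by every
BJH reduction. The desorption branch is the default, matching standard
practice for this material class.

All constants live in one table (`constants.py`) shared with the forward
generator, so round-trip tests close to discretization error
(total volume within ~1.5%, modal diameter within ~9% across modes
40–120 Å with the default 80-point pressure grid).

## Protein loading

Loading is quantified indirectly from supernatant depletion,
q = (c₀ − c_eq)·m_solution/m_sorbent, with concentrations handled as mass
fractions (mg per g of solution; aqueous buffer density taken as 1 g/mL
when converting from mg/mL). Depletions below the assay's limit of
quantification are reported as zero with a flag rather than dropped.

Langmuir fits are done in the nonlinear form (no Lineweaver-style
linearization, which distorts the error structure). Residuals are
weighted by 1/q by default because spectrophotometric loadings carry
multiplicative error; absolute weighting is available. Initialization
uses the maximum observed loading and the half-maximum concentration.

The pore-filling model treats the protein as ellipsoids of density
1.4 g/cm³ packing at φ = 0.74. The geometric capacity is
m_lys = ρ·φ·V_pore. The achieved loading inverts the volume balance for
1 g of carrier, V_loaded = (V_unloaded − m_lys/ρ)/(1 + m_lys), giving
m_lys = (V_unloaded − V_loaded)/(V_loaded + 1/ρ). The operation takes
both volumes explicitly: for a carrier equilibrated with buffer, the
buffer-treated placebo's pore volume is the appropriate unloaded
baseline, since buffer alone already occupies some pore space.

## SAXS correlation-length model

I(q) = A/qⁿ + C/(1+(qξ)ᵐ) + background, q in nm⁻¹, ξ stored and reported
in Å (×0.1 at the model boundary). Fitting is weighted linear-space least
squares (σ weights when present), not log-space — the common choice in
small-angle practice, exposed as the residual definition. Bounds are
physical and wide: n ∈ [2, 5], m ∈ [0.5, 4], ξ ∈ [1, 500] Å.
Auto-initialization reads n from the low-q log-log slope, the background
from the high-q tail, and multi-starts the Porod exponent over a small
grid, keeping the lowest-χ² solution; with two competing power laws a
single local search can stall at the n = 2 bound. Parameters ending at a
bound are flagged. Radial averaging of 2-D detector images is out of
scope; the module consumes 1-D curves.

## Impactor reduction

Stage cut-offs are the archival NGI calibration at 60 L/min with
per-stage flow exponents, scaled as D₅₀(Q) = D₅₀,₆₀·(60/Q)^x; the table
ships as versioned constants and can be overridden. The cumulative
undersize distribution is based on impactor-sized mass only (stages 1–7 +
micro-orifice collector); inlet and pre-separator deposits count toward
the emitted dose but not the sized distribution. MMAD and GSD come from
linear interpolation in (probit, ln d) between the bracketing stages —
exact for log-normal aerosols — with a global-regression mode as an
option. FPF interpolates the undersize curve at exactly 5.0 µm on the
same scale and re-bases to the emitted dose. An internal-standard
recovery factor multiplies every location's mass before reduction. Mass
balances outside 75–125% of the loaded dose are flagged.

## Release, dissolution, viability

Interval release offers two bookkeepings. `as_printed` evaluates
ω_i = C_i·m_i/(ω_lys·m_sample) literally at each sampling time.
`carryover_corrected` reconstructs the newly released mass,
m_i = C_i·m_vessel − C_{i−1}·(m_vessel − withdrawn_{i−1}), which undoes
the dilution caused by replacing withdrawn aliquots with fresh medium;
its cumulative sum equals the true released fraction exactly on
noiseless data. Both are kept because the literal formula's treatment of
carryover is ambiguous when samples are total concentrations; the modes
agree when nothing is withdrawn or only one interval exists.

Si dissolution percentages divide the measured Si concentration by the
theoretical Si inventory, dose × Si mass fraction. The default fraction
is 28.08/60.08 = 0.4674 from the standard SiO₂ molar mass; an alternative
value can be supplied for literal reproduction of reports that use a
different silica molar mass. T₅₀% comes from an OLS line through all
points in the early linear window (default 0–8 h), not two-point
bracketing; window endpoints are parameters.

Viability normalizes absorbance to blank/untreated anchors and fits the
four-parameter logistic y = d + (a−d)/(1+(x/c)^b). When the response
never departs from the top plateau by more than ~10% across the tested
range, the inflection is unidentifiable and the fit is reported with an
`ic50_beyond_range` flag instead of a spurious estimate.

## TGA segmentation

Boundary weights at 25, 100, 200, 800 and 1000 °C are linearly
interpolated. Water is the 25–100 °C loss, protein the 200–800 °C loss
minus a constant silanol-condensation correction (default 2.2 wt%; 2.5
is accepted as an alternative convention and the report surfaces which
was used), salts the 800–1000 °C loss, and the carrier takes the
remainder. The 100–200 °C window belongs to no component; its loss is
folded into the carrier and reported separately for the audit trail.
Negative corrected components are floored at zero and flagged.

## Synthetic-data generators

Each generator emulates one instrument export from stated truth
parameters and returns the truth alongside the data. Noise is
multiplicative Gaussian throughout (instrument errors are relative);
defaults are noiseless so oracle tests are exact.

- **Isotherm**: cylindrical pores from a log-normal pore-volume
  distribution (default median 80 Å-class carrier, 0.70 cm³/g).
  Desorption empties pores at d = 2(r_K + t) — exactly the criterion BJH
  inverts — while adsorption condenses at d = r_K + 2t (cylindrical
  meniscus), which produces the correct hysteresis direction without
  modeling cavitation or pore blocking. Films in open pores are annular
  and capped at the pore volume. Default pressure grid: 80 points per
  branch, P/P₀ 0.02–0.995.
- **Impactor run**: log-normal aerosol (defaults MMAD 2 µm, GSD 1.8)
  partitioned between scaled cut-offs by the analytic CDF after removing
  device (5%) and extrathoracic (10%) fractions — so reduction errors
  measure the reduction, not the sample.
- **Release**: first-order release to a plateau (defaults 0.703 of the
  load at 0.15 h⁻¹, 7.8 wt% protein powder, 10 mg in 5 g medium) with
  exact withdrawal/replacement bookkeeping at each sampling time; the
  default schedule (0.5, 1, 2, 4, 8, 24, 48, 72 h) is a typical
  dissolution design reaching plateau within 24 h.
- **Dissolution**: first-order Si release (default 0.112 h⁻¹ at a
  30 mg/L particle dose), ~93% dissolved by 24 h.
- **Thermogram**: one logistic step per component, centred inside its
  window with widths (5, 35, 12 °C) chosen so every step completes
  within its window; the silanol loss is added to the protein step so
  segmentation must subtract it.
- **Scattering, adsorption records, dose-response**: direct evaluation
  of the respective model with self-consistent bookkeeping (adsorption
  records back-compute initial concentrations from the mass balance).

What the generators do **not** emulate: instrument drift, heteroscedastic
baselines, pore-network effects (cavitation, pore blocking, ink-bottle
hysteresis), particle bounce or re-entrainment in the impactor, protein
conformational change on release, or assay interference in MTT. Passing
round-trip tests therefore demonstrates the correctness of the
reductions under idealized single-mechanism data, not robustness to
every artifact of real instruments.

## Numerical choices and limitations

- Linear interpolation is used at all tabulated-boundary lookups
  (isotherm pressures, thermogram temperatures, undersize tables).
- BJH is a mesopore method: results below ~20 Å and above ~1000 Å are
  outside its validity; the 17 Å skip threshold is configurable.
- The probit MMAD construction needs undersize values strictly inside
  (0, 100)%; degenerate tables (all mass on one stage) raise errors
  rather than extrapolate silently, and bracketing failures are flagged
  as extrapolations.
- Problem sizes throughout (80-point isotherms, 120-point scattering
  curves, 8-level dose-response series) match typical instrument exports
  and keep the full test suite in a few seconds.
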