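# aerosilica

Analysis pipeline for the physicochemical characterization of
protein-loaded mesoporous silica particle (MSP) dry-powder-inhaler (DPI)
formulations. It covers the full measurement chain used to qualify such a
carrier — from pore structure, through protein loading, to aerodynamic
performance and dissolution in simulated lung fluid — together with a
synthetic-data module that emulates every instrument export with known
ground truth, so the whole pipeline is testable without instrument data.

## Who it is for

Formulation scientists and analytical chemists working on inhaled
biologics who need reproducible, scriptable reductions of:

- **N₂ sorption isotherms** → BET specific surface area, BJH pore-size
  distribution, single-point total pore volume, average pore diameter,
  and percent pore-metric reductions upon loading (`physisorption`);
- **protein adsorption data** → supernatant mass-balance loadings and
  Langmuir isotherm fits q = q_max·K·c/(1+K·c) (`protein_loading`);
- **pore-filling balances** → geometric maximum capacity
  m_lys = ρ_lys·φ·V_pore and the achieved loading from the measured pore
  volume drop, m_lys = (V_unloaded − V_loaded)/(V_loaded + 1/ρ_lys)
  (`protein_loading`);
- **1-D SAXS curves** → correlation-length model fits
  I(q) = A/qⁿ + C/(1+(qξ)ᵐ) + bkg, where ξ proxies the pore-wall
  thickness (`saxs_model`);
- **NGI cascade-impactor depositions** → emitted/delivered dose, fine
  particle fraction (FPF, < 5 µm of emitted dose), MMAD and GSD from the
  probit/log-diameter construction (`apsd`);
- **release & dissolution time series** → interval and cumulative release
  fractions under withdrawal/replacement sampling, Si % dissolved and
  T₅₀%, enzymatic activity ratios, 4PL viability fits (`kinetics`);
- **thermograms** → water / protein / salt / silica segmentation with the
  silanol-condensation correction (`tga`).

## Worked example

```python
from aerosilica import synthetic_data as sd, physisorption as ph
from aerosilica import protein_loading as pl, apsd

# a carrier-like isotherm: log-normal pores, median 80.5 Å, 0.70 cm³/g
iso, truth = sd.gen_isotherm(median_diameter_A=80.5, geometric_sigma=1.25,
                             total_volume=0.70, external_area=5.0, seed=0)
bet = ph.bet_surface_area(iso)                       # 342 m²/g, r² = 0.9998
v   = ph.total_pore_volume(iso)                      # 0.71 cm³/g
psd = ph.bjh_distribution(iso, external_area=5.0)
d   = ph.average_pore_diameter(psd)                  # 82.6 Å

# achieved loading from the pore-volume drop (placebo 0.64 → washed 0.40)
m = pl.loading_from_pore_reduction(0.64, 0.40, rho_lys=1.4)   # 0.215 g/g

# aerodynamic reduction of a synthetic impactor run at 64 L/min
run, _ = sd.gen_impactor_run(mmad=1.64, gsd=1.69,
                             device_retention_frac=0.0955, seed=0)
res = apsd.reduce(run)
# FPF 87.4%  MMAD 1.64 µm  GSD 1.69  delivered dose 90.5%
```

The BET area (342 m²/g) is the monolayer capacity of the regression over
P/P₀ 0.05–0.30 times the N₂ cross-section conversion (4.3525 m²·g⁻¹ per
cm³ STP·g⁻¹). The 0.215 g/g says that filling the measured 0.24 cm³/g of
lost pore volume with protein of density 1.4 g/cm³ corresponds to 0.215 g
of protein per gram of carrier. The impactor reduction returns exactly the
aerosol parameters the generator used because the sized mass is
partitioned by a log-normal CDF and the reduction inverts it.

Every subcommand is also available from the shell, e.g.:

```sh
aerosilica simulate isotherm --seed 42 --out iso.csv
aerosilica physisorption --isotherm iso.csv --bet-range 0.05:0.30 --out metrics.json
aerosilica capacity --v-unloaded 0.64 --v-loaded 0.40
```

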