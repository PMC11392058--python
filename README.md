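# nanosites

Reactive surface-site analysis of metal-oxide nanomaterials from
probe-molecule data: an in-chemico (acellular) workflow for hazard-oriented
materials categorization.

Toxicologically relevant reactivity lives at a nanomaterial's *reactive
surface sites*, which neither mass nor BET area count.  `nanosites`
implements the three-probe workflow that does:

1. **Methanol chemisorption** titrates surface sites 1:1.  The chemisorbed
   amount is the area between feed and outlet breakthrough curves,
   `n_ads = F · ∫(1 − y_out/y_feed) dt`, from internal-standard-normalized
   mass-spectrometer traces; dividing by sample mass gives the specific
   site content (mmol g⁻¹) and, with the BET area, the site surface
   density (sites nm⁻²).
2. **Temperature-programmed surface reaction (TPSR)** of the chemisorbed
   methoxy classifies the sites: dimethyl ether marks acid sites,
   formaldehyde redox sites, and CO₂ either basic sites (released hot,
   carbonates) or strongly oxidizing sites (released cold, formates).
3. **DTT oxidation** measures oxidative potential.  Conversion net of the
   no-particle control, `X = 100(C_neg − C_sample)/C0`, is normalized per
   mass (OP_mass), per area (OP_area), or — the per-site descriptor this
   package is built around — per reactive site as the **oxidative turnover
   frequency**, `OxTOF = OP_mass / (10³ · n_sites)` in h⁻¹, the exact
   analogue of a catalytic turnover frequency.

Materials are then grouped into statistically distinct reactivity
categories (natural-log transform, one-way ANOVA, Tukey HSD, compact
letter display), and doses convert exactly between µg mL⁻¹, m² L⁻¹ and
µmol of sites per litre.  A seeded synthetic-data module emulates every
instrument signal — sigmoidal breakthrough fronts with drift, Gaussian
TPSR peaks, first-order DTT depletion with triplicate noise — with ground
truth recorded, so the whole pipeline is testable without laboratory data.

Intended users: nanosafety and nanotoxicology researchers evaluating
surface-reactivity descriptors and site-based dose metrics, and catalysis
people who want the same breakthrough/TPSR arithmetic scripted.

## Worked example

Simulate the eight-material benchmark panel and analyze it end to end:

```sh
nanosites simulate --seed 7 --out-dir study
nanosites report --in-dir study --out-dir out
# -> 3 oxtof categories (F = 298, p = 6.06e-14)
# -> report written to out/panel_report.tsv
```

The report table (abridged):

| sample       | sites (mmol/g) | density (nm⁻²) | nature          | X (%) | OxTOF (h⁻¹) | letters |
|--------------|---------------:|---------------:|-----------------|------:|------------:|---------|
| TiO2 NM-101  | 2.801          | 7.50           | acidic          | 30.8  | 0.055       | c       |
| TiO2 DT51    | 1.951          | 13.99          | acidic          | 20.8  | 0.053       | c       |
| CeO2 NM-211  | 0.700          | 5.55           | redox           | 26.3  | 0.188       | b       |
| CuO-SA       | 0.400          | 20.06          | oxidizing-redox | 62.6  | 0.783       | a       |
| ZnO NM-110   | 0.301          | 20.13          | basic           | 2.2   | —           | (excl.) |
| CuFe2O4-SA   | 0.500          | 9.13           | oxidizing-redox | 73.2  | 0.732       | a       |
| Fe3O4-SA     | 0.200          | 10.93          | basic           | 2.2   | 0.055       | c       |
| Co3O4-SA     | 0.301          | 6.96           | oxidizing-redox | 46.5  | 0.774       | a       |

Reading it: the chemisorption stage recovers each material's site content
(e.g. 2.8 mmol g⁻¹ for TiO2 NM-101, i.e. 7.5 sites nm⁻² over its
225 m² g⁻¹ BET area — note the titania with the *largest* area has one of
the *lowest* site densities).  TPSR labels the titanias acidic, ceria
redox, ZnO and Fe₃O₄ basic, and the copper/cobalt oxides oxidizing-redox
(CO₂ released below 300 °C).  The Tukey letters split the panel into three
OxTOF categories: copper/cobalt oxides ≫ ceria ≫ titanias and iron oxide.
ZnO is excluded from the ranking because its DTT depletion is carried by
dissolved zinc ions, not its (genuinely basic) particle surface.

Dose-scale conversions are one-liners:

```sh
nanosites dose --mass-conc 100 --sites 2.8
# gravimetric: 100 ug/mL
# site molarity: 280 umol/L
nanosites dose --mass-conc 25 --invert 7.5
# implied specific sites: 0.3 mmol/g
```

The same operations are plain library calls (`nanosites.chemisorption`,
`.tpsr`, `.dtt`, `.dose_metrics`, `.ranking`, `.synthetic_data`,
`.workflow`) — see `docs/methods.md` for the models, defaults and
limitations.

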