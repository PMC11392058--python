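# Methods

`nanosites` implements an acellular (in-chemico) workflow that characterizes
the reactive surface of metal-oxide engineered nanomaterials (ENMs) by three
linked measurements — methanol chemisorption, temperature-programmed surface
reaction (TPSR), and the dithiothreitol (DTT) oxidation assay — and reduces
them to a per-site reactivity descriptor, the oxidative turnover frequency
(OxTOF), plus a statistical grouping of materials into reactivity
categories.  This note records the models, the defaults and why, the scope of
the synthetic-data emulation, and the numerical choices.

## Site titration from breakthrough curves

Methanol vapor titrates reactive surface hydroxyls 1:1: each chemisorbing
CH3OH becomes a surface methoxy and releases one H2O, so moles of methanol
held back by the bed count reactive sites.  The bed is fed a constant stream
(defaults: 100 mL min⁻¹ of 2000 ppm methanol in argon with 5% helium) until
the outlet saturates at the feed level.  The chemisorbed amount is the area
between feed and outlet curves,

    n_ads = F_MeOH · ∫ (1 − y_out(t) / y_feed) dt ,

integrated by the trapezoidal rule on the native (possibly irregular) time
grid — no resampling, to avoid interpolation bias.

**Internal-standard normalization.**  The outlet fraction y_out comes from
the ratio of the methanol ion current (m/z 31) to the helium internal
standard (default m/z 4; configurable), rescaled so the mean over the final
10% of the run equals the feed fraction.  Because source and detector drift
multiply both channels equally, the ratio cancels drift exactly; the
residual uptake error under 1–2% channel noise and up to 10% drift is below
1% (the package's recovery property tests bound it at 2% over a 50-run
suite).

**Saturation test.**  A run only integrates if it is saturated.  The
criterion is the least-squares slope of the last 10% of the window,
tolerated up to 0.5% of the plateau value per minute.  The raw slope
estimate on a noisy plateau fluctuates above that tolerance even for
genuinely saturated runs, so the test flags a run as unsaturated only when
the slope exceeds the tolerance by more than twice its own standard error.
A still-rising front sits orders of magnitude above the threshold and is
always caught.

**Molar feed rate.**  Converted from volumetric flow by the ideal gas law at
reference conditions of 25 °C and 1 atm (24.45 L mol⁻¹); both are
configurable since flow controllers may be calibrated to other references.

**Derived quantities.**  Blank uptake (inert SiC bed) is subtracted; a
negative difference is clamped to zero and flagged below-detection rather
than raised, so inert samples flow through the pipeline.  Specific site
content is uptake/mass (µmol mg⁻¹ ≡ mmol g⁻¹, one site per methanol); site
surface density is sites·g⁻¹ (via Avogadro's number) divided by the BET
area in nm² g⁻¹.  The published worked examples — 2.8 mmol g⁻¹ on
225 m² g⁻¹ → 7 sites nm⁻², and 0.7 on 76 → 6 — are reproduced exactly.

Multilayer adsorption and in-bed transport are out of scope; the
chemisorption-temperature field (100 °C, or 50 °C for highly reactive
materials) records the protocol used but no correction is applied.

## TPSR classification

Heating the methoxy-covered surface under inert flow converts the adsorbate
into diagnostic products: dimethyl ether (DME, m/z 45) on acid sites,
formaldehyde (HCHO, m/z 30) on redox sites, and CO₂ (m/z 44) either from
carbonate decomposition on basic sites (high release temperature) or from
formate decomposition on strongly oxidizing surfaces that combust the
methoxy (low release temperature).  Lower peak temperatures mean more
reactive sites.  Channels are treated as product-pure; fragmentation
overlap between m/z values is not deconvolved.

Per product, the pipeline is: extract the ramp segment (longest contiguous
non-decreasing temperature run spanning ≥ 50 °C), normalize by the internal
standard, subtract a linear baseline, detect peaks, and integrate areas.

* **Baseline**: a line through two anchors, each the mean of the
  lowest-decile signal within the first/last 10% of points, placed at the
  mean temperature of those selected points (so a sloped baseline is
  followed exactly); the corrected signal is floored at zero.  The decile
  anchoring is robust to peaks near the window edges at the cost of a small
  positive area bias (≈ the noise amplitude times the temperature span)
  under noise; classification is built on area *ratios* and is insensitive
  to it.
* **Peaks**: Savitzky–Golay smoothing (window 11 points, order 2,
  configurable), SciPy prominence-based maxima with the threshold set to
  5% of the run-wide maximum across all product channels (a per-channel
  reference would let minor channels resolve their own noise floor).  The
  reported peak temperature is the intensity-weighted centroid over the
  half-height region — unbiased for symmetric peaks and far less
  grid-jittery than the discrete argmax (≤ 0.5 °C scatter at 1% noise
  versus several °C).  FWHM comes from the half-height crossings.
* **Classification**: acid share ← DME area; redox share ← HCHO area, plus
  the CO₂ area when the dominant CO₂ peak sits at or below the
  basic-vs-oxidizing threshold (default 300 °C, chosen between the
  observed ~220–250 °C oxidizing regime and the > 300 °C basic regime;
  configurable); basic share ← CO₂ area above the threshold.  CO₂ area
  with no detected peak carries no temperature information and is left out
  of the shares.  The label is the argmax share ("oxidizing-redox" when
  low-temperature CO₂ carries the redox share; "mixed" when no share
  reaches 0.5; "unreactive" when all areas vanish).  Site strength is
  "strong" when the dominant product's peak lies below its reference
  temperature (DME 345 °C, HCHO 300 °C, CO₂ 275 °C), else "moderate".
* **Reactivity map**: a quantitative rendering of a qualitative picture,
  and explicitly heuristic.  y = basic − acid fraction ∈ [−1, 1];
  x = redox fraction × (1 − (T_redox − 150)/300) clipped to [0, 1], with
  T_redox the area-weighted mean temperature of the redox-contributing
  peaks, so hotter surfaces that oxidize at lower temperature score larger
  x.  Classification and map coordinates are invariant under uniform
  intensity scaling.

## DTT oxidative-potential descriptors

The single-endpoint DTT assay mixes 3 mL of a 200 µg mL⁻¹ particle
suspension with 3 mL of 100 µM DTT (6 mL reactor at 100 µg mL⁻¹ and
50 µM), incubates 1 h at 37 °C, and quantifies unreacted DTT with Ellman's
reagent at 412 nm against a linear calibration.  With C0 the nominal
initial DTT (µM), V the volume (mL), t the time (h), m the particle mass in
the reactor (mg, computed from the mixing protocol), BET the area
(m² g⁻¹) and n_s the site content (mmol g⁻¹):

    X      = 100 (C_neg − C_sample) / C0          conversion, % (net of the
                                                  no-particle control)
    NIOG   = X / X_positive                       vs. the H2O2 control
    OP_mass = (X/100) C0 V / (t m)                nmol h⁻¹ mg⁻¹
    OP_area = 10³ OP_mass / BET                   nmol h⁻¹ m⁻²
    OxTOF  = OP_mass / (10³ n_s)                  h⁻¹

(µM·mL = nmol, and 1 mmol g⁻¹ = 10³ nmol mg⁻¹, so the two identities
OP_area·BET = 10³·OP_mass and OxTOF·n_s·10³ = OP_mass hold to rounding and
are enforced in tests at 10⁻⁹ relative.)  OxTOF is the per-site analogue of
a catalytic turnover frequency: DTT molecules oxidized per reactive surface
site per hour.  Negative net conversions are stored (flagged
below-detection), never clamped, so replicate means stay unbiased.
Materials whose DTT depletion is carried by dissolved ions rather than the
particle surface (ZnO) are flagged dissolution-suspect via configuration
and excluded from ranking by default.

The calibration is ordinary least squares of absorbance on concentration,
requiring ≥ 3 points with non-zero spread; r² < 0.99 warns.

## Statistical grouping

Replicate descriptor values are natural-log transformed (multiplicative
assay noise is closer to normal on the log scale; the base is irrelevant to
F statistics, Tukey decisions and letters).  Non-positive replicates are
dropped with a record; a sample without two positive replicates is
excluded.  One-way ANOVA uses the classical between/within decomposition
with the F distribution (degenerate inputs resolve to F = 0, p = 1 for no
between-group variation, F = ∞, p = 0 for no within-group variation).
Tukey's HSD p-values come from the studentized-range distribution with
pooled within-group variance (SciPy; Tukey–Kramer for unbalanced groups).
The compact letter display uses the insert-and-absorb algorithm with
letters ordered by descending group mean; samples share a letter iff they
are not significantly different, and this is re-verified exhaustively
against the pairwise matrix on every call — an internal oracle, not just a
test.  The number of distinct letters is the number of reactivity
categories.

## Dose metrics

Unit-exact conversions: site molarity (µmol L⁻¹) = gravimetric dose
(µg mL⁻¹) × site content (mmol g⁻¹); area dose (m² L⁻¹) = gravimetric dose
× BET × 10⁻³; the inverse recovers a site content from any printed
(gravimetric, site-molarity) pair; mixtures are volume-weighted means.

## Synthetic data: what is emulated, and what is not

The generators emulate the *statistical structure* of the instrument
records, not the physics:

* **Breakthrough**: logistic front y(t) = y_feed/(1 + e^−(t−t_b)/τ)
  (default midpoint 10 min, width τ = 0.5 min, 1 s sampling), a shared
  linear multiplicative drift (default 5%) on both channels, and 1%
  relative Gaussian noise per channel.  The true uptake is integrated on a
  10× denser noise-free grid by the same area definition, independent of
  the analysis path.  The blank reproduces a 0.3 min dead time.
* **TPSR**: 10 °C min⁻¹ ramp from 50 to 450 °C (the ramp rate after
  chemisorption is not stated in the protocol; the pretreatment rate is
  assumed), one Gaussian per product peak on a small linear baseline, 1%
  noise relative to the tallest peak.
* **DTT**: first-order depletion C = C0·e^−(k+k0)t against a background
  rate k0 = 0.05 h⁻¹, read through a calibration line of slope
  0.0283 A µM⁻¹ (two TNB chromophores per DTT at ε ≈ 14 150 M⁻¹ cm⁻¹)
  and intercept 0.05 A, with 0.002 A additive noise.  Per-replicate
  catalytic rates carry mean-one lognormal variation (20% relative),
  giving the ~20% replicate dispersion of the descriptor.

The eight-material default panel uses the published BET areas (225, 84, 76,
12, 9, 33, 11, 26 m² g⁻¹), published or dose-pair-implied site contents
(NM-101 2.8, DT51 1.95, CeO₂ 0.7, CuO 0.4, ZnO 0.3, CuFe₂O₄ 0.5, Fe₃O₄
0.2, Co₃O₄ 0.3 mmol g⁻¹), the reported product peak temperatures (DME 349
and 339 °C on the titanias, HCHO 259 °C on ceria, CO₂ at 230–245 °C on
the copper/cobalt oxides and 340–350 °C on ZnO/Fe₃O₄), and per-site
oxidation-rate tiers in the reported ratios: the absolute scale is anchored
at the Co₃O₄ microparticle point (6.7% conversion, NIOG 0.08, about
sevenfold below its nanoparticle counterpart → nano OxTOF 0.78 h⁻¹), with
ceria fourfold lower (0.195 h⁻¹) and the titania/iron-oxide tier ~3.5×
below ceria (0.056 h⁻¹).  ZnO's DTT signal is generated near the negative
control and flagged dissolution-suspect.  The H₂O₂ positive control runs
at 83.75% conversion, the value implied by the 6.7%/0.08 pair.

What passing tests show — and do not show.  The emulation has logistic
fronts, Gaussian peaks, exactly first-order depletion and lognormal
replicate scatter; real data have asymmetric fronts, peak shoulders and
tailing, channel fragmentation overlap, and drift that is not purely
multiplicative.  Recovery within the tested tolerances therefore
demonstrates the correctness of the estimators under the stated noise
model, not instrument-grade robustness.  One deliberate consequence of the
single-endpoint assay is retained: at high conversion the log-descriptor
dispersion compresses (saturation), so top-tier groups show less than the
nominal 20% spread, and the pooled Tukey variance is mildly heterogeneous —
the three-category outcome is recovered in ~97% of seeded studies rather
than always.

## Numerical choices and degenerate inputs

* Floats are written with 17 significant digits and parsed with a
  correctly-rounded parser, so every file round trip is bit-exact.
* Trapezoidal integration everywhere; time in seconds, temperatures in °C
  at all interfaces; rates per minute only inside the uptake integral.
* Seeds: every generator draws from one `numpy.random.default_rng(seed)`;
  panel children derive sub-seeds below 2³¹ from the root generator.
* Degenerate statistical inputs (identical groups, zero within-group
  variance, singleton replicates) resolve to the documented fixed points
  instead of NaNs.
* Problem sizes in tests: 50-run uptake suite, 50-case peak grid, 200-seed
  category suite, 100-seed microparticle emulation — sized to keep the full
  suite around a minute while leaving the binomial margins interpretable.

## Known limitations

* The breakthrough-integral formulation is a reconstruction of the
  saturation-feed protocol; the original supplementary equations were not
  available and analytical equivalence cannot be asserted.
* Reported conversion assumes the nominal C0; an error in the stock
  concentration propagates linearly into all descriptors.
* The reactivity-map coordinates are a heuristic ordering device, not a
  calibrated scale.
* No kinetic modeling: TPSR peaks are not Redhead-analyzed, and the DTT
  assay is single-endpoint (no time-course fitting).
* Multilayer chemisorption on very basic surfaces (e.g. ZnO) inflates site
  counts; the package records the chemisorption temperature but applies no
  correction.
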