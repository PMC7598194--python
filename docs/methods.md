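# Methods

## Model structure

The body is represented by 16 perfused organs (lung, brain, heart, muscle,
bone, skin, fat, gonads, kidney, liver, stomach, small and large intestine,
pancreas, spleen, gallbladder) plus arterial, venous and portal-vein blood
pools. Each organ carries a vascular, an interstitial and a cellular
sub-compartment. Blood flows venous pool → lung → arterial pool → systemic
organs → venous pool; stomach, intestines, pancreas, spleen and gallbladder
drain into the portal vein, which joins the hepatic-artery inflow at the
liver. Intravenous doses (bolus or infusion) enter the venous pool.

Amounts are tracked in µmol, time in minutes, volumes in litres.
Concentrations are reported in ng/mL at two sampling sites: plasma of the
venous pool and plasma of the arterial pool, obtained from the pool blood
concentration through the blood-to-plasma ratio.

**Exchange fluxes.** All exchange is driven by unbound-concentration
differences. Vascular ↔ interstitial exchange uses a perfusion-scaled
conductance `κ·Q` with κ = 20: large enough that the two spaces track each
other closely (the organ behaves perfusion-limited), finite so that a bolus
front passing the lung is only partially stripped — consistent with the
observed substantial-but-incomplete pulmonary first-pass uptake of
fentanyl. Interstitial ↔ cellular exchange uses a permeability-surface-area
conductance `PS = P · a · V_cell` with a specific cell surface area
a = 1000 cm²/cm³; with fentanyl's calculated permeability this exchange is
fast but not instantaneous, with norfentanyl's fixed 1.8·10⁻² cm/min it is
~18 min⁻¹. Interstitial binding uses an interstitial:plasma binding-protein
ratio of 0.5.

**Elimination.** CYP3A4 and CYP3A7 convert fentanyl to norfentanyl in liver
cells at rate `kcat · E(t) · [E]_ref · V_cell · Cu/(Km + Cu)` on the unbound
cellular concentration; produced norfentanyl enters the metabolite's own
distribution system mol-for-mol. The unspecific hepatic pathway is a
first-order loss (k = 1.46 min⁻¹) from the amount in liver vascular plasma;
an unbound-intracellular variant can be selected
(`unspecific_on_plasma=False`) for sensitivity exploration — the plasma
variant is the default and the documented convention. P-gp effluxes
fentanyl from the cellular space of liver, intestines and kidney into a
terminal efflux accumulator and from brain cells back into brain blood.
Renal filtration removes `GFR_fraction · GFR · fu · C_plasma` from kidney
vascular plasma for both analytes. Six cumulative accumulators (CYP3A4,
CYP3A7, unspecific, parent urine, metabolite urine, P-gp efflux) close the
mass balance; the CYP accumulators are formation trackers whose mass
continues in the metabolite system, so the balance check uses the terminal
sinks plus both analytes' compartment amounts.

**Enzyme inactivation (DDI).** A CYP3A4 relative-activity state obeys
`dE/dt = kdeg (E₀ − E) − kinact · I/(K_I + I) · E` with the perpetrator's
unbound liver concentration I(t) supplied as an external profile
(voriconazole: K_I = 9.33 µmol/L, kinact = 0.015 min⁻¹; kdeg defaults to
5·10⁻⁴ min⁻¹, a ~36 h CYP3A4 turnover half-life). Optional competitive
inhibition multiplies Km by (1 + I/Ki) when a Ki is supplied; the default
is irreversible-only. Because inactivation approaches steady state with a
~70 min time constant at strong exposure, interaction scenarios dose
fentanyl after a pretreatment window (the shipped example uses 24 h),
mirroring clinical designs with perpetrator pretreatment.

## Physiology snapshot

All system-dependent parameters live in a versioned snapshot in
`src/fenpbpk/data/`, assembled from public reference tables:

* `organs.csv` — adult reference (30-year-old male, 73 kg): ICRP-style organ
  volumes and flow fractions; regional vascular fractions chosen so total
  blood is ~5.3 L with 1.20 L in the large-vein/right-heart pool and 0.55 L
  in the large-artery/left-heart pool (the ICRP regional blood split);
  tissue composition (water, neutral lipid, phospholipid, acidic
  phospholipid, intracellular pH 7.0) from the standard composition tables
  of mechanistic partition methods.
* `maturation.csv` — weight/height/hematocrit by postmenstrual age (PMA) and
  organ-share multipliers (brain ~11% of body weight at term birth, reduced
  muscle and fat, elevated liver/kidney/skin shares, higher blood volume per
  kg). Cardiac output scales as `5.6 L/min · (W/73)^0.75`; GFR as
  `112 mL/min · (W/73)^0.75 · PMA^3.4/(PMA^3.4 + 47.7^3.4)` (sigmoid
  maturation, half-mature at ~48 weeks PMA).
* `ontogeny.csv` — piecewise-linear fraction-of-adult tables: CYP3A4 rising
  from ~0.11 at term to 1.0 by ~4 years; CYP3A7 ~12× the adult remnant at
  birth, decaying over months; P-gp from proteomic age-group medians; and
  the AAG plasma-concentration ratio. The AAG table passes through two
  anchor ratios (0.533 at PMA 32 wk, 0.643 at 2.9 y) chosen so that
  unbound-fraction scaling from the adult 20.8% reproduces the established
  pediatric values of 33% (preterm) and 29% (2.9 y); the remaining knots
  follow the published monotone maturation shape toward the adult level.
* `enzymes.csv` — effective adult concentrations in the expressing organs'
  cellular space: CYP3A4 4.32 µmol/L (the published open-systems reference
  concentration against which the catalytic constant was standardized),
  CYP3A7 0.35 µmol/L, and small effective P-gp capacities (P-gp carries no
  meaningful terminal-elimination share in the adult pathway split and has
  negligible exposure sensitivity).

Pediatric individuals are specified by gestational plus chronological age;
PMA is the single maturation clock. Ontogeny tables clamp outside their
knot range, so every adult age maps exactly to the adult level. Tissue
composition is held age-independent (only compartment sizes, flows, binding
proteins and enzyme levels mature) — a deliberate simplification.

## Distribution inputs

Fentanyl (base, pKa 8.99, logP 3.49) uses the ion-partitioning method for
moderate-to-strong bases: extracellular/intracellular water with pH
partitioning (pH 7.0 cell / 7.4 plasma), neutral lipid and phospholipid
terms, and electrostatic association with acidic phospholipids whose
association constant is back-calculated from the blood-to-plasma ratio 0.87
via erythrocyte partitioning (erythrocyte water 0.603, pH 7.22, acidic
phospholipid 0.5 mg/g, hematocrit 0.45). Adipose neutral lipid uses the
vegetable-oil correction `log P_vo = 1.115 logP − 1.35`. Norfentanyl
(pKa 10.03, logP 2.00) uses a membrane-affinity method: phospholipids bind
both species (cation with a 20-fold handicap), neutral storage lipid only
the neutral species. Cellular permeability follows
`log10 P = 0.6 logP − 0.4 log10 MW − 1.0` (cm/min) with a charge-dependent
variant that lets the ionized fraction permeate 20-fold slower; norfentanyl
uses its fixed calculated value 1.8·10⁻² cm/min. Unbound fractions in any
individual come from single-protein (AAG) scaling of the adult values
(fentanyl 20.8%, norfentanyl 81.9%).

## Numerics

The right-hand side is a constant sparse-structured linear operator plus a
handful of Michaelis–Menten terms, integrated segment-wise between dosing
events with the stiff BDF method and an analytic Jacobian. Default
tolerances rtol 10⁻⁹ / atol 10⁻¹² µmol keep the relative mass-balance error
below 10⁻⁶ at every output time (typically ~10⁻¹³); population batch runs
use rtol 10⁻⁷ / atol 10⁻¹⁰. The default output grid is 0.25-min spacing in
the first 10 minutes after each dosing event, 1-min to 2 h, geometric
beyond; peak capture for bolus studies uses an explicit dense early grid.
Boluses are state jumps in the venous pool; infusions are constant inputs
over their window. A degenerate one-compartment model shares the full
dosing/event/integration path and is verified against closed-form bolus and
constant-infusion kinetics to <10⁻⁸ relative error.

Ties and degenerate inputs: zero-dose regimens return identically zero;
single-analyte assemblies route CYP conversion flux to a sink; Cmax/Tmax
take the first grid maximum; AUC_last is the linear trapezoid on the output
grid; clearance prediction adds a log-linear tail (`C_last/λ_z`, slope from
the final 30% of the time span) and warns when the extrapolated share
exceeds 20%.

## Virtual populations

Interindividual variability enters as log-normal multipliers with mean 1 on
the natural scale (σ² = ln(1 + CV²)) on CYP3A4, CYP3A7 and P-gp expression
and on the unspecific clearance rate constant; default CVs 0.35, 0.45, 0.6
and 0.35 — representative literature magnitudes, overridable per run.
Demographic sampling draws age uniformly in a range and weight log-normally
(CV 0.12) around the age-typical value; an individual-patient mode fixes
demographics and varies only the elimination processes. Population profiles
are aggregated pointwise as geometric mean and geometric SD; non-positive
values (pre-dose zeros, censored points) are excluded rather than offset,
because offsets distort the early-time spread.

## Parameter estimation

Fitting minimizes the sum of squared log10 residuals (points below the LLOQ
excluded; LLOQ/2 substitution available) over all supplied profiles, with
uniform random restarts in (log-)bounds refined by bounded Nelder-Mead;
deterministic for a fixed seed. The catalytic constant of the
norfentanyl-formation pathway is weakly identified by parent-only profiles
(exposure sensitivity ≈ −0.3), so recovery under noise uses paired
parent + metabolite profiles, as in the original estimation setting. The
abdominal-surgery scenario fits a single clearance-reduction factor per
individual profile (CYP3A4, CYP3A7 and unspecific pathways scaled by
1 − factor; renal filtration untouched) by bounded scalar minimization.

## Synthetic data

The fixture library (`data/studies.csv`) transcribes the dosing regimens,
demographics and sampling sites of the adult model-building and pediatric
evaluation study arms (0.3–60 µg/kg boluses and short infusions, 24–58 h
infusions, loading + maintenance schemes, arterial and venous sampling).
Synthetic observed datasets are model simulations sampled at assay-like
times, multiplied by log-normal noise (matching the log-scale evaluation
statistics) and censored below an LLOQ with censored points dropped. They
emulate the sampling schedules, noise level and censoring of digitized
clinical profiles but not real-data features such as model misspecification,
assay-specific error structure, co-medication effects or within-subject
time-varying physiology — so closed-loop tests demonstrate correctness of
the machinery and identifiability under the stated noise, not clinical
predictive accuracy.

## Design choices made where the design was open

* Unspecific hepatic clearance acts on liver vascular plasma (its printed
  description: first-order elimination from plasma in the liver); the
  intracellular variant is provided as a config switch.
* CYP3A4/3A7 metabolism is restricted to liver cells; P-gp is enabled in
  liver, gut, kidney (terminal) and brain (to blood), configurable.
* The perpetrator concentration driving inactivation is the unbound liver
  concentration from the supplied profile.
* The blood-to-plasma ratio stays at the adult 0.87 for all ages, flagged in
  every scaling report (no pediatric measurement exists).
* The unspecific clearance rate constant is age-independent; an ontogeny on
  it can be emulated via expression multipliers but is deliberately not a
  default.
* Problem sizes in tests and in the acceptance script: the adult
  pathway-split run uses a single 7-day simulation; the neonatal peak
  ladder uses populations of 100 with a fixed seed; recovery tests use
  12-point, 24–36 h profiles with 2 restarts.

## Known limitations

* The physiology snapshot is assembled from public reference tables; it is
  not any proprietary database, so absolute exposures carry snapshot
  uncertainty even where pathway splits and scalings are robust.
* Norfentanyl kinetics are evaluated against adult-style synthetic data
  only; its pediatric behavior inherits the parent's scaling assumptions.
* Oral, transdermal and sublingual routes, pharmacodynamics, pregnancy and
  organ-impairment populations are out of scope.
* Correlations between enzyme expressions, and covariates beyond
  age/weight/sex, are not modeled.
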