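# Methods

This note records the models implemented in solvtol, the defaults and
their units, and the reasoning behind choices the assay description
leaves open.

## Closed-vial partitioning (`solvtol.chem`)

A dose of volatile solvent in a sealed vial is assumed to reach
three-way equilibrium between aqueous phase, headspace and (beyond the
aqueous solubility) a free liquid phase.  Below solubility:

    n_total = C_aq · V_aq + H_cc · C_aq · V_gas

so `C_aq = n_total / (V_aq + H_cc · V_gas)`.  Above solubility S, the
aqueous phase is pinned at S, the headspace at `H_cc · S`, and the
remainder is free phase.  The *nominal* concentration `n_total / V_aq`
is reported alongside, because dose series are labelled on that scale
once free phase is present.  Mass balance holds to 1e−9 relative by
construction and is property-tested.

Units: µmol for amounts, mmol L⁻¹ for concentrations, mL for volumes,
°C for temperatures (µmol/mL ≡ mmol L⁻¹, so no hidden factors).

**Henry constants.**  `H_cc` is the dimensionless gas/aqueous
concentration ratio.  Between tabulated temperatures, ln H_cc is
interpolated linearly against 1/T(K) — the van't Hoff form, which is
how Henry-constant temperature dependence is conventionally
parameterised.  Outside the table the nearest endpoint is used with a
`UserWarning` rather than an error, because incubation temperatures
legitimately range over 24–37 °C across species while shipped tables
cover 20–37 °C.  The packaged constants (`data/solvents.toml`) are
literature values chosen by the implementer — molar masses, liquid
densities, log P_o/w (1.48 / 1.97 / 2.64 / 2.88 for 1,2-DCA / CF / CT /
PCE), solubilities (0.9, 5, 66.6, 86.9 mM) and H_cc near 25 °C extended
by van't Hoff — and are editable data, not hard-coded truth.

**Dosing.**  Neat doses convert via `volume · density / molar mass`;
ethanolic stocks via `volume · molarity`.  The ethanol carrier's effect
on partitioning and growth is ignored: at the µL volumes involved it is
negligible, and ethanol-only controls show no growth difference.
Kinetics of equilibration are out of scope (vials equilibrate overnight
before inoculation); only the equilibrium state is modelled.

## Growth kinetics (`solvtol.growth`)

μ is the least-squares slope of ln(OD600) versus time within the
exponential window; on an exact exponential this equals the two-point
form `ln(X_t/X_0)/t` for any pair of in-window points, which is the
classical definition it generalises.

**Zero-growth rule.**  μ = 0 is assigned when the OD never rises above
0.04, when the trace decreases overall (final reading below the first
and total rise under 0.02 — the two-part form makes the rule robust to
single-reading noise), or when no exponential window exists.

**Window detection.**  Among all contiguous windows of ≥ `min_points`
(default 3) readings with OD above a quantification floor, the
*longest* window whose log-linear fit has positive slope and
R² ≥ `r2_min` (default 0.998) is selected; ties go to the steeper, then
the earlier window.  Two numerical facts drive this design, both
measured on the simulator at the stated read noise (SD 0.005 OD):

* maximising the slope instead selects short noise-inflated windows at
  low OD and overestimates μ by 13–40% (median);
* a lenient gate (R² ≥ 0.98) lets the longest window absorb one
  stationary-phase reading, underestimating μ by ~8%.

The floor (default 0.04, deliberately the same value as the zero-growth
threshold) excludes readings where additive read noise dominates
ln(OD); the strict gate excludes the stationary roll-over.  With both,
median recovery error is 1.4–2% across μ from 0.1 to 1.0 h⁻¹.  On
noiseless data the rule reduces to the obvious one: a globally
log-linear curve yields the full span, and lag/plateau segments are
excluded exactly.  All three knobs are keyword arguments.

**Percent of control.**  μ₀ is the mean over no-solvent control
replicates (all solvents of a species are assayed against one shared
control set from the same batch); each treated replicate is reported as
100·μ/μ₀.  An assay whose controls all fail is invalid and raises.

## EC50 estimation (`solvtol.doseresp`)

Estimation is model-free linear interpolation, not a parametric
Hill/4PL fit — the dose-response shape is deliberately left to the data
(the logistic shape exists only in the simulator).  Rules, in order:

1. **Left-censoring first:** if the lowest tested dose already shows no
   growth (0%), the EC50 is below it and is reported as a bound.
   Checking this before interpolation matters: the implicit control
   (0, 100%) would otherwise produce a spurious interpolated value
   whose position reflects dose spacing, not biology.
2. **Interpolation:** scanning upward in concentration with the control
   point prepended, the first segment crossing 50% from above is
   interpolated linearly.  On non-monotone curves this yields the
   lowest (conservative) crossing.
3. **Extrapolation / right-censoring:** if every percent exceeds 50, an
   OLS line through all points (control included — it is a real
   observation and excluding it is a keyword away) is solved for 50%;
   a non-decreasing fit is right-censored at the highest tested dose.

Percent values are floored at 0; values above 100 (growth stimulation)
are legal and handled by the crossing scan.

**Replicates.**  Default is replicate-first: one EC50 per replicate
curve, then mean ± sample SD across replicates, so the spread describes
the EC50 itself.  An `average_curve` mode (average the percents, then
estimate once) is provided since either convention is defensible when
error bars on EC50s are reported.  When replicates disagree in
censoring class, the majority class is reported and the conflict is
kept in diagnostics.

## Tolerance analytics (`solvtol.tolerance`)

* **Percent of solubility** `100 · EC50 / S`, reported raw and rounded;
  censored estimates produce `<`/`>` annotations from their bounds.
* **Free-phase tolerance**: EC50 (or right-censored bound) strictly
  above S, meaning the organism still grows at ≥ 50% of μ₀ with a
  separate solvent phase present.  By construction this is equivalent
  to percent-of-solubility > 100.
* **Normalized tolerance scores**: per solvent, 100 · EC50 / EC50_ref;
  the four per-solvent scores are averaged into one species score.  The
  default reference is the per-solvent maximum-EC50 species (a fixed
  most-tolerant reference species behaves identically when it tops
  every solvent; a species name can be passed instead).  Censored
  estimates enter through their bounds and are flagged rather than
  dropped — dropping them would silently bias multi-species averages —
  with an `exclude` switch for the alternative.
* **Regressions**: unweighted OLS (no weighting scheme is implied by
  the assay) of per-solvent EC50s, or of the averaged normalized score,
  on μ₀; needs ≥ 3 species with point estimates and non-degenerate μ₀
  variance.
* **Toxicity ranking**: solvents sorted by ascending EC50 per species,
  with every pairwise inversion of the hydrophobicity rule (more toxic
  despite lower log P_o/w) reported.

**Curated panel.**  `load_curated_results()` returns 32 records (eight
species × four solvents) transcribing published EC50 outcomes: point
values where a number is printed, left/right-censored bounds where
growth failed at the lowest dose or never halved, and `[lo, hi]` ranges
where only a bracket is stated.  Records carry qualitative flags
(`above_pce_solubility`, `no_growth_at_lowest`) and a textual source
locator; no value is digitized from a figure.  Range records expose
their conservative lower end via `effective_value`.

## Synthetic assays (`solvtol.simulate`)

The generator encodes the structure the analysis assumes: per species,
a lag (default 2 h), exponential growth from OD 0.02 to a hard plateau
at 0.8, and phase timing shared across concentrations so that solvent
changes only the *rate*: μ(c) = μ₀ · f(c) with

* `linear`: f = max(0, 1 − c/(2·EC50)),
* `logistic`: f = 1/(1 + (c/EC50)^h), default Hill slope 2,

both exactly 1 at c = 0 and 0.5 at the EC50.  Noise is additive
Gaussian per reading (default SD 0.005 OD), truncated at 0 —
spectrophotometer read noise, which dominates at the low ODs where fit
windows sit; multiplicative (proportional) noise is deliberately not
modelled.  The default layout is five doses + control, triplicate, 13
time points spanning lag + 1.2× the control's time to plateau; dose
series default to geometric spacing (ratio 2) bracketing the pair's
true EC50, mimicking a well-designed assay.  Seeds are mandatory and
runs are bit-reproducible.

The default eight-species panel spans μ₀ from 0.08 to 1.0 h⁻¹ and EC50s
echoing the curated panel's ordering (1,2-DCA mildest; respirers most
sensitive), so end-to-end demos behave like the real assay.

**What a green test establishes.**  The generator omits several
features of real data: smooth (non-hard) stationary transitions, death
phases, batch/position effects, lag shifts under solvent stress, and
co-solvent interactions.  Recovery results therefore validate the
estimators under the assay's own idealisations — growth that varies
only in rate — not against every failure mode of a spectrophotometer
time series.

## Pipeline and I/O (`solvtol.io`)

Long-form CSV for OD data (`time_h, species, solvent, conc_mM,
replicate, od600`, optional `is_blank`; or dose columns
`mode, volume_ul, stock_M` resolved through the vial model using
per-species incubation temperatures), TOML for constants, JSON for the
report.  Blanks are averaged per species × time point and subtracted.
Validation errors carry row indices; duplicated (condition, time) rows
are rejected.  Concentrations switch to the nominal scale for a
species × solvent block as soon as any dose exceeds solubility, and the
switch is logged.  `run_report` logs every judgment call — zero-growth
assignments, censoring, extrapolations, scale switches, skipped
regressions — because these are exactly the decisions a reader of an
EC50 table needs to audit.  Identical inputs produce byte-identical
outputs.

## Known limitations

* Single-solvent partitioning only: no competitive multicomponent
  equilibria, sorption to stoppers, or dissolution kinetics.
* The EC50 estimator reports no confidence interval beyond replicate
  SD; a parametric fit would, but is out of scope by design.
* Censored estimates propagate as bounds, not by survival-analysis
  likelihood methods; with five doses per curve anything richer would
  be overfitting.
* Regression of raw EC50s pools nothing across solvents (scales are
  incommensurate); only the normalized score collapses solvents.
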