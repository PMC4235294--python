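# Methods

## Model structure

The PBPK/PD model tracks carbaryl amounts (nmol) in seven pools — GI tract,
liver, fat, brain, rest-of-body, plasma and red blood cells — plus a
1-naphthol (1-N) disposition pool, cumulative urinary 1-N, cumulative
"other metabolites", and active/carbamylated acetylcholinesterase (E, EC)
in brain and RBC: 14 states.

Oral dosing adds the event dose directly to the GI tract; absorption is
first-order (ka) into the liver. Each perfused tissue t exchanges with
plasma through an effective conductance

    K_t = Q_t · PA_t / (Q_t + PA_t)        [L/h]

(tissue blood flow and membrane permeability–area in series) driven by the
free-concentration gradient `C_plasma − C_t/P_t`, where P_t is the
tissue:plasma partition coefficient. This is the diffusion-limited
single-pool form: at the shipped defaults PA_t ≪ Q_t, so K_t ≈ PA_t and
membrane permeability is rate-limiting; the series form was preferred over
a bare PA_t flux because it keeps cardiac output and flow fractions as live
model parameters and degrades gracefully if a user configures PA_t ≳ Q_t.
Plasma and RBC exchange through PA_rbc directly (no flow limitation within
blood).

Carbaryl hydrolyses to 1-N in every compartment (first-order k_hyd,t; an
optional Michaelis–Menten branch for hepatic hydrolysis ships disabled —
dietary doses sit orders of magnitude below saturation). The 1-N pool
(volume V_1N) loses to urine at CL_u/V_1N and to unspecified further
metabolites at k_met. AChE kinetics at each site s ∈ {brain, RBC}:

    dE/dt  = k_syn − k_deg·E − k_i·C_s·E + k_r·EC
    dEC/dt = k_i·C_s·E − k_r·EC

with C_s the carbaryl concentration in brain tissue or RBC (µM).
Carbamylation consumes one carbaryl equivalent; decarbamylation releases
the naphthol moiety into the 1-N pool, so summed over all pools the system
conserves administered moles exactly between dose events — the test suite
asserts ≤1e−6 relative error at every output grid point, and the solver
typically achieves ~1e−15.

Because synthesis continues at full rate while enzyme is carbamylated, the
total E+EC can transiently exceed baseline after exposure ends, so active
enzyme briefly overshoots E0 (a small negative "inhibition", worst case
about −0.1 % after a milligram bolus). Time-course series report this
rebound as-is; biomarker panels clip inhibition at 0 %, matching the
baseline-=-0 % reporting convention.

## Numerics

Boluses are applied as state jumps with a solver restart at each event
(exact, no forcing-function smearing). Integration uses LSODA with an
analytic Jacobian, rtol 1e−9/atol 1e−13 for single-run work and rtol 1e−7
inside the Monte Carlo loop; output is dense-evaluated on a uniform 1-min
grid (spot sampling needs minute resolution; the sensitivity screen uses
5-min output since it only reads peaks and cumulative amounts). Grid values
are right-continuous at events. An independent fixed-step RK4 oracle at
0.01-min steps agrees with the adaptive solution to ≤1e−4 relative on a 6-h
single-dose problem.

Terminal half-life is estimated by log-linear regression of plasma
concentration over 36–72 h after a single bolus, where the decline is
log-linear to visual accuracy.

## Default parameterization

The shipped `default_params.yaml` is a literature-plausible reference-adult
(70 kg) set, explicitly calibrated to two behavioral targets rather than
copied from any published compilation:

* terminal plasma half-life after an oral bolus = 9.0 h (36–72 h fit) —
  the accepted human value for carbaryl; the fat depot (P_fat 24, PA_fat
  8 L/h, k_hyd,fat 0.065/h) controls the terminal phase;
* 1-N elimination slower than carbaryl clearance: k_met + CL_u/V_1N =
  0.053/h (t½ ≈ 13 h versus 9 h) — the mechanism by which spot urinary 1-N
  integrates roughly the prior two days of intake.

PD rates are physiologically motivated: decarbamylation k_r = 1.4/h
(carbamylated AChE recovers with a ~30-min half-time; no aging for
carbamates), brain AChE turnover k_deg = 0.004/h (~1 week), and RBC AChE
k_deg = 4e−4/h because circulating red cells do not resynthesize the enzyme
— renewal is erythropoiesis-limited. The parameter file has 44 scalar
parameters; the configuration schema documents every unit.

## Sensitivity screen and Monte Carlo

The screen perturbs each parameter by +1 % (forward difference) under a
standardized, deterministic exposure: a week of constant-rate oral intake
(implemented as a zero-order GI infusion so the screening input has no
event-timing arbitrariness), repeated at 29.7, 426 and 426 000 ng/kg/day.
Outputs: cumulative urinary 1-N (µmol), peak % AChE depression in brain and
RBC, peak brain carbaryl amount (µmol), peak plasma concentration (µM). A
parameter is sensitive when |NSC| > 0.1 for any output at any level (the
absolute value is the defensible reading of a one-sided threshold). With
first-order kinetics the three concentration-type outputs give
dose-invariant NSCs; the %-depression outputs saturate mildly at the 1000×
dose, which is why classification stability also depends on parameters not
sitting exactly at the 0.1 boundary. Under the shipped defaults 21
parameters are sensitive and the set is identical at all three dose levels.

Monte Carlo varies the sensitive parameters (body weight excepted — it is a
fixed per-subject input) with declared-assumption spreads: lognormal GSD
1.3 for kinetic constants, normal CV 0.3 for volume fractions, truncated at
±3σ (GSD³ on the log scale). A joint draw that violates a structural
invariant (volume fractions summing above 1) is rejected and redrawn.
Per subject, the exposure profile, body weight and urine output are fixed
across the 10 (or 2, at desk scale) repetitions; parameters and the spot
sampling/void times are re-sampled per repetition. Seeding is hierarchical
(master seed → stage → subject → repetition), so any single iteration can
be replayed in isolation.

## Synthetic population: what it emulates and what it does not

The generator reproduces the *stated statistical structure* of a
dietary-exposure simulation for U.S. adults: year-average doses lognormal
(GM 70.2 ng/kg/day, GSD 1.84 — both recovered by a lognormal fit over 500
subjects within sampling error), daily event counts with support [1, 23]
and median 4 (shifted negative binomial, truncated), and uniform ages
20–90. Body-weight (sex-specific GM 83/68 kg, GSD 1.25) and urine-output
(GM 1.0 mL/min, GSD 1.9) distributions are chosen to match adult ranges;
they scale results without changing the qualitative regression findings.
Event clock times follow a three-peak mealtime mixture truncated to waking
hours (uniform fallback available). Event doses get a per-day lognormal
multiplier (GSD 2.0) plus per-event noise (GSD 2.2), then one global rescale
so each subject's realized year-average equals the target exactly (≤1e−9
relative) — so the fitted population distribution is exactly the configured
one.

Not emulated: true dietary residue dynamics (seasonality, market-share
correlation between days), food-vs-water source structure, within-person
correlation of meal size and dose, children. Passing tests therefore
demonstrate internal consistency of the pipeline under this declared
structure, not fidelity to any real population's exposure time series.

## Regression analyses

Four analysis sets over the iteration panels, all plain OLS with intercept
on raw scales (slope = biomarker sensitivity in the analytical-chemistry
sense; R² = explained/total variation; no multiple-testing correction):
urinary 1-N vs four dose windows; six outputs vs the 2-day window; 24-h
inhibition vs dose restricted to >50 ng/kg/day (strict inequality); and
brain-inhibition / brain-concentration predictor comparisons. A
zero-variance response reports R² = 0 with a warning so degenerate
fixtures remain analyzable.

Three qualitative orderings are computed as boolean flags: the 2-day window
explains spot urinary 1-N best; RBC inhibition tracks brain inhibition
better than either chemical marker; spot urinary 1-N beats spot plasma
carbaryl for predicting the 24-h brain concentration. These are
calibration-dependent and reported rather than asserted: on raw scales the
R² of lognormal-tailed data is dominated by high-leverage points, so at
desk scale (100 panels) the orderings fluctuate with the seed, while
log-scale correlations already show the 2-day window winning. Runs of a few
hundred panels and above reproduce the expected raw-scale ordering
(year ≈ 0 < week < 24-h < 2-day).

## Problem sizes

The shipped test and acceptance configurations use the full 500-subject
population wherever it is cheap (population statistics, profile
generation) and a 50 × 2 desk profile for the Monte Carlo loop — the same
code path as 500 × 10, which is the configuration a user would run for
production numbers (`--profile full`; roughly an hour of integration on one
core at 1-min output resolution).

## Known limitations

* Single-pool diffusion-limited tissues; no explicit tissue-blood
  sub-compartments, no enterohepatic recirculation, no protein binding.
* The 1-N pool is a one-compartment stand-in; only urinary 1-N is
  mechanistically meaningful downstream.
* Chemical parameters (PA, CL_u, V_1N) do not scale with body weight; only
  volumes (∝ BW) and cardiac output (∝ BW^0.75) do.
* Measurement realism (limits of detection, creatinine correction, assay
  error) is deliberately out of scope; simulated spot concentrations are
  exact.
* Carbamylated enzyme is not degraded (EC decays only by decarbamylation);
  at carbamate-realistic k_r this is inconsequential, but it is the cause
  of the small post-exposure inhibition rebound noted above.
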