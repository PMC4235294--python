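# carbarylsim

Linked exposure–PBPK/PD simulation and biomarker-utility analysis for the
carbamate insecticide **carbaryl**.

## The problem

Biomonitoring surveys measure biomarkers — urinary metabolites, blood
concentrations, enzyme activities — and then want to infer either *exposure*
(how much did this person take in, and over what period?) or *effect* (how
inhibited is acetylcholinesterase at the target tissue, the brain, which
cannot be sampled in living people?). Whether a given biomarker supports
either inference depends on kinetics: absorption, distribution, metabolism
and excretion set the time window a marker integrates and the tightness of
its coupling to the target-tissue dose.

`carbarylsim` answers this quantitatively for carbaryl by simulation:

1. **Virtual population** — 500 adults (ages 20–90) with lognormal
   year-average dietary carbaryl doses (GM 70.2 ng/kg/day, GSD 1.84) and
   365-day schedules of discrete oral exposure events (1–23/day, median 4),
   plus per-subject body weight and urine output (bladder-filling rate).
2. **PBPK/PD model** — a 14-state ODE system: carbaryl amounts in GI tract,
   liver, fat, brain, rest-of-body, plasma and red blood cells
   (diffusion-limited tissues), hydrolysis to 1-naphthol (1-N) in every
   compartment, a 1-N disposition pool with urinary and metabolic clearance,
   and reversible AChE carbamylation kinetics
   (dE/dt = k_syn − k_deg·E − k_i·C·E + k_r·EC) in brain and RBC.
3. **Spot sampling** — a sampling time drawn from the final 24 h and a most
   recent void >1 h earlier define the spot urinary concentration
   `(moles_sampling − moles_mrv) / ((t_sampling − t_mrv) · urine_output)`.
4. **Sensitivity screen + Monte Carlo** — normalized sensitivity
   coefficients (forward difference, |NSC| > 0.1) over all parameters, five
   outputs, three dose levels; then subjects × repetitions iterations
   re-sampling the sensitive parameters and sampling times.
5. **Regression analysis** — ordinary least squares of each biomarker
   against windowed dose averages (prior year / week / 2 days / 24 h),
   against brain AChE inhibition, and against the 24-h average brain
   carbaryl concentration, reporting slope, intercept, R² and n.

## Worked example

```bash
python examples/01_single_dose_kinetics.py
```

```
dose:                         1.00 mg oral bolus at t=0
peak plasma carbaryl:         67.7 nM at t = 0.6 h
terminal half-life (36-72 h): 9.01 h
peak brain AChE inhibition:   2.75 %
urinary 1-naphthol by 72 h:   2990 nmol (60 % of dose)
mass-balance error:           2.7e-15 (relative)
```

Absorption is fast (peak within the hour), the terminal half-life sits at
the ~9 h reported for carbaryl in humans (a calibration target of the
shipped default parameter file), a milligram bolus produces only a few
percent transient brain AChE inhibition, and most of the dose leaves as
urinary 1-naphthol — the biomarker of exposure. Moles are conserved to
machine precision across the week.

The other examples build the population (`02`), assemble a spot biomarker
panel for one subject-week (`03`), run the sensitivity screen (`04`), and
run the whole desk-scale pipeline with regression reports (`05`). The same
pipeline is scriptable from the shell:

```bash
carbarylsim --out run1 --seed 1 all --profile desk   # 50 subjects x 2 reps
carbarylsim --out run1 analyze --dose-floor 50
```

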