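# Default carbaryl PBPK/PD parameterization.
#
# Reference adult, 70 kg.  These are defaults for reproduction of the
# model's qualitative kinetic behaviour (oral-bolus terminal plasma
# half-life ~9 h; urinary 1-naphthol eliminated more slowly than carbaryl),
# not a published physiological compilation.
#
# Units: body_weight kg; cardiac_output L/h; volume fractions = fraction of
# body weight (density 1 kg/L); flow fractions = fraction of cardiac output;
# urine_output L/min; ka and all first-order rates 1/h; permeability_area
# L/h; clearance L/h; naphthol_volume L; k_syn nmol/h; k_i 1/(uM.h);
# mm_vmax nmol/h; mm_km nM.

physiology:
  body_weight: 70.0
  cardiac_output: 348.0
  tissue_volume_fraction:
    liver: 0.026
    fat: 0.21
    brain: 0.02
    rest: 0.52
    blood: 0.079
  blood_flow_fraction:
    liver: 0.25
    fat: 0.05
    brain: 0.12
    rest: 0.55
  hematocrit: 0.45
  urine_output: 0.001

chemical:
  ka: 1.5
  partition_coefficient:
    liver: 2.5
    fat: 24.0
    brain: 3.0
    rest: 2.5
    rbc: 1.2
  permeability_area:
    liver: 30.0
    fat: 8.0
    brain: 6.0
    rest: 40.0
    rbc: 150.0
  hydrolysis_rate:
    gi: 0.05
    liver: 1.2
    fat: 0.065
    brain: 0.15
    rest: 0.15
    plasma: 0.25
    rbc: 0.1
  naphthol_metabolism_rate: 0.02
  naphthol_urinary_clearance: 0.6
  naphthol_volume: 18.0
  mm_enabled: false
  mm_vmax: 50000.0
  mm_km: 50000.0

pd:
  # brain AChE turnover ~ 1 week; RBC AChE renewal is erythropoiesis-limited
  # (enzyme is not resynthesized within a circulating red cell)
  brain:
    k_syn: 0.004
    k_deg: 0.004
    k_i: 0.4
    k_r: 1.4
  rbc:
    k_syn: 0.002
    k_deg: 0.0004
    k_i: 0.5
    k_r: 1.4

# Monte Carlo distributions for the parameters flagged sensitive by the
# shipped local sensitivity screen (|NSC| > 0.1 for any output at any dose
# level).  Body weight is also sensitive but is a fixed per-subject input,
# not a Monte Carlo variable.  Kinetic constants: lognormal, GSD 1.3;
# physiological fractions: normal, CV 0.3.  Spreads are declared
# assumptions, overridable here.
monte_carlo:
  - {parameter: chemical.hydrolysis_rate.brain, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.hydrolysis_rate.liver, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.hydrolysis_rate.rest, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.naphthol_metabolism_rate, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.naphthol_urinary_clearance, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.naphthol_volume, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.partition_coefficient.brain, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.partition_coefficient.liver, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.partition_coefficient.rbc, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.partition_coefficient.rest, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.permeability_area.fat, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.permeability_area.liver, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: chemical.permeability_area.rest, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: pd.brain.k_i, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: pd.brain.k_r, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: pd.rbc.k_i, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: pd.rbc.k_r, shape: lognormal, spread: 1.3, sensitive: true}
  - {parameter: physiology.tissue_volume_fraction.brain, shape: normal, spread: 0.3, sensitive: true}
  - {parameter: physiology.tissue_volume_fraction.liver, shape: normal, spread: 0.3, sensitive: true}
  - {parameter: physiology.tissue_volume_fraction.rest, shape: normal, spread: 0.3, sensitive: true}
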