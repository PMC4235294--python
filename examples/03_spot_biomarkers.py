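"""One subject, one week: spot biomarker panel.

Simulates the final exposure week of one generated subject, draws a random
spot-sampling time (and a most-recent-void time >1 h earlier) from the last
24 h, and assembles the full observable panel: spot urinary 1-naphthol,
spot plasma carbaryl, spot and 24-h AChE inhibition in brain and RBC, the
24-h average brain carbaryl (the inaccessible target-tissue dose), and the
four windowed dose metrics the biomarkers are regressed against.
"""

from carbarylsim import (
    assemble_panel,
    default_params,
    draw_exposure_profile,
    draw_subjects,
    extract_week,
    sample_spot_times,
    simulate,
)

params = default_params()
subject = draw_subjects(10, seed=4)[2]
profile = draw_exposure_profile(subject, seed=4)
events = extract_week(profile, end_day=365)

week_min = 7 * 1440.0
tc = simulate(params, events, week_min)
times = sample_spot_times(seed=4, sim_end=week_min)
panel = assemble_panel(tc, profile, subject, times)

print(f"subject: {subject.body_weight:.0f} kg, urine output "
      f"{subject.urine_output * 1000:.2f} mL/min, {len(events)} events this week")
print(f"sampled at minute {times.t_sampling:.0f}, last void {times.t_sampling - times.t_mrv:.0f} min earlier")
for name, value in panel.as_dict().items():
    print(f"  {name:28s} {value:12.4g}")
print("dose metrics are ng/kg/day; a spot urine value integrates excretion")
print("since the last void, which is why it tracks the ~2-day dose window.")
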