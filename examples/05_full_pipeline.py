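"""The whole study at desk scale: population -> Monte Carlo -> regressions.

Runs 50 subjects x 2 repetitions (the scaled-down profile of the full
500 x 10 design; same code path), then fits the four regression analysis
sets and prints each slope/R² with the question it answers.  Expect a few
minutes of runtime.  The qualitative R² orderings are calibration- and
scale-sensitive: at 100 panels the raw-scale R² of lognormal-tailed data is
leverage-noisy, so flags here can differ from a full-scale run.
"""

from pathlib import Path

from carbarylsim.pipeline import run_all

outdir = Path("pipeline_desk_out")
manifest = run_all(None, outdir, master_seed=1, profile="desk")

print(f"outputs in {outdir}/ (subjects, exposures, sensitivity, panels, results, plots)")
print("stage timings:", {k: f"{v:.0f}s" for k, v in manifest.timings_s.items()})

import pandas as pd

results = pd.read_csv(outdir / "results.csv")
print("\nregression results (y = slope*x + intercept):")
for _, r in results.iterrows():
    print(f"  [{r.analysis_set}] {r.y_metric} ~ {r.x_metric}"
          f"{'' if r.subset == 'all' else ' | ' + r.subset}: "
          f"slope={r.slope:.3g}, R2={r.r_squared:.3f}, n={r.n}")

print("\nqualitative flags (calibration-dependent):")
for k, v in manifest.qualitative_flags.items():
    print(f"  {k}: {v}")
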