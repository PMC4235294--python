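"""Biomarker-utility regression analyses over the Monte Carlo panels.

Four analysis sets of ordinary least squares fits, each reporting slope,
intercept, R² and n:

1. spot urinary 1-naphthol vs the dose averaged over each of four exposure
   windows (prior year / week / 2 days / 24 h) — which exposure period does
   the urinary biomarker reflect?
2. six model outputs vs the 2-day average dose — which output tracks recent
   intake best?
3. 24-h-averaged brain and RBC AChE inhibition vs the 2-day average dose,
   restricted to doses strictly above a floor (default 50 ng/kg/day) —
   does a correlation emerge once un-inhibited low-dose subjects are
   excluded?
4. (a) brain AChE inhibition (the inaccessible effect metric) vs each
   accessible marker; (b) 24-h-average brain carbaryl (the target-tissue
   dose) vs the two candidate exposure biomarkers.

R² follows the explained-variation/total-variation definition; a
zero-variance response is reported as R² = 0 with a warning rather than NaN
so degenerate fixtures stay analyzable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "ols_fit",
    "analysis_set_1",
    "analysis_set_2",
    "analysis_set_3",
    "analysis_set_4",
    "run_all_analyses",
    "qualitative_flags",
    "results_to_frame",
    "report",
]


@dataclass(frozen=True)
class RegressionResult:
    x_metric: str
    y_metric: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    subset: str = "all"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n < 3:
            raise ValueError(f"need n >= 3, got {self.n}")


def ols_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_metric: str = "x",
    y_metric: str = "y",
    subset: str = "all",
) -> RegressionResult:
    """Simple linear regression of y on x with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate fit: {x_metric} is constant")
    if np.ptp(y) == 0:
        warnings.warn(
            f"{y_metric} has zero variance; R² reported as 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return RegressionResult(x_metric, y_metric, 0.0, float(y[0]), 0.0, x.size, subset)
    fit = stats.linregress(x, y)
    return RegressionResult(
        x_metric=x_metric,
        y_metric=y_metric,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(x.size),
        subset=subset,
    )


DOSE_WINDOWS = ("dose_avg_year", "dose_avg_week", "dose_avg_24h", "dose_avg_2day")

SET2_OUTPUTS = (
    "spot_urinary_1n_nM",
    "avg24_brain_carbaryl_pM",
    "spot_inhibition_brain_pct",
    "spot_inhibition_rbc_pct",
    "avg24_inhibition_brain_pct",
    "avg24_inhibition_rbc_pct",
)


def _col(panels: pd.DataFrame, name: str) -> np.ndarray:
    if name not in panels.columns:
        raise KeyError(f"panels table lacks column {name!r}")
    return panels[name].to_numpy(dtype=float)


def analysis_set_1(panels: pd.DataFrame) -> list[RegressionResult]:
    """Spot urinary 1-N (nM) regressed on each windowed dose average."""
    y = _col(panels, "spot_urinary_1n_nM")
    return [
        ols_fit(_col(panels, w), y, x_metric=w, y_metric="spot_urinary_1n_nM")
        for w in DOSE_WINDOWS
    ]


def analysis_set_2(panels: pd.DataFrame) -> list[RegressionResult]:
    """Each of six model outputs regressed on the 2-day average dose."""
    x = _col(panels, "dose_avg_2day")
    return [
        ols_fit(x, _col(panels, out), x_metric="dose_avg_2day", y_metric=out)
        for out in SET2_OUTPUTS
    ]


def analysis_set_3(
    panels: pd.DataFrame, dose_floor: float = 50.0
) -> list[RegressionResult]:
    """24-h-averaged inhibition vs 2-day dose, doses strictly above the floor."""
    kept = panels[panels["dose_avg_2day"] > dose_floor]
    if kept.empty:
        raise ValueError(f"no panels with 2-day average dose > {dose_floor}")
    x = _col(kept, "dose_avg_2day")
    subset = f"dose_avg_2day > {dose_floor:g}"
    return [
        ols_fit(x, _col(kept, out), x_metric="dose_avg_2day", y_metric=out, subset=subset)
        for out in ("avg24_inhibition_brain_pct", "avg24_inhibition_rbc_pct")
    ]


def analysis_set_4(panels: pd.DataFrame) -> list[RegressionResult]:
    """(a) brain inhibition vs accessible markers; (b) 24-h brain carbaryl vs
    the two candidate exposure biomarkers."""
    results = [
        ols_fit(
            _col(panels, "spot_inhibition_rbc_pct"),
            _col(panels, "spot_inhibition_brain_pct"),
            x_metric="spot_inhibition_rbc_pct",
            y_metric="spot_inhibition_brain_pct",
        ),
        ols_fit(
            _col(panels, "avg24_inhibition_rbc_pct"),
            _col(panels, "avg24_inhibition_brain_pct"),
            x_metric="avg24_inhibition_rbc_pct",
            y_metric="avg24_inhibition_brain_pct",
        ),
        ols_fit(
            _col(panels, "spot_urinary_1n_nM"),
            _col(panels, "spot_inhibition_brain_pct"),
            x_metric="spot_urinary_1n_nM",
            y_metric="spot_inhibition_brain_pct",
        ),
        ols_fit(
            _col(panels, "spot_plasma_carbaryl_pM"),
            _col(panels, "spot_inhibition_brain_pct"),
            x_metric="spot_plasma_carbaryl_pM",
            y_metric="spot_inhibition_brain_pct",
        ),
        ols_fit(
            _col(panels, "spot_urinary_1n_nM"),
            _col(panels, "avg24_brain_carbaryl_pM"),
            x_metric="spot_urinary_1n_nM",
            y_metric="avg24_brain_carbaryl_pM",
        ),
        ols_fit(
            _col(panels, "spot_plasma_carbaryl_pM"),
            _col(panels, "avg24_brain_carbaryl_pM"),
            x_metric="spot_plasma_carbaryl_pM",
            y_metric="avg24_brain_carbaryl_pM",
        ),
    ]
    return results


def run_all_analyses(
    panels: pd.DataFrame, dose_floor: float = 50.0
) -> dict[str, list[RegressionResult]]:
    return {
        "set1_dose_windows": analysis_set_1(panels),
        "set2_outputs_vs_2day_dose": analysis_set_2(panels),
        "set3_inhibition_above_floor": analysis_set_3(panels, dose_floor),
        "set4_brain_predictors": analysis_set_4(panels),
    }


def qualitative_flags(results: dict[str, list[RegressionResult]]) -> dict[str, bool]:
    """Calibration-dependent orderings of the regression R² values.

    These are reported, not guaranteed: they depend on the shipped default
    kinetic calibration and the exposure generator's variability structure.

    * ``two_day_window_best`` — among the four dose windows, the 2-day
      average explains spot urinary 1-N best;
    * ``rbc_tracks_brain_inhibition`` — RBC inhibition (spot and 24-h)
      predicts brain inhibition better than either chemical marker;
    * ``urine_beats_plasma_for_brain_dose`` — spot urinary 1-N predicts the
      24-h-average brain carbaryl concentration better than spot plasma
      carbaryl does.
    """
    set1 = {r.x_metric: r.r_squared for r in results["set1_dose_windows"]}
    set4 = {(r.x_metric, r.y_metric): r.r_squared for r in results["set4_brain_predictors"]}
    chem_vs_brain = [
        set4[("spot_urinary_1n_nM", "spot_inhibition_brain_pct")],
        set4[("spot_plasma_carbaryl_pM", "spot_inhibition_brain_pct")],
    ]
    rbc_vs_brain = [
        set4[("spot_inhibition_rbc_pct", "spot_inhibition_brain_pct")],
        set4[("avg24_inhibition_rbc_pct", "avg24_inhibition_brain_pct")],
    ]
    return {
        "two_day_window_best": set1["dose_avg_2day"] == max(set1.values()),
        "rbc_tracks_brain_inhibition": min(rbc_vs_brain) > max(chem_vs_brain),
        "urine_beats_plasma_for_brain_dose": (
            set4[("spot_urinary_1n_nM", "avg24_brain_carbaryl_pM")]
            > set4[("spot_plasma_carbaryl_pM", "avg24_brain_carbaryl_pM")]
        ),
    }


def results_to_frame(results: dict[str, list[RegressionResult]]) -> pd.DataFrame:
    rows = []
    for set_name, rs in results.items():
        for r in rs:
            row = {"analysis_set": set_name}
            row.update({f.name: getattr(r, f.name) for f in dc_fields(r)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting

_PLOT_GROUPS = {
    "set1_dose_windows": "analysis1_dose_windows",
    "set2_outputs_vs_2day_dose": "analysis2_outputs_vs_2day_dose",
    "set3_inhibition_above_floor": "analysis3_inhibition_above_floor",
    "set4_brain_predictors": "analysis4_brain_predictors",
}


def report(
    results: dict[str, list[RegressionResult]],
    panels: pd.DataFrame,
    outdir: str | Path,
) -> list[Path]:
    """Write results.csv and one scatter-plot figure per analysis set.

    File naming is deterministic; the output directory is created if absent.
    Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = outdir / "results.csv"
    results_to_frame(results).to_csv(csv_path, index=False, float_format="%.10g")
    written.append(csv_path)

    for set_name, stem in _PLOT_GROUPS.items():
        rs = results.get(set_name, [])
        if not rs:
            continue
        ncol = 2
        nrow = (len(rs) + ncol - 1) // ncol
        fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 3.6 * nrow), squeeze=False)
        for ax in axes.ravel()[len(rs):]:
            ax.set_visible(False)
        for r, ax in zip(rs, axes.ravel()):
            if r.subset != "all":
                sub = panels[panels["dose_avg_2day"] > float(r.subset.split(">")[-1])]
            else:
                sub = panels
            x = sub[r.x_metric].to_numpy(dtype=float)
            y = sub[r.y_metric].to_numpy(dtype=float)
            ax.plot(x, y, ".", ms=2, alpha=0.4)
            xs = np.array([x.min(), x.max()])
            ax.plot(xs, r.slope * xs + r.intercept, "r-", lw=1)
            ax.set_xlabel(r.x_metric, fontsize=8)
            ax.set_ylabel(r.y_metric, fontsize=8)
            ax.set_title(f"slope={r.slope:.3g}  $R^2$={r.r_squared:.3g}  n={r.n}", fontsize=8)
        fig.tight_layout()
        png = outdir / f"{stem}.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written.append(png)
    return written
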