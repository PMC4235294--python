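"""Spot biomarker sampling and windowed dose metrics.

Turns a simulated week (:class:`~carbarylsim.model.TimeCourse`) plus the
subject's exposure profile into the observable panel: spot urinary
1-naphthol, spot plasma carbaryl, spot and 24-h-averaged AChE inhibition in
brain and RBC, 24-h-average brain carbaryl, and the four windowed dose
metrics (prior year / week / 2 days / 24 h).

The spot urine concentration follows the bladder-accumulation equation

    spot 1-N (nM) = (moles_sampling - moles_mrv)
                    / ((t_sampling - t_mrv) * urine_output)

with cumulative urinary amounts in nmol, times in min and urine output in
L/min; cumulative amounts are interpolated linearly on the output grid.
Sampling times are uniform over the final 24 h of the simulation, with the
most recent void (mrv) more than 1 h before the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .model import TimeCourse
from .population import MINUTES_PER_DAY, ExposureProfile, Subject

MIN_VOID_GAP_MIN = 60.0


@dataclass(frozen=True)
class SpotSampleTimes:
    """Spot-sample and most-recent-void times (min on the simulation clock)."""

    t_sampling: float
    t_mrv: float

    def __post_init__(self) -> None:
        if self.t_sampling - self.t_mrv <= MIN_VOID_GAP_MIN:
            raise ValueError(
                f"most recent void must be > {MIN_VOID_GAP_MIN:.0f} min before "
                f"sampling (gap = {self.t_sampling - self.t_mrv:.1f} min)"
            )
        if self.t_mrv < 0:
            raise ValueError("t_mrv must be non-negative")


@dataclass(frozen=True)
class BiomarkerPanel:
    """The six observables plus the four windowed dose metrics for one
    Monte Carlo iteration."""

    spot_urinary_1n_nM: float
    spot_plasma_carbaryl_pM: float
    spot_inhibition_brain_pct: float
    spot_inhibition_rbc_pct: float
    avg24_inhibition_brain_pct: float
    avg24_inhibition_rbc_pct: float
    avg24_brain_carbaryl_pM: float
    dose_avg_year: float     # ng/kg/day
    dose_avg_week: float
    dose_avg_2day: float
    dose_avg_24h: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def sample_spot_times(seed: int, sim_end: float) -> SpotSampleTimes:
    """Draw (t_sampling, t_mrv) uniformly from the final 24 h of the
    simulation, rejecting void times less than 1 h before the sample."""
    if sim_end < MINUTES_PER_DAY:
        raise ValueError("simulation must cover at least 24 h")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    lo = sim_end - MINUTES_PER_DAY
    while True:
        # the pair is drawn jointly: a sample falling in the first hour of
        # the window admits no valid earlier void, so both are redrawn
        t_sampling = rng.uniform(lo, sim_end)
        t_mrv = rng.uniform(lo, sim_end)
        if t_sampling - t_mrv > MIN_VOID_GAP_MIN:
            return SpotSampleTimes(t_sampling=float(t_sampling), t_mrv=float(t_mrv))


def spot_urinary_1n(
    tc: TimeCourse, times: SpotSampleTimes, urine_output: float
) -> float:
    """Spot urinary 1-naphthol concentration (nM) from the bladder-accumulation
    equation; ``urine_output`` in L/min."""
    if urine_output <= 0:
        raise ValueError(f"urine_output must be positive, got {urine_output}")
    if times.t_mrv < tc.t_min[0] or times.t_sampling > tc.t_min[-1]:
        raise ValueError("sampling window not covered by the time course")
    cum = tc.cumulative_urinary_1n_nmol
    moles_sampling = float(np.interp(times.t_sampling, tc.t_min, cum))
    moles_mrv = float(np.interp(times.t_mrv, tc.t_min, cum))
    return (moles_sampling - moles_mrv) / (
        (times.t_sampling - times.t_mrv) * urine_output
    )


def window_average(
    t: np.ndarray, values: np.ndarray, t_end: float, width: float
) -> float:
    """Trapezoidal mean of a time series over the closed window
    [t_end - width, t_end]; endpoints are linearly interpolated."""
    if width <= 0:
        raise ValueError("width must be positive")
    t_start = t_end - width
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t_start:.1f}, {t_end:.1f}] not covered by series "
            f"[{t[0]:.1f}, {t[-1]:.1f}]"
        )
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inner], [t_end]))
    vv = np.concatenate(
        ([np.interp(t_start, t, values)], values[inner], [np.interp(t_end, t, values)])
    )
    return float(np.trapezoid(vv, tt) / width)


def dose_window_averages(
    profile: ExposureProfile,
    subject: Subject,
    end_day: int,
    t_sampling: float,
) -> dict[str, float]:
    """The four windowed dose metrics (ng/kg/day) for a spot sample taken at
    simulation minute ``t_sampling`` of the week ending on ``end_day``.

    The year metric uses the full 365-day profile.  Week, 2-day and 24-h
    windows are right-closed at the sampling instant on the absolute year
    clock (day 1 starts at minute 0).
    """
    bw = subject.body_weight
    abs_sampling = (end_day - 7) * MINUTES_PER_DAY + t_sampling
    abs_event = (
        (profile.events["day"].to_numpy() - 1) * MINUTES_PER_DAY
        + profile.events["time_min"].to_numpy()
    )
    dose = profile.events["dose_ng"].to_numpy()

    def window_sum(width_min: float) -> float:
        mask = (abs_event > abs_sampling - width_min) & (abs_event <= abs_sampling)
        return float(dose[mask].sum())

    return {
        "dose_avg_year": float(dose.sum()) / bw / 365.0,
        "dose_avg_week": window_sum(7 * MINUTES_PER_DAY) / bw / 7.0,
        "dose_avg_2day": window_sum(2 * MINUTES_PER_DAY) / bw / 2.0,
        "dose_avg_24h": window_sum(MINUTES_PER_DAY) / bw / 1.0,
    }


def assemble_panel(
    tc: TimeCourse,
    profile: ExposureProfile,
    subject: Subject,
    times: SpotSampleTimes,
    end_day: int = 365,
) -> BiomarkerPanel:
    """Fill every panel field from one simulated week.

    Spot values are read by linear interpolation at ``t_sampling``; 24-h
    averages are trapezoidal means over the 24 h ending at ``t_sampling``.
    Inhibition is clipped at 0 from below: the model's small post-exposure
    rebound of active enzyme above baseline reads as 0 % inhibition.
    """
    t = tc.t_min

    def at_sampling(series: np.ndarray) -> float:
        return float(np.interp(times.t_sampling, t, series))

    def avg24(series: np.ndarray) -> float:
        return window_average(t, series, times.t_sampling, float(MINUTES_PER_DAY))

    doses = dose_window_averages(profile, subject, end_day, times.t_sampling)
    clip = lambda v: max(v, 0.0)
    return BiomarkerPanel(
        spot_urinary_1n_nM=spot_urinary_1n(tc, times, subject.urine_output),
        spot_plasma_carbaryl_pM=at_sampling(tc.plasma_conc_pM),
        spot_inhibition_brain_pct=clip(at_sampling(tc.inhibition_brain_pct)),
        spot_inhibition_rbc_pct=clip(at_sampling(tc.inhibition_rbc_pct)),
        avg24_inhibition_brain_pct=clip(avg24(tc.inhibition_brain_pct)),
        avg24_inhibition_rbc_pct=clip(avg24(tc.inhibition_rbc_pct)),
        avg24_brain_carbaryl_pM=avg24(tc.brain_conc_pM),
        **doses,
    )
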