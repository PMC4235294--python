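"""Synthetic virtual population and dietary carbaryl exposure profiles.

Emulates the statistical structure of a simulated U.S. adult dietary
exposure population: 500 adults aged 20–90 whose year-average daily carbaryl
intake is lognormal (GM 70.2 ng/kg/day, GSD 1.84), with 1–23 discrete oral
exposure events per day (median 4) over a 365-day year, plus per-subject
urine output (bladder-filling rate) drawn to emulate survey-reported urine
flow rates.  Everything is generated programmatically and reproducibly from
a seed; no external data are read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DoseEvent

MINUTES_PER_DAY = 1440
DAYS_PER_YEAR = 365

#: shifted negative-binomial parameters for daily event counts, chosen so the
#: count distribution has support [1, 23] (truncated) and median 4
COUNT_NB_N = 2.0
COUNT_NB_P = 0.38
MAX_EVENTS_PER_DAY = 23

#: within-day event-time mixture: three mealtime peaks (min of day) over
#: waking hours, with dispersion wide enough to cover snacking
MEAL_MEANS = (480.0, 750.0, 1110.0)     # 08:00, 12:30, 18:30
MEAL_SDS = (60.0, 75.0, 90.0)
MEAL_WEIGHTS = (0.30, 0.35, 0.35)
WAKING_WINDOW = (300.0, 1410.0)         # 05:00 .. 23:30


@dataclass(frozen=True)
class Subject:
    """One virtual person."""

    id: int
    age: float                   # years
    sex: str                     # "M" / "F"
    body_weight: float           # kg
    urine_output: float          # L/min
    target_year_avg_dose: float  # ng/kg/day

    def __post_init__(self) -> None:
        if not 20.0 <= self.age <= 90.0:
            raise ValueError(f"age must lie in [20, 90], got {self.age}")
        for name in ("body_weight", "urine_output", "target_year_avg_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ExposureProfile:
    """365 days of discrete oral exposure events for one subject.

    ``events`` columns: day (1-based), time_min (minute of day), dose_ng.
    Every day carries at least one and at most 23 events; after global
    rescaling the realized year-average dose per kg equals the subject's
    target exactly (to floating-point rescaling precision).
    """

    subject_id: int
    events: pd.DataFrame

    def daily_counts(self) -> pd.Series:
        return self.events.groupby("day").size()

    def year_average_dose_per_kg(self, body_weight: float) -> float:
        """Realized year-average daily dose, ng/kg/day."""
        return float(self.events["dose_ng"].sum()) / body_weight / DAYS_PER_YEAR

    def validate(self) -> None:
        counts = self.daily_counts()
        if len(counts) != DAYS_PER_YEAR:
            raise ValueError("profile must cover every day of the year")
        if counts.min() < 1 or counts.max() > MAX_EVENTS_PER_DAY:
            raise ValueError("daily event count outside [1, 23]")
        if (self.events["dose_ng"] <= 0).any():
            raise ValueError("all doses must be positive")


def draw_subjects(
    n: int,
    seed: int,
    *,
    dose_gm: float = 70.2,
    dose_gsd: float = 1.84,
    bw_gm_male: float = 83.0,
    bw_gm_female: float = 68.0,
    bw_gsd: float = 1.25,
    urine_gm: float = 0.001,
    urine_gsd: float = 1.9,
) -> list[Subject]:
    """Draw ``n`` virtual adults.

    Ages uniform on [20, 90]; body weights lognormal with a sex-specific
    geometric mean; urine outputs lognormal (GM 1.0 mL/min); target
    year-average doses lognormal with the configured GM/GSD (defaults match
    the emulated dietary-exposure population).
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    ages = rng.uniform(20.0, 90.0, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    bw_gm = np.where(sexes == "M", bw_gm_male, bw_gm_female)
    bws = np.exp(rng.normal(np.log(bw_gm), np.log(bw_gsd)))
    urine = np.exp(rng.normal(np.log(urine_gm), np.log(urine_gsd), size=n))
    doses = np.exp(rng.normal(np.log(dose_gm), np.log(dose_gsd), size=n))
    return [
        Subject(
            id=i,
            age=float(ages[i]),
            sex=str(sexes[i]),
            body_weight=float(bws[i]),
            urine_output=float(urine[i]),
            target_year_avg_dose=float(doses[i]),
        )
        for i in range(n)
    ]


def _draw_event_times(rng: np.random.Generator, n: int) -> np.ndarray:
    """Clock times (min of day) from the truncated mealtime mixture."""
    comp = rng.choice(len(MEAL_MEANS), size=n, p=MEAL_WEIGHTS)
    lo, hi = WAKING_WINDOW
    means = np.asarray(MEAL_MEANS)[comp]
    sds = np.asarray(MEAL_SDS)[comp]
    a, b = (lo - means) / sds, (hi - means) / sds
    return stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=means, scale=sds)


def draw_exposure_profile(
    subject: Subject,
    seed: int,
    *,
    day_gsd: float = 2.0,
    event_gsd: float = 2.2,
    uniform_times: bool = False,
) -> ExposureProfile:
    """Generate one subject's 365-day exposure profile.

    Daily event counts are a shifted negative binomial truncated to [1, 23]
    (median 4); event clock times follow a mealtime-weighted mixture (or a
    uniform waking-hours draw with ``uniform_times``); raw event doses are
    lognormal with an additional per-day lognormal multiplier (``day_gsd``)
    so that 24-h, 2-day, week and year dose averages genuinely differ; all
    doses are then rescaled by one global factor so the realized
    year-average dose per kg equals the subject's target exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject.id), 2]))
    counts = 1 + np.minimum(
        rng.negative_binomial(COUNT_NB_N, COUNT_NB_P, size=DAYS_PER_YEAR),
        MAX_EVENTS_PER_DAY - 1,
    )
    n_total = int(counts.sum())
    days = np.repeat(np.arange(1, DAYS_PER_YEAR + 1), counts)
    if uniform_times:
        times = rng.uniform(*WAKING_WINDOW, size=n_total)
    else:
        times = _draw_event_times(rng, n_total)
    day_mult = np.exp(rng.normal(0.0, np.log(day_gsd), size=DAYS_PER_YEAR))
    raw = np.exp(rng.normal(0.0, np.log(event_gsd), size=n_total)) * day_mult[days - 1]
    target_total_ng = subject.target_year_avg_dose * subject.body_weight * DAYS_PER_YEAR
    doses = raw * (target_total_ng / raw.sum())
    events = pd.DataFrame({"day": days, "time_min": times, "dose_ng": doses})
    events = events.sort_values(["day", "time_min"], kind="mergesort").reset_index(drop=True)
    return ExposureProfile(subject_id=subject.id, events=events)


def extract_week(profile: ExposureProfile, end_day: int) -> list[DoseEvent]:
    """The final 7 days' events (days end_day-6 .. end_day) on a continuous
    minute clock starting at 0, ready for :func:`carbarylsim.simulate`."""
    if end_day < 7:
        raise ValueError(f"end_day must be >= 7, got {end_day}")
    if end_day > DAYS_PER_YEAR:
        raise ValueError(f"end_day must be <= {DAYS_PER_YEAR}, got {end_day}")
    start_day = end_day - 6
    window = profile.events[profile.events["day"].between(start_day, end_day)]
    t = (window["day"] - start_day) * MINUTES_PER_DAY + window["time_min"]
    order = np.argsort(t.to_numpy(), kind="mergesort")
    return [
        DoseEvent(float(ti), float(di))
        for ti, di in zip(t.to_numpy()[order], window["dose_ng"].to_numpy()[order])
    ]


# ---------------------------------------------------------------------------
# CSV interfaces

SUBJECT_COLUMNS = ["id", "age", "sex", "bw_kg", "urine_output_L_min", "target_dose_ng_kg_day"]


def subjects_to_csv(subjects: Sequence[Subject], path: str | Path) -> None:
    pd.DataFrame(
        [
            [s.id, s.age, s.sex, s.body_weight, s.urine_output, s.target_year_avg_dose]
            for s in subjects
        ],
        columns=SUBJECT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def subjects_from_csv(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        Subject(
            id=int(r.id),
            age=float(r.age),
            sex=str(r.sex),
            body_weight=float(r.bw_kg),
            urine_output=float(r.urine_output_L_min),
            target_year_avg_dose=float(r.target_dose_ng_kg_day),
        )
        for r in df.itertuples()
    ]


def exposures_to_csv(profiles: Sequence[ExposureProfile], path: str | Path) -> None:
    frames = []
    for prof in profiles:
        df = prof.events.copy()
        df.insert(0, "subject_id", prof.subject_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def exposures_from_csv(path: str | Path) -> dict[int, ExposureProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return {
        int(sid): ExposureProfile(
            subject_id=int(sid),
            events=g.drop(columns="subject_id").reset_index(drop=True),
        )
        for sid, g in df.groupby("subject_id")
    }
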