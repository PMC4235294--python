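"""Local sensitivity screening and the population Monte Carlo engine.

The screen perturbs every scalar model parameter by a small fraction and
computes forward-difference normalized sensitivity coefficients,

    NSC = ((Y(p*(1+delta)) - Y(p)) / Y(p)) / delta,

for five outputs — cumulative urinary 1-naphthol (umol), peak brain and RBC
AChE depression (%), peak carbaryl amount in brain (umol) and peak plasma
carbaryl concentration (uM) — under a standardized week of constant-rate
oral exposure, repeated at three dose levels spanning the population's
lowest and highest year-average daily doses and 1000x the highest.
A parameter is sensitive when |NSC| exceeds the threshold (default 0.1) for
any output at any dose level.

The Monte Carlo engine runs each subject's final exposure week ``reps``
times, re-sampling the sensitive parameters and the spot sampling times on
every repetition while holding body weight, urine output and the exposure
profile fixed per subject.  Seeding is hierarchical: (master seed, subject,
rep) determines an independent, reproducible stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DoseEvent, MW_CARBARYL, I_BRAIN, SimulationError, TimeCourse, simulate
from .params import (
    ConfigError,
    McDistribution,
    ModelParams,
    flatten_params,
    get_param,
    scale_physiology,
    set_params,
)
from .population import ExposureProfile, Subject, draw_exposure_profile, extract_week
from .sampling import BiomarkerPanel, SpotSampleTimes, assemble_panel, sample_spot_times

SCREEN_OUTPUTS = (
    "urinary_1N_umol",
    "brain_AChE_depression_pct",
    "RBC_AChE_depression_pct",
    "brain_carbaryl_umol",
    "plasma_carbaryl_uM",
)

SCREEN_DOSE_LEVELS = (29.7, 426.0, 426_000.0)  # ng/kg/day
NSC_THRESHOLD = 0.1


class NscUndefinedError(ZeroDivisionError):
    """Baseline output is zero, so a relative sensitivity is undefined."""


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    output: str
    dose_level: float        # ng/kg/day
    nsc: float
    sensitive: bool
    failed: bool = False


@dataclass(frozen=True)
class IterationRecord:
    """One Monte Carlo iteration: inputs sampled and panel produced."""

    subject_id: int
    rep: int
    sampled_params: dict[str, float]
    times: SpotSampleTimes | None
    panel: BiomarkerPanel | None
    error: str | None = None


# ---------------------------------------------------------------------------
# screening


def screening_outputs(tc: TimeCourse) -> dict[str, float]:
    return {
        "urinary_1N_umol": float(tc.cumulative_urinary_1n_nmol[-1]) / 1000.0,
        "brain_AChE_depression_pct": float(tc.inhibition_brain_pct.max()),
        "RBC_AChE_depression_pct": float(tc.inhibition_rbc_pct.max()),
        "brain_carbaryl_umol": float(tc.states[I_BRAIN].max()) / 1000.0,
        "plasma_carbaryl_uM": float(tc.plasma_conc_uM.max()),
    }


def run_screening_simulation(
    params: ModelParams,
    dose_ng_kg_day: float,
    duration_days: int = 7,
    grid_step_min: float = 5.0,
) -> TimeCourse:
    """A deterministic standardized exposure: constant-rate oral input at the
    stated dose, simulated for a week (zero-order GI infusion, no randomness)."""
    rate_nmol_h = (
        dose_ng_kg_day * params.physiology.body_weight / MW_CARBARYL / 24.0
    )
    return simulate(
        params,
        events=[],
        duration_min=duration_days * 1440.0,
        grid_step_min=grid_step_min,
        gi_infusion_nmol_per_h=rate_nmol_h,
        rtol=1e-8,
        atol=1e-12,
    )


def normalized_sensitivity(
    params: ModelParams,
    param_name: str,
    output_fn: Callable[[ModelParams], float],
    delta_frac: float = 0.01,
) -> float:
    """Forward-difference normalized sensitivity coefficient of one output
    with respect to one parameter."""
    if not 0.0 < delta_frac <= 0.1:
        raise ValueError("delta_frac must lie in (0, 0.1]")
    p0 = get_param(params, param_name)
    if p0 == 0.0:
        raise NscUndefinedError(f"parameter {param_name} is zero; NSC undefined")
    y0 = output_fn(params)
    if y0 == 0.0:
        raise NscUndefinedError(f"baseline output is zero for {param_name}; NSC undefined")
    y1 = output_fn(set_params(params, {param_name: p0 * (1.0 + delta_frac)}))
    return ((y1 - y0) / y0) / delta_frac


def sensitivity_screen(
    params: ModelParams,
    dose_levels: Sequence[float] = SCREEN_DOSE_LEVELS,
    threshold: float = NSC_THRESHOLD,
    delta_frac: float = 0.01,
    parameters: Sequence[str] | None = None,
    duration_days: int = 7,
    grid_step_min: float = 5.0,
) -> list[SensitivityRecord]:
    """Screen every (parameter, output, dose level) cell.

    One baseline and one perturbed simulation per (parameter, dose level);
    all five outputs are read from the same run.  Failed simulations are
    recorded (``failed=True``, NSC = nan) rather than dropped.
    """
    if any(d <= 0 for d in dose_levels):
        raise ValueError("dose levels must be positive")
    names = list(parameters) if parameters is not None else sorted(flatten_params(params))
    records: list[SensitivityRecord] = []
    for dose in dose_levels:
        base = screening_outputs(
            run_screening_simulation(params, dose, duration_days, grid_step_min)
        )
        for name in names:
            p0 = get_param(params, name)
            try:
                if p0 == 0.0:
                    raise NscUndefinedError(name)
                perturbed = set_params(params, {name: p0 * (1.0 + delta_frac)})
                pert = screening_outputs(
                    run_screening_simulation(perturbed, dose, duration_days, grid_step_min)
                )
            except (SimulationError, NscUndefinedError, ConfigError):
                for output in SCREEN_OUTPUTS:
                    records.append(
                        SensitivityRecord(name, output, dose, float("nan"), False, True)
                    )
                continue
            for output in SCREEN_OUTPUTS:
                if base[output] == 0.0:
                    records.append(
                        SensitivityRecord(name, output, dose, float("nan"), False, True)
                    )
                    continue
                nsc = ((pert[output] - base[output]) / base[output]) / delta_frac
                records.append(
                    SensitivityRecord(name, output, dose, nsc, abs(nsc) > threshold)
                )
    return records


def sensitive_parameters(records: Sequence[SensitivityRecord]) -> set[str]:
    """Parameters sensitive for any output at any dose level."""
    return {r.parameter for r in records if r.sensitive}


def sensitivity_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.parameter, r.output, r.dose_level, r.nsc, r.sensitive, r.failed)
            for r in records
        ],
        columns=["parameter", "output", "dose_level", "nsc", "sensitive", "failed"],
    )


# ---------------------------------------------------------------------------
# Monte Carlo


def _sample_one(
    dist: McDistribution, central: float, rng: np.random.Generator
) -> float:
    """One truncated draw: +/-3 sigma (normal, sigma = CV*central) or within
    GSD^3 of the geometric mean (lognormal)."""
    u = rng.uniform()
    if dist.shape == "lognormal":
        sigma = math.log(dist.spread)
        if sigma == 0.0:
            return central
        z = stats.truncnorm.ppf(u, -3.0, 3.0)
        return central * math.exp(sigma * z)
    sigma = dist.spread * central
    if sigma == 0.0:
        return central
    return central + sigma * stats.truncnorm.ppf(u, -3.0, 3.0)


def sample_parameters(
    params: ModelParams, rng: np.random.Generator, max_tries: int = 100
) -> tuple[ModelParams, dict[str, float]]:
    """Sample all sensitive Monte Carlo distributions and return the updated,
    re-validated parameter set plus the sampled values.

    A joint draw that violates a structural invariant (e.g. tissue volume
    fractions summing above 1) is rejected and redrawn.
    """
    dists = [d for d in params.monte_carlo if d.sensitive]
    if not dists:
        return params, {}
    for _ in range(max_tries):
        sampled = {
            d.parameter: _sample_one(
                d, d.central if d.central is not None else get_param(params, d.parameter), rng
            )
            for d in dists
        }
        try:
            return set_params(params, sampled), sampled
        except ConfigError:
            continue
    raise ConfigError(
        f"could not draw a physically valid parameter set in {max_tries} tries"
    )


def _child_seed(master_seed: int, *path: int) -> int:
    return int(
        np.random.SeedSequence([int(master_seed), *map(int, path)]).generate_state(1)[0]
        % (2**31)
    )


def monte_carlo(
    params: ModelParams,
    subjects: Sequence[Subject],
    reps: int = 10,
    seed: int = 0,
    profiles: dict[int, ExposureProfile] | None = None,
    end_day: int = 365,
    grid_step_min: float = 1.0,
    rtol: float = 1e-7,
) -> list[IterationRecord]:
    """Run the full population Monte Carlo: len(subjects) x reps iterations.

    Per subject, the exposure profile, body weight and urine output are fixed
    across repetitions; per repetition, sensitive model parameters and the
    spot sampling times are re-sampled.  Failed simulations are retained as
    records with ``error`` set and no panel.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    records: list[IterationRecord] = []
    for s_idx, subject in enumerate(subjects):
        if profiles is not None and subject.id in profiles:
            profile = profiles[subject.id]
        else:
            profile = draw_exposure_profile(subject, seed=seed)
        events = extract_week(profile, end_day)
        duration = 7 * 1440.0
        for rep in range(1, reps + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 4, s_idx, rep])
            )
            try:
                p_iter, sampled = sample_parameters(params, rng)
                phys = scale_physiology(p_iter.physiology, subject.body_weight)
                phys = phys.model_copy(update={"urine_output": subject.urine_output})
                p_iter = p_iter.model_copy(update={"physiology": phys})
                times = sample_spot_times(
                    seed=_child_seed(seed, 5, s_idx, rep), sim_end=duration
                )
                tc = simulate(
                    p_iter, events, duration, grid_step_min=grid_step_min, rtol=rtol
                )
                panel = assemble_panel(tc, profile, subject, times, end_day=end_day)
                records.append(
                    IterationRecord(subject.id, rep, sampled, times, panel)
                )
            except (SimulationError, ConfigError, ValueError) as exc:
                records.append(
                    IterationRecord(
                        subject.id, rep, {}, None, None, error=f"{type(exc).__name__}: {exc}"
                    )
                )
    return records


def panels_to_frame(records: Sequence[IterationRecord]) -> pd.DataFrame:
    """Flatten successful iteration records into the panels table."""
    rows = []
    for r in records:
        if r.error is not None:
            continue
        row = {"subject_id": r.subject_id, "rep": r.rep,
               "t_sampling": r.times.t_sampling, "t_mrv": r.times.t_mrv}
        row.update(r.panel.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
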