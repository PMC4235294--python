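"""Normalized sensitivity coefficients and the Monte Carlo engine."""

import numpy as np
import pytest

from carbarylsim import (
    default_params,
    draw_subjects,
    monte_carlo,
    normalized_sensitivity,
    panels_to_frame,
    sensitive_parameters,
    sensitivity_screen,
)
from carbarylsim.params import McDistribution, get_param
from carbarylsim.sensitivity import (
    NscUndefinedError,
    SCREEN_OUTPUTS,
    sample_parameters,
    sensitivity_to_frame,
)


class TestNsc:
    def test_linear_output_gives_unit_nsc(self, params):
        out = lambda p: 3.7 * get_param(p, "chemical.ka")
        assert normalized_sensitivity(params, "chemical.ka", out) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_independent_output_gives_zero(self, params):
        assert normalized_sensitivity(params, "chemical.ka", lambda p: 42.0) == 0.0

    def test_quadratic_output_forward_difference_value(self, params):
        # Y = p^2 at delta 1%: ((1.01^2 - 1)/1)/0.01 = 2.01 exactly
        out = lambda p: get_param(p, "chemical.ka") ** 2
        nsc = normalized_sensitivity(params, "chemical.ka", out, delta_frac=0.01)
        assert nsc == pytest.approx(2.01, rel=1e-9)

    def test_zero_baseline_output_is_reported_not_silenced(self, params):
        with pytest.raises(NscUndefinedError):
            normalized_sensitivity(params, "chemical.ka", lambda p: 0.0)

    def test_delta_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            normalized_sensitivity(params, "chemical.ka", lambda p: 1.0, delta_frac=0.5)


@pytest.fixture(scope="module")
def screen_records(params):
    return sensitivity_screen(params)


class TestScreen:
    def test_one_record_per_cell(self, params, screen_records):
        from carbarylsim.params import flatten_params

        n_params = len(flatten_params(params))
        assert len(screen_records) == n_params * len(SCREEN_OUTPUTS) * 3

    def test_dead_michaelis_menten_branch_has_zero_nsc(self, screen_records):
        mm = [r for r in screen_records if r.parameter.startswith("chemical.mm_")]
        assert mm and all(not r.failed and r.nsc == 0.0 for r in mm)

    def test_dose_scaling_linearity_via_body_weight(self, screen_records):
        # the screening input is dose-per-kg * BW, so body weight acts as a
        # dose magnitude multiplier for amount-type outputs in the linear regime
        recs = [
            r for r in screen_records
            if r.parameter == "physiology.body_weight" and r.output == "urinary_1N_umol"
        ]
        assert len(recs) == 3
        for r in recs:
            assert r.nsc == pytest.approx(1.0, abs=0.05)

    def test_sensitive_set_identical_across_dose_levels(self, screen_records):
        df = sensitivity_to_frame(screen_records)
        sets = {
            dose: frozenset(g[g.sensitive]["parameter"])
            for dose, g in df.groupby("dose_level")
        }
        assert len(sets) == 3
        assert len(set(sets.values())) == 1

    def test_no_failed_cells_with_defaults(self, screen_records):
        assert not any(r.failed for r in screen_records)

    def test_shipped_monte_carlo_list_matches_screen(self, params, screen_records):
        screened = sensitive_parameters(screen_records) - {"physiology.body_weight"}
        configured = {d.parameter for d in params.monte_carlo}
        assert configured == screened


def test_nsc_stable_under_delta_halving(params):
    """Numerical-derivative stability on a smooth model output."""
    from carbarylsim.sensitivity import run_screening_simulation, screening_outputs

    def out(p):
        return screening_outputs(run_screening_simulation(p, 426.0, duration_days=2))[
            "plasma_carbaryl_uM"
        ]

    a = normalized_sensitivity(params, "chemical.hydrolysis_rate.liver", out, 0.02)
    b = normalized_sensitivity(params, "chemical.hydrolysis_rate.liver", out, 0.01)
    assert b == pytest.approx(a, rel=0.05)


class TestSampleParameters:
    def test_all_lognormal_draws_positive(self, params, rng):
        for _ in range(25):
            sampled_params, sampled = sample_parameters(params, rng)
            for dist in params.monte_carlo:
                if dist.shape == "lognormal":
                    assert sampled[dist.parameter] > 0.0

    def test_truncation_bounds_respected(self, params, rng):
        for _ in range(25):
            _, sampled = sample_parameters(params, rng)
            for dist in params.monte_carlo:
                central = get_param(params, dist.parameter)
                v = sampled[dist.parameter]
                if dist.shape == "lognormal":
                    bound = dist.spread**3
                    assert central / bound <= v <= central * bound
                else:
                    bound = 3 * dist.spread * central
                    assert central - bound <= v <= central + bound

    def test_zero_spread_returns_central(self, params, rng):
        frozen = params.model_copy(
            update={
                "monte_carlo": tuple(
                    McDistribution(
                        parameter=d.parameter,
                        shape="lognormal",
                        spread=1.0,
                        sensitive=True,
                    )
                    for d in params.monte_carlo
                )
            }
        )
        _, sampled = sample_parameters(frozen, rng)
        for name, v in sampled.items():
            assert v == get_param(params, name)


class TestMonteCarlo:
    def test_desk_profile_bookkeeping(self, desk_records):
        assert len(desk_records) == 50 * 2
        assert not any(r.error for r in desk_records)
        keys = {(r.subject_id, r.rep) for r in desk_records}
        assert len(keys) == 100

    def test_reps_share_subject_level_inputs(self, desk_records):
        by_subject = {}
        for r in desk_records:
            by_subject.setdefault(r.subject_id, []).append(r)
        for recs in by_subject.values():
            year_doses = {round(r.panel.dose_avg_year, 12) for r in recs}
            assert len(year_doses) == 1  # same profile across reps

    def test_reps_resample_parameters_and_times(self, desk_records):
        r1, r2 = desk_records[0], desk_records[1]
        assert r1.subject_id == r2.subject_id
        assert r1.sampled_params != r2.sampled_params
        assert r1.times != r2.times

    def test_degenerate_variability_samples_nothing(self, params):
        frozen = params.model_copy(
            update={
                "monte_carlo": tuple(
                    d.model_copy(update={"sensitive": False}) for d in params.monte_carlo
                )
            }
        )
        subjects = draw_subjects(2, seed=8)
        records = monte_carlo(frozen, subjects, reps=2, seed=8, grid_step_min=5.0)
        by_subject = {}
        for r in records:
            # fix the sampling times to isolate parameter variability
            by_subject.setdefault(r.subject_id, []).append(r)
        for recs in by_subject.values():
            assert recs[0].sampled_params == {} == recs[1].sampled_params

    def test_hierarchical_seeding_reproducible(self, params):
        subjects = draw_subjects(2, seed=9)
        a = monte_carlo(params, subjects, reps=1, seed=9, grid_step_min=5.0)
        b = monte_carlo(params, subjects, reps=1, seed=9, grid_step_min=5.0)
        assert panels_to_frame(a).equals(panels_to_frame(b))

    def test_panels_frame_has_full_schema(self, desk_panels):
        expected = {
            "subject_id", "rep", "t_sampling", "t_mrv",
            "spot_urinary_1n_nM", "spot_plasma_carbaryl_pM",
            "spot_inhibition_brain_pct", "spot_inhibition_rbc_pct",
            "avg24_inhibition_brain_pct", "avg24_inhibition_rbc_pct",
            "avg24_brain_carbaryl_pM",
            "dose_avg_year", "dose_avg_week", "dose_avg_2day", "dose_avg_24h",
        }
        assert expected == set(desk_panels.columns)
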