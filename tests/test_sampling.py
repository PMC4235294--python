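"""Spot biomarker extraction and windowed dose metrics."""

import numpy as np
import pytest

from carbarylsim import (
    DoseEvent,
    SpotSampleTimes,
    assemble_panel,
    dose_window_averages,
    draw_exposure_profile,
    extract_week,
    sample_spot_times,
    simulate,
    spot_urinary_1n,
    window_average,
)
from carbarylsim.model import I_URINE, TimeCourse
from carbarylsim.population import ExposureProfile, Subject

import pandas as pd

WEEK_MIN = 7 * 1440.0


def _synthetic_timecourse(params, t, urine_series):
    """A TimeCourse with a prescribed cumulative-urinary trajectory."""
    states = np.zeros((14, len(t)))
    states[I_URINE] = urine_series
    return TimeCourse(t_min=np.asarray(t, float), states=states, params=params)


class TestSpotTimes:
    def test_ten_thousand_draws_respect_constraints(self):
        sim_end = WEEK_MIN
        ts = np.empty(10_000)
        tm = np.empty(10_000)
        for i in range(10_000):
            pair = sample_spot_times(seed=i, sim_end=sim_end)
            ts[i], tm[i] = pair.t_sampling, pair.t_mrv
        assert ts.min() >= sim_end - 1440.0 and ts.max() <= sim_end
        assert tm.min() >= sim_end - 1440.0
        assert (ts - tm).min() > 60.0

    def test_reproducible_under_seed(self):
        assert sample_spot_times(7, WEEK_MIN) == sample_spot_times(7, WEEK_MIN)

    def test_invalid_gap_rejected(self):
        with pytest.raises(ValueError, match="void"):
            SpotSampleTimes(t_sampling=1000.0, t_mrv=950.0)


class TestSpotUrine:
    def test_printed_equation_hand_example(self, params):
        """6 nmol excreted over 120 min at 1 mL/min -> 50 nM."""
        t = np.arange(0.0, 10081.0)
        cum = np.interp(t, [0.0, 9960.0, 10080.0], [4.0, 4.0, 10.0])
        tc = _synthetic_timecourse(params, t, cum)
        times = SpotSampleTimes(t_sampling=10080.0, t_mrv=9960.0)
        assert spot_urinary_1n(tc, times, urine_output=0.001) == pytest.approx(50.0)

    def test_no_excretion_gives_zero(self, params):
        t = np.arange(0.0, 2881.0)
        tc = _synthetic_timecourse(params, t, np.full_like(t, 7.0))
        times = SpotSampleTimes(t_sampling=2800.0, t_mrv=2000.0)
        assert spot_urinary_1n(tc, times, urine_output=0.002) == 0.0

    def test_doubling_urine_output_halves_concentration(self, params):
        t = np.arange(0.0, 2881.0)
        tc = _synthetic_timecourse(params, t, t * 0.01)
        times = SpotSampleTimes(t_sampling=2500.0, t_mrv=2100.0)
        c1 = spot_urinary_1n(tc, times, urine_output=0.001)
        c2 = spot_urinary_1n(tc, times, urine_output=0.002)
        assert c1 == pytest.approx(2.0 * c2)
        assert c1 > 0

    def test_constant_excretion_rate_recovers_rate_over_output(self, params):
        # for cumulative excretion r*t the spot concentration is r/q exactly,
        # independent of the void window
        r, q = 0.004, 0.0015
        t = np.arange(0.0, 10081.0)
        tc = _synthetic_timecourse(params, t, r * t)
        for t_mrv, t_s in [(9000.0, 9500.0), (8700.0, 10080.0), (9999.0, 10080.0)]:
            times = SpotSampleTimes(t_sampling=t_s, t_mrv=t_mrv)
            assert spot_urinary_1n(tc, times, q) == pytest.approx(r / q, rel=1e-12)

    def test_bad_inputs_rejected(self, params):
        t = np.arange(0.0, 1441.0)
        tc = _synthetic_timecourse(params, t, t * 0.01)
        times = SpotSampleTimes(t_sampling=1200.0, t_mrv=900.0)
        with pytest.raises(ValueError):
            spot_urinary_1n(tc, times, urine_output=0.0)
        with pytest.raises(ValueError):
            spot_urinary_1n(tc, SpotSampleTimes(2000.0, 1000.0), urine_output=0.001)


class TestWindowAverage:
    def test_constant_series(self):
        t = np.arange(0.0, 100.0)
        assert window_average(t, np.full_like(t, 3.3), 90.0, 50.0) == pytest.approx(3.3)

    def test_linear_ramp_over_exact_window(self):
        t = np.arange(0.0, 101.0)
        vals = 0.07 * t  # ramp 0 -> 7 over [0, 100]
        assert window_average(t, vals, 100.0, 100.0) == pytest.approx(3.5)

    def test_degenerate_single_step_window(self):
        t = np.arange(0.0, 10.0)
        vals = t**2
        assert window_average(t, vals, 5.0, 1.0) == pytest.approx((16 + 25) / 2)

    def test_insufficient_coverage_raises(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError, match="not covered"):
            window_average(t, t, 9.0, 20.0)


class TestDoseWindows:
    @staticmethod
    def _subject(bw=70.0):
        return Subject(id=0, age=40.0, sex="F", body_weight=bw,
                       urine_output=0.001, target_year_avg_dose=70.0)

    @staticmethod
    def _profile(events):
        df = pd.DataFrame(events, columns=["day", "time_min", "dose_ng"])
        return ExposureProfile(subject_id=0, events=df)

    def test_hand_fixture_single_event(self):
        """7000 ng, 12 h before sampling, 70 kg: 24-h avg 100, 2-day avg 50."""
        subject = self._subject(bw=70.0)
        # sampling at noon of day 365; event at midnight of day 365
        profile = self._profile([(365, 0.0, 7000.0)])
        out = dose_window_averages(profile, subject, end_day=365,
                                   t_sampling=6 * 1440.0 + 720.0)
        assert out["dose_avg_24h"] == pytest.approx(100.0)
        assert out["dose_avg_2day"] == pytest.approx(50.0)
        assert out["dose_avg_week"] == pytest.approx(100.0 / 7.0)
        assert out["dose_avg_year"] == pytest.approx(100.0 / 365.0)

    def test_identical_daily_dosing_equalizes_windows(self):
        subject = self._subject()
        events = [(d, 600.0, 3500.0) for d in range(1, 366)]
        profile = self._profile(events)
        out = dose_window_averages(profile, subject, end_day=365,
                                   t_sampling=6 * 1440.0 + 720.0)
        vals = list(out.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_old_exposure_excluded_from_short_windows(self):
        subject = self._subject()
        events = [(d, 600.0, 4000.0) for d in range(1, 360)]  # nothing in final 6 days
        profile = self._profile(events)
        out = dose_window_averages(profile, subject, end_day=365,
                                   t_sampling=6 * 1440.0 + 700.0)
        assert out["dose_avg_24h"] == 0.0
        assert out["dose_avg_2day"] == 0.0
        assert out["dose_avg_year"] > 0.0

    def test_windows_never_look_into_the_future(self):
        subject = self._subject()
        # one event one minute after sampling
        profile = self._profile([(365, 721.0, 9999.0), (1, 600.0, 100.0)])
        t_s = 6 * 1440.0 + 720.0
        out = dose_window_averages(profile, subject, end_day=365, t_sampling=t_s)
        assert out["dose_avg_24h"] == 0.0
        # shifting sampling +1 min picks the event up (right-closed window)
        out2 = dose_window_averages(profile, subject, end_day=365, t_sampling=t_s + 1.0)
        assert out2["dose_avg_24h"] > 0.0


class TestAssemblePanel:
    def test_zero_exposure_profile_gives_null_panel(self, params):
        subject = TestDoseWindows._subject()
        # minimal valid profile days with tiny far-past doses only
        profile = TestDoseWindows._profile([(d, 600.0, 1e-6) for d in range(1, 366)])
        tc = simulate(params, [], WEEK_MIN, grid_step_min=5.0)
        times = SpotSampleTimes(t_sampling=WEEK_MIN - 100.0, t_mrv=WEEK_MIN - 400.0)
        panel = assemble_panel(tc, profile, subject, times)
        assert panel.spot_urinary_1n_nM == 0.0
        assert panel.spot_plasma_carbaryl_pM == 0.0
        assert panel.spot_inhibition_brain_pct == 0.0
        assert panel.avg24_inhibition_rbc_pct == 0.0

    def test_panel_invariants_on_random_subjects(self, params, population_500):
        for subject in population_500[:8]:
            profile = draw_exposure_profile(subject, seed=42)
            events = extract_week(profile, 365)
            tc = simulate(params, events, WEEK_MIN, grid_step_min=2.0, rtol=1e-7)
            times = sample_spot_times(seed=subject.id, sim_end=WEEK_MIN)
            panel = assemble_panel(tc, profile, subject, times)
            d = panel.as_dict()
            assert all(v >= 0.0 for v in d.values()), d
            for key in d:
                if "inhibition" in key:
                    assert d[key] <= 100.0
            # default exposures sit far from the cholinergic-crisis regime
            assert panel.spot_inhibition_brain_pct < 10.0

    def test_grid_refinement_stability_of_spot_urine(self, params):
        subject = TestDoseWindows._subject()
        events = [DoseEvent(1000.0, 5e5), DoseEvent(4000.0, 5e5), DoseEvent(8000.0, 5e5)]
        times = SpotSampleTimes(t_sampling=WEEK_MIN - 200.0, t_mrv=WEEK_MIN - 1000.0)
        vals = []
        for step in (2.0, 1.0):
            tc = simulate(params, events, WEEK_MIN, grid_step_min=step)
            vals.append(spot_urinary_1n(tc, times, subject.urine_output))
        assert vals[1] == pytest.approx(vals[0], rel=1e-3)
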