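"""Schedules, shift simulation, TWA accounting, exceedance, sanity bounds."""

import numpy as np
import pytest

import roastair as ra
from roastair.errors import ScheduleError
from roastair.scenario import (
    FAR_FIELD,
    NEAR_FIELD,
    OFF_EXPOSURE,
    SegmentResult,
    TaskSegment,
)


class TestBuildSchedule:
    def test_scenario_a_preset_shape(self):
        sched = ra.build_schedule("scenario_A")
        labels = [s.label for s in sched.segments]
        assert labels.count("grinding") == 4
        assert labels.count("packaging") == 12
        assert sum(s.duration_min for s in sched.segments) == pytest.approx(480.0)
        grind = next(s for s in sched.segments if s.label == "grinding")
        assert grind.duration_min == 15.0 and grind.generation == pytest.approx(0.6)

    def test_scenario_b_preset_shape(self):
        sched = ra.build_schedule("scenario_B")
        grind = next(s for s in sched.segments if s.label == "grinding")
        pack = next(s for s in sched.segments if s.label == "packaging")
        assert grind.duration_min == 1.0
        assert grind.generation == pytest.approx(10.9)
        assert pack.generation == pytest.approx(0.64)
        assert pack.coffee_mass_kg == pytest.approx(181.8)
        assert sum(s.duration_min for s in sched.segments) == pytest.approx(480.0)

    def test_empty_spec_rejected(self):
        with pytest.raises(ScheduleError):
            ra.build_schedule({})

    def test_duration_mismatch_reports_residual(self):
        with pytest.raises(ScheduleError, match="residual"):
            ra.Schedule((TaskSegment("x", OFF_EXPOSURE, 100.0),))

    def test_near_field_without_source_rejected(self):
        with pytest.raises(ScheduleError):
            TaskSegment("pack", NEAR_FIELD, 15.0)

    def test_single_off_segment_gives_zero_profile(self):
        sched = ra.Schedule((TaskSegment("off", OFF_EXPOSURE, 480.0),))
        prof = ra.simulate_schedule(sched, ra.default_system("scenario_A"))
        assert np.all(prof.worker_ppb == 0.0)
        assert ra.full_shift_twa(prof) == 0.0


class TestSimulate:
    def test_emitted_masses_per_task(self, scenario_a_profile, scenario_b_profile):
        em_a = scenario_a_profile.emitted_mass_by_task
        assert em_a["packaging"] == pytest.approx([0.035 * 15] * 12)
        assert em_a["grinding"] == pytest.approx([9.0] * 4)
        em_b = scenario_b_profile.emitted_mass_by_task
        assert em_b["packaging"] == pytest.approx([9.6] * 12)
        assert em_b["grinding"] == pytest.approx([10.9] * 4)

    def test_emitted_mass_additivity(self, scenario_a_profile):
        total = sum(sum(v) for v in scenario_a_profile.emitted_mass_by_task.values())
        direct = sum(
            r.generation_mg_min * r.duration_min
            for r in scenario_a_profile.segment_results
            if r.location == NEAR_FIELD
        )
        assert total == pytest.approx(direct, rel=1e-12)

    def test_running_twa_ends_at_full_shift_twa(self, scenario_a_profile):
        assert scenario_a_profile.running_twa_ppb[-1] == pytest.approx(
            ra.full_shift_twa(scenario_a_profile), rel=1e-12
        )

    def test_single_task_dilution_identity(self):
        # One 15-min near-field task then 465 min off exposure: the
        # full-shift TWA is the task TWA scaled by 15/480.
        sched = ra.Schedule((
            TaskSegment("grind", NEAR_FIELD, 15.0, generation_mg_min=0.6),
            TaskSegment("off", OFF_EXPOSURE, 465.0),
        ))
        prof = ra.simulate_schedule(sched, ra.default_system("scenario_A"))
        task_twa = prof.segment_results[0].twa_ppb
        assert ra.full_shift_twa(prof) == pytest.approx(task_twa * 15 / 480, rel=1e-9)

    def test_constant_concentration_shift(self):
        sched = ra.Schedule((
            TaskSegment("fixed", FAR_FIELD, 480.0, fixed_concentration_ppb=5.0),
        ))
        prof = ra.simulate_schedule(sched, ra.default_system("scenario_A"))
        assert ra.full_shift_twa(prof) == pytest.approx(5.0, rel=1e-12)

    def test_far_field_continuity_across_segments(self, scenario_a_profile):
        # The far-field trace never jumps between segments.
        ff = scenario_a_profile.far_field_ppb
        assert np.abs(np.diff(ff)).max() < 0.5  # ppb per grid step, smooth

    def test_added_off_time_dilutes(self):
        nf = TaskSegment("grind", NEAR_FIELD, 15.0, generation_mg_min=0.6)
        short = ra.Schedule((nf, TaskSegment("off", OFF_EXPOSURE, 465.0)))
        long = ra.Schedule(
            (nf, TaskSegment("off", OFF_EXPOSURE, 945.0)), shift_length_min=960.0
        )
        sys = ra.default_system("scenario_A")
        assert ra.full_shift_twa(ra.simulate_schedule(long, sys)) < ra.full_shift_twa(
            ra.simulate_schedule(short, sys)
        )

    def test_linearity_in_generation(self):
        sched = ra.build_schedule("scenario_A")
        sys = ra.default_system("scenario_A")
        base = ra.simulate_schedule(sched, sys)
        doubled = ra.simulate_schedule(
            sched.scaled_generation({"packaging": 0.07, "grinding": 1.2}), sys
        )
        assert ra.full_shift_twa(doubled) == pytest.approx(
            2 * ra.full_shift_twa(base), rel=1e-9
        )
        np.testing.assert_allclose(
            doubled.worker_ppb, 2 * base.worker_ppb, rtol=1e-9, atol=1e-12
        )


class TestExceedance:
    def test_zero_profile_has_no_exceedances(self):
        sched = ra.Schedule((TaskSegment("off", OFF_EXPOSURE, 480.0),))
        prof = ra.simulate_schedule(sched, ra.default_system("scenario_A"))
        rep = ra.exceedance(prof)
        assert not rep.exceeds_rel
        assert rep.max_rolling_15min_twa_ppb == 0.0
        assert rep.max_task_stel_ratio == 0.0

    def test_constant_at_stel_gives_unit_ratio(self):
        sched = ra.Schedule((
            TaskSegment("fixed", FAR_FIELD, 480.0, fixed_concentration_ppb=25.0),
        ))
        prof = ra.simulate_schedule(sched, ra.default_system("scenario_A"))
        rep = ra.exceedance(prof, stel_ppb=25.0)
        assert rep.max_task_stel_ratio == pytest.approx(1.0, rel=1e-12)
        assert rep.max_rolling_15min_twa_ppb == pytest.approx(25.0, rel=1e-9)

    def test_short_excursion_ratio(self):
        # A 1-min task at 123.5 ppb against the 25-ppb short-term limit.
        assert 123.5 / 25.0 == pytest.approx(4.9, abs=0.05)
        segs = [(123.5, 1.0), (0.2, 14.0)]
        assert ra.twa(segs) == pytest.approx(8.4, abs=0.05)

    def test_rolling_twa_flags_scenario_a_grinding(self, scenario_a_profile):
        rep = ra.exceedance(scenario_a_profile)
        # Grinding dominates short-term exposure; the rolling 15-min max
        # must be at least the best grinding-task TWA.
        grind_twa = max(scenario_a_profile.per_task_twa["grinding"])
        assert rep.max_rolling_15min_twa_ppb >= grind_twa - 1e-6


class TestContentFraction:
    def test_reference_values(self):
        assert ra.content_fraction(9.0, 10.0, 19.0) == pytest.approx(4.7, abs=0.05)
        assert ra.content_fraction(9.6, 181.8, 19.0) == pytest.approx(0.28, abs=0.005)
        assert ra.content_fraction(0.0, 10.0, 19.0) == 0.0

    def test_presets_stay_below_5_percent(self, scenario_a_profile, scenario_b_profile):
        for prof in (scenario_a_profile, scenario_b_profile):
            for r in prof.segment_results:
                if r.location != NEAR_FIELD:
                    continue
                mass = 10.0 if prof is scenario_a_profile else 181.8
                assert ra.content_fraction(r.emitted_mass_mg, mass) <= 5.0
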