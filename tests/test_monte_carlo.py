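"""Input sampling, MC propagation, and the inter-zone-flow sensitivity sweep."""

import numpy as np
import pytest

import roastair as ra
from roastair.errors import ConfigError
from roastair.montecarlo import Fixed, Normal, Uniform, mc_steady_state


def make_system(**kw):
    defaults = dict(room_volume=7787.0, nf_volume=0.884, supply_air=73.2,
                    interzone_flow=10.6, generation=0.6)
    defaults.update(kw)
    return ra.TwoZoneSystem(**defaults)


class TestSampleInputs:
    def test_fixed_draws_are_identical(self):
        spec = ra.MCSpec(100, seed=1, distributions={"supply_air": 73.2})
        ds = ra.sample_inputs(spec)
        assert np.all(ds.draws["supply_air"] == 73.2)

    def test_uniform_bounds_and_mean(self):
        spec = ra.MCSpec(100_000, seed=1, distributions={
            "supply_air": {"kind": "uniform", "lo": 65.9, "hi": 80.5},
        })
        q = ra.sample_inputs(spec).draws["supply_air"]
        assert q.min() >= 65.9 and q.max() <= 80.5
        assert q.mean() == pytest.approx(73.2, rel=1e-3)

    def test_normal_upper_tail_fraction(self):
        # sd = 0.14 / 1.96: about 2.5% of draws exceed mean + 1.96 sd.
        sd = 0.14 / 1.96
        spec = ra.MCSpec(100_000, seed=2, distributions={
            "generation:grinding": {"kind": "normal", "mean": 0.6, "sd": sd},
        })
        g = ra.sample_inputs(spec).draws["generation:grinding"]
        assert (g > 0.74).mean() == pytest.approx(0.025, abs=0.003)

    def test_truncation_counted_for_mostly_negative_normal(self):
        spec = ra.MCSpec(10_000, seed=3, distributions={
            "generation:packaging": {"kind": "normal", "mean": 0.035, "sd": 0.24 / 1.96},
        })
        ds = ra.sample_inputs(spec)
        g = ds.draws["generation:packaging"]
        assert np.all(g > 0)
        # ~39% of raw normal mass lies at or below zero.
        frac = ds.truncation_counts["generation:packaging"] / (
            10_000 + ds.truncation_counts["generation:packaging"]
        )
        assert frac == pytest.approx(0.388, abs=0.03)

    def test_unknown_distribution_kind_rejected(self):
        with pytest.raises(ConfigError):
            ra.MCSpec(10, seed=1, distributions={"x": {"kind": "triangular", "a": 1}})
        with pytest.raises(ConfigError):
            Uniform(2.0, 1.0)
        with pytest.raises(ConfigError):
            Normal(1.0, -0.1)

    def test_seeded_determinism(self):
        spec = ra.MCSpec(1000, seed=9, distributions={
            "supply_air": {"kind": "uniform", "lo": 65.9, "hi": 80.5},
            "generation:grinding": {"kind": "normal", "mean": 0.6, "sd": 0.07},
        })
        a = ra.sample_inputs(spec).draws
        b = ra.sample_inputs(spec).draws
        assert a.equals(b)


class TestRunMC:
    def test_zero_variance_equals_deterministic(self):
        sched = ra.build_schedule("scenario_A")
        sys = ra.default_system("scenario_A")
        spec = ra.MCSpec(5, seed=1, distributions={
            "supply_air": Fixed(73.2),
            "generation:grinding": Fixed(0.6),
            "generation:packaging": Fixed(0.035),
        })
        summary = ra.run_mc(sched, sys, spec, dt_min=0.2)
        det = ra.simulate_schedule(sched, sys, dt_min=0.2)
        fs = ra.full_shift_twa(det)
        assert summary.full_shift_median_ppb == fs
        assert summary.full_shift_p95_ppb == fs
        assert summary.per_task["grinding"]["median"] == pytest.approx(
            float(np.mean(det.per_task_twa["grinding"])), rel=1e-12
        )

    def test_reproducible_and_percentiles_ordered(self):
        sched = ra.build_schedule("scenario_A")
        sys = ra.default_system("scenario_A")
        spec = ra.MCSpec(60, seed=42, distributions={
            "supply_air": {"kind": "uniform", "lo": 65.9, "hi": 80.5},
            "generation:grinding": {"kind": "normal", "mean": 0.6, "sd": 0.14 / 1.96},
            "generation:packaging": {"kind": "normal", "mean": 0.035, "sd": 0.24 / 1.96},
        })
        a = ra.run_mc(sched, sys, spec, dt_min=0.25)
        b = ra.run_mc(sched, sys, spec, dt_min=0.25)
        assert a.as_dict() == b.as_dict()
        assert a.full_shift_p95_ppb >= a.full_shift_median_ppb >= 0
        for stats in a.per_task.values():
            assert stats["p95"] >= stats["median"] >= 0
        assert a.n_failed == 0

    def test_median_brackets_deterministic_for_monotone_output(self):
        # Steady-state NF concentration is monotone in G, so the MC median
        # at G's median should straddle the deterministic value tightly.
        sys = make_system(interzone_flow=30.0)
        spec = ra.MCSpec(40_000, seed=7, distributions={
            "generation:task": {"kind": "normal", "mean": 0.6, "sd": 0.0714},
        })
        summary = mc_steady_state(sys, spec)
        det = ra.mass_to_ppb(ra.steady_state(sys.with_generation(0.6)).c_nf, 86.09)
        assert summary["median"] == pytest.approx(det, rel=0.02)
        assert summary["p95"] >= summary["median"]

    def test_steady_state_mc_matches_direct_sampling_oracle(self):
        sys = make_system(interzone_flow=30.0)
        spec = ra.MCSpec(100_000, seed=11, distributions={
            "generation:task": {"kind": "normal", "mean": 0.6, "sd": 0.14 / 1.96},
            "supply_air": {"kind": "uniform", "lo": 65.9, "hi": 80.5},
        })
        summary = mc_steady_state(sys, spec)
        # Independent oracle: direct sampling of G*(1/Q + 1/beta)*conv.
        rng = np.random.default_rng(123)
        g = 0.6 + (0.14 / 1.96) * rng.standard_normal(100_000)
        g = np.abs(g)  # truncation is immaterial this far from zero
        q = rng.uniform(65.9, 80.5, 100_000)
        vals = g * (1 / q + 1 / 30.0) * ra.mass_to_ppb(1.0, 86.09)
        assert summary["median"] == pytest.approx(np.median(vals), rel=0.01)
        assert summary["median"] == pytest.approx(8.0, abs=0.2)

    def test_halved_iterations_stable_within_batch_se(self):
        sched = ra.build_schedule("scenario_A")
        sys = ra.default_system("scenario_A")
        dists = {
            "supply_air": {"kind": "uniform", "lo": 65.9, "hi": 80.5},
            "generation:grinding": {"kind": "normal", "mean": 0.6, "sd": 0.14 / 1.96},
        }
        full = ra.run_mc(sched, sys, ra.MCSpec(200, seed=5, distributions=dists),
                         dt_min=0.5)
        half = ra.run_mc(sched, sys, ra.MCSpec(100, seed=5, distributions=dists),
                         dt_min=0.5)
        se = max(full.full_shift_median_batch_se, 1e-9)
        assert abs(full.full_shift_median_ppb - half.full_shift_median_ppb) < 3 * se + 0.05

    def test_unmapped_distribution_name_rejected(self):
        spec = ra.MCSpec(5, seed=1, distributions={"nonsense": 1.0})
        with pytest.raises(ConfigError):
            ra.run_mc(ra.build_schedule("scenario_A"),
                      ra.default_system("scenario_A"), spec, dt_min=0.5)


class TestSensitivityBeta:
    def test_reduced_form_is_exactly_linear(self):
        sys = make_system()
        res = ra.sensitivity_beta(sys, [1.77, 5.3, 10.6, 42.4])
        conv = ra.mass_to_ppb(1.0, 86.09)
        assert res.slope_ppb_m3_min == pytest.approx(0.6 * conv, rel=1e-9)
        assert res.intercept_ppb == pytest.approx(0.6 / 73.2 * conv, rel=1e-9)
        assert res.max_abs_residual_ppb < 1e-9

    def test_fold_change_still_air(self):
        sys = make_system()
        res = ra.sensitivity_beta(sys, [1.77, 5.3])
        assert res.fold_change(1.77, 5.3) == pytest.approx(2.9, abs=0.05)

    def test_fold_change_typical_air(self):
        sys = make_system()
        res = ra.sensitivity_beta(sys, [10.6, 42.4])
        # (1/Q + 1/10.6) / (1/Q + 1/42.4)
        expected = (1 / 73.2 + 1 / 10.6) / (1 / 73.2 + 1 / 42.4)
        assert res.fold_change(10.6, 42.4) == pytest.approx(expected, rel=1e-9)

    def test_well_mixed_limit(self):
        sys = make_system()
        res = ra.sensitivity_beta(sys, [1e6, 1e7])
        gq = ra.mass_to_ppb(0.6 / 73.2, 86.09)
        # beta = 1e6 leaves a residual G/beta term of relative size Q/beta.
        assert res.table["c_nf_ppb"].iloc[0] == pytest.approx(gq, rel=1e-4)
        assert res.fold_change(1e6, 1e7) == pytest.approx(1.0, abs=1e-4)

    def test_fold_changes_invariant_to_generation_rescale(self):
        a = ra.sensitivity_beta(make_system(generation=0.6), [1.77, 5.3])
        b = ra.sensitivity_beta(make_system(generation=6.0), [1.77, 5.3])
        assert a.fold_change(1.77, 5.3) == pytest.approx(b.fold_change(1.77, 5.3), rel=1e-12)
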