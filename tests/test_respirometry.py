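import math
import warnings

import numpy as np
import pytest

from sealmito import respirometry as resp
from sealmito.errors import (
    ClippingWarning,
    InsufficientDataError,
    MissingBaselineError,
    NoVarianceError,
    QCWarning,
    UndefinedRatioError,
    ValidationError,
)
from sealmito.respirometry import (
    FluxSeries,
    OxygenTrace,
    RunStates,
    SampleStateSet,
    SteadyState,
    TitrationEvent,
)
from sealmito.synthetic import TraceSpec, simulate_trace

from conftest import TRUE_FLUXES


class TestOxygenTrace:
    def test_time_must_increase(self):
        with pytest.raises(ValidationError, match="increasing"):
            OxygenTrace("r", "a", "pre", "B", [0, 1, 1], [1, 1, 1], 2.0, 2.0)

    def test_positive_volume_and_mass(self):
        with pytest.raises(ValidationError):
            OxygenTrace("r", "a", "pre", "B", [0, 1], [1, 1], 0.0, 2.0)
        with pytest.raises(ValidationError):
            OxygenTrace("r", "a", "pre", "B", [0, 1], [1, 1], 2.0, -1.0)

    def test_negative_conc_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            OxygenTrace("r", "a", "pre", "B", [0, 1], [1, -1], 2.0, 2.0)

    def test_events_sorted(self):
        tr = OxygenTrace(
            "r", "a", "pre", "B", [0, 1, 2], [3, 2, 1], 2.0, 2.0,
            events=[TitrationEvent(2.0, "ADP"), TitrationEvent(1.0, "M")],
        )
        assert [e.t for e in tr.events] == [1.0, 2.0]

    def test_unknown_agent(self):
        with pytest.raises(ValidationError, match="agent"):
            TitrationEvent(0.0, "caffeine")


class TestComputeFlux:
    def test_constant_conc_zero_flux(self, constant_trace):
        fx = resp.compute_flux(constant_trace, smoothing_window=20)
        assert np.allclose(fx.flux, 0.0, atol=1e-9)

    def test_linear_decline_dimensional_oracle(self, linear_trace):
        # -1 nmol ml^-1 s^-1 * 2 ml / 2 mg = 1 nmol s^-1 mg^-1 = 1000 pmol
        fx = resp.compute_flux(linear_trace, smoothing_window=20)
        assert np.allclose(fx.flux, 1000.0, rtol=1e-9)

    def test_noisy_plateau_recovery_within_5pct(self, protocols):
        spec = TraceSpec(protocol_id="B", true_state_fluxes=TRUE_FLUXES,
                         noise_sd=0.5, tissue_mass=5.0, seed=11)
        trace, _ = simulate_trace(spec, protocols)
        fx = resp.compute_flux(trace, smoothing_window=60)
        states = resp.detect_steady_states(
            fx, trace.events, protocols["B"], stability_tol=0.3, window=240
        )
        states = resp.baseline_correct(states, run_id=trace.run_id)
        oxphos = next(s for s in states if s.state_label == "OXPHOS")
        assert oxphos.flux == pytest.approx(40.0, rel=0.05)

    def test_too_few_samples(self):
        tr = OxygenTrace("r", "a", "pre", "B", [0, 1], [2, 1], 2.0, 2.0)
        with pytest.raises(InsufficientDataError):
            resp.compute_flux(tr, smoothing_window=1.5)

    def test_window_larger_than_span(self, linear_trace):
        with pytest.raises(ValidationError):
            resp.compute_flux(linear_trace, smoothing_window=500.0)

    def test_sparse_sampling_in_window(self, linear_trace):
        with pytest.raises(InsufficientDataError):
            resp.compute_flux(linear_trace, smoothing_window=2.0)

    def test_reox_interval_masked(self, protocols):
        spec = TraceSpec(protocol_id="B", true_state_fluxes=TRUE_FLUXES,
                         tissue_mass=5.0, dwell=1500.0, seed=3)
        trace, _ = simulate_trace(spec, protocols)
        assert trace.reox_times, "fixture should trigger reoxygenation"
        fx = resp.compute_flux(trace, smoothing_window=20)
        for lo, hi in fx.masked_intervals:
            sel = (fx.t >= lo) & (fx.t <= hi)
            assert np.all(np.isnan(fx.flux[sel]))

    def test_nonuniform_sampling(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.5, 1.5, size=200))
        conc = 400.0 - 0.5 * t
        tr = OxygenTrace("r", "a", "pre", "B", t, conc, 2.0, 2.0)
        fx = resp.compute_flux(tr, smoothing_window=20)
        assert np.allclose(fx.flux, 500.0, rtol=1e-6)


class TestDetectSteadyStates:
    def test_generator_plateaus_protocol_b(self, protocols, noiseless_b_run):
        trace, truth = noiseless_b_run
        fx = resp.compute_flux(trace)
        states = resp.detect_steady_states(fx, trace.events, protocols["B"])
        states = resp.baseline_correct(states, run_id=trace.run_id)
        got = {s.state_label: s.flux for s in states}
        assert got["Ln"] == pytest.approx(5.0, abs=1e-6)
        assert got["OXPHOS"] == pytest.approx(40.0, abs=1e-6)
        assert got["LOmy"] == pytest.approx(8.0, abs=1e-6)
        assert got["ETS"] == pytest.approx(55.0, abs=1e-6)

    def test_zero_events_only_baseline(self, constant_trace, protocols):
        fx = resp.compute_flux(constant_trace, smoothing_window=20)
        states = resp.detect_steady_states(fx, [], protocols["B"])
        assert [s.state_label for s in states] == ["baseline"]

    def test_unstable_ramp_flagged_missing(self, protocols):
        # relative slope of exp(k t) is k = 5% > stability_tol everywhere
        t = np.arange(0.0, 200.0, 1.0)
        flux = np.exp(0.05 * t)
        fs = FluxSeries(t=t, flux=flux)
        states = resp.detect_steady_states(fs, [], protocols["B"],
                                           stability_tol=0.02, window=60)
        assert len(states) == 1
        assert states[0].missing
        assert "no_steady_state" in states[0].qc_flags

    def test_windows_never_overlap_reox(self, protocols):
        spec = TraceSpec(protocol_id="B", true_state_fluxes=TRUE_FLUXES,
                         tissue_mass=5.0, dwell=1500.0, seed=3)
        trace, _ = simulate_trace(spec, protocols)
        fx = resp.compute_flux(trace)
        states = resp.detect_steady_states(fx, trace.events, protocols["B"])
        for s in states:
            if s.window is None:
                continue
            for lo, hi in fx.masked_intervals:
                assert s.window[1] <= lo or s.window[0] >= hi

    def test_state_labels_follow_protocol(self, protocols, noiseless_b_run):
        trace, _ = noiseless_b_run
        fx = resp.compute_flux(trace)
        states = resp.detect_steady_states(fx, trace.events, protocols["B"])
        assert [s.state_label for s in states] == [
            "baseline", "Ln", "OXPHOS", "cytc_check", "LOmy", "ETS"
        ]


class TestBaselineCorrect:
    def test_simple_subtraction(self):
        states = [SteadyState("baseline", 2.0), SteadyState("OXPHOS", 42.0)]
        out = resp.baseline_correct(states)
        assert out[1].flux == pytest.approx(40.0)
        assert out[1].baseline_corrected

    def test_zero_baseline_identity(self):
        states = [SteadyState("baseline", 0.0), SteadyState("Ln", 5.0)]
        out = resp.baseline_correct(states)
        assert out[1].flux == 5.0

    def test_negative_clipped_with_warning(self):
        states = [SteadyState("baseline", 5.0), SteadyState("Ln", 4.0)]
        with pytest.warns(ClippingWarning):
            out = resp.baseline_correct(states)
        assert out[1].flux == 0.0
        assert "clipped_negative" in out[1].qc_flags

    def test_missing_baseline_names_run(self):
        with pytest.raises(MissingBaselineError, match="runX"):
            resp.baseline_correct([SteadyState("OXPHOS", 40.0)], run_id="runX")

    def test_explicit_baseline_flux(self):
        out = resp.baseline_correct([SteadyState("ETS", 57.0)], baseline_flux=2.0)
        assert out[0].flux == pytest.approx(55.0)


class TestCytcTest:
    def test_exactly_10pct_passes(self):
        assert resp.cytc_test(40.0, 44.0) is True  # strict inequality

    def test_zero_change_passes(self):
        assert resp.cytc_test(40.0, 40.0) is True

    def test_15pct_fails(self):
        assert resp.cytc_test(40.0, 46.0) is False

    def test_nonpositive_before_errors(self):
        with pytest.raises(UndefinedRatioError):
            resp.cytc_test(0.0, 5.0)
        with pytest.raises(UndefinedRatioError):
            resp.cytc_test(-1.0, 5.0)


class TestOxygenWindow:
    def _trace(self, conc):
        t = np.arange(float(len(conc)))
        return OxygenTrace("r", "a", "pre", "B", t, conc, 2.0, 2.0,
                           events=[TitrationEvent(0.0, "M")])

    def test_in_range_empty(self):
        tr = self._trace(np.linspace(400, 250, 100))
        assert resp.check_oxygen_window(tr) == []

    def test_dip_below_reported(self):
        conc = np.full(100, 300.0)
        conc[40:71] = 240.0  # 30 s excursion
        tr = self._trace(conc)
        intervals = resp.check_oxygen_window(tr)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert hi - lo == pytest.approx(30.0)

    def test_bounds_closed(self):
        tr = self._trace(np.concatenate([[400.0], np.full(50, 300.0), [250.0]]))
        assert resp.check_oxygen_window(tr) == []

    def test_only_after_first_event(self):
        conc = np.full(100, 300.0)
        conc[:5] = 200.0  # before the event at t=10
        t = np.arange(100.0)
        tr = OxygenTrace("r", "a", "pre", "B", t, conc, 2.0, 2.0,
                         events=[TitrationEvent(10.0, "M")])
        assert resp.check_oxygen_window(tr) == []


class TestAggregateSample:
    def test_standardization_identity_single_run(self):
        run = RunStates("B", {"OXPHOS": 40.0, "LOmy": 40.0})
        s = resp.aggregate_sample([run], "a", "pre")
        assert s.std_LOmy == pytest.approx(s.mean_OXPHOS)

    def test_hand_computed_standardization(self):
        # pooled OXPHOS {40, 44, 40, 44} -> mean 42; CI/OXPHOS_CI = 0.75
        runs = [
            RunStates("A", {"OXPHOS": 40.0, "Ln": 5.0, "ETS": 55.0}),
            RunStates("B", {"OXPHOS": 44.0, "Ln": 6.0, "ETS": 57.0}),
            RunStates("CI", {"OXPHOS": 40.0, "CI": 30.0, "ETS": 56.0}),
            RunStates("CII", {"OXPHOS": 44.0, "CII": 22.0, "ETS": 58.0}),
        ]
        s = resp.aggregate_sample(runs, "a", "pre")
        assert s.mean_OXPHOS == pytest.approx(42.0)
        assert s.std_CI == pytest.approx(31.5)
        assert s.std_CII == pytest.approx(0.5 * 42.0)
        assert s.mean_Ln == pytest.approx(5.5)

    def test_excluded_run_contributes_nothing(self):
        runs = [
            RunStates("A", {"OXPHOS": 40.0, "Ln": 5.0}),
            RunStates("B", {"OXPHOS": 100.0, "Ln": 50.0}, cytc_pass=False),
        ]
        s = resp.aggregate_sample(runs, "a", "pre")
        assert s.mean_OXPHOS == pytest.approx(40.0)
        assert s.mean_Ln == pytest.approx(5.0)
        assert s.n_runs == 1

    def test_all_excluded_marks_sample(self):
        runs = [RunStates("A", {"OXPHOS": 40.0}, cytc_pass=False)]
        s = resp.aggregate_sample(runs, "a", "pre")
        assert s.excluded

    def test_single_state_missing_oxphos_in_run(self):
        runs = [
            RunStates("A", {"OXPHOS": 40.0}),
            RunStates("CI", {"CI": 30.0}),  # no OXPHOS in the measuring run
        ]
        s = resp.aggregate_sample(runs, "a", "pre")
        assert math.isnan(s.std_CI)

    def test_exclusion_monotonicity(self):
        runs = [
            RunStates("A", {"OXPHOS": 40.0, "Ln": 5.0, "ETS": 55.0}),
            RunStates("B", {"OXPHOS": 44.0, "Ln": 6.0, "LOmy": 8.0}),
        ]
        full = resp.aggregate_sample(runs, "a", "pre")
        fewer = resp.aggregate_sample(
            [runs[0], RunStates("B", runs[1].states, cytc_pass=False)], "a", "pre"
        )
        assert fewer.n_runs < full.n_runs
        assert math.isnan(fewer.std_LOmy) and not math.isnan(full.std_LOmy)

    def test_leak_states_never_pooled(self):
        # Ln and LOmy stay distinct even when both are present
        runs = [RunStates("B", {"OXPHOS": 40.0, "Ln": 5.0, "LOmy": 13.0})]
        s = resp.aggregate_sample(runs, "a", "pre")
        assert s.mean_Ln == pytest.approx(5.0)
        assert s.std_LOmy == pytest.approx(13.0)


class TestRespiratoryRatios:
    def _sample(self, **kw):
        base = dict(animal_id="a", timepoint="pre", mean_Ln=10.0,
                    mean_OXPHOS=40.0, mean_ETS=40.0, std_CI=31.5,
                    std_CII=20.0, std_LOmy=8.0)
        base.update(kw)
        return SampleStateSet(**base)

    def test_fcr_unity_when_equal(self):
        r = resp.respiratory_ratios(self._sample())
        assert r.FCR == pytest.approx(1.0)

    def test_ccr_arithmetic(self):
        r = resp.respiratory_ratios(self._sample())
        assert r.CCR_Ln == pytest.approx(0.25)

    def test_scr_ci_continues_aggregate_example(self):
        r = resp.respiratory_ratios(self._sample(mean_OXPHOS=42.0, mean_ETS=56.0))
        assert r.SCR_CI == pytest.approx(0.75)

    def test_ratio_roundtrip(self):
        s = self._sample(mean_OXPHOS=42.0, mean_ETS=56.0)
        r = resp.respiratory_ratios(s)
        assert r.SCR_CI * s.mean_OXPHOS == pytest.approx(s.std_CI, rel=1e-12)

    def test_zero_denominator_errors(self):
        with pytest.raises(UndefinedRatioError, match="OXPHOS"):
            resp.respiratory_ratios(self._sample(mean_OXPHOS=0.0))
        with pytest.raises(UndefinedRatioError, match="ETS"):
            resp.respiratory_ratios(self._sample(mean_ETS=0.0))

    def test_warns_outside_unit_interval(self):
        with pytest.warns(QCWarning, match="FCR"):
            resp.respiratory_ratios(self._sample(mean_ETS=20.0))


class TestPairedCompare:
    def test_textbook_oracle(self):
        # diffs = [1, 3, 1, -1]: mean 1, sd sqrt(8/3), t = 1.2247...,
        # p = 2*sf(t, df=3) = 0.30807 (frozen closed-form computation)
        res = resp.paired_compare([10, 12, 9, 14], [11, 15, 10, 13])
        assert res.t == pytest.approx(1.224744871391589, rel=1e-12)
        assert res.p == pytest.approx(0.3080680092503572, rel=1e-9)
        assert res.mean_diff == pytest.approx(1.0)
        assert not res.significant

    def test_identical_vectors_no_variance(self):
        with pytest.raises(NoVarianceError):
            resp.paired_compare([1, 2, 3], [1, 2, 3])

    def test_constant_shift_no_variance(self):
        with pytest.raises(NoVarianceError):
            resp.paired_compare([1, 2, 3], [2, 3, 4])

    def test_listwise_deletion(self):
        res = resp.paired_compare([10, 12, math.nan, 9, 14],
                                  [11, 15, 20.0, 10, 13])
        assert res.n == 4
        assert res.t == pytest.approx(1.224744871391589, rel=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            resp.paired_compare([1.0], [2.0])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            resp.paired_compare([1, 2], [1, 2, 3])


class TestRunStates:
    def test_cytc_failure_excludes(self, protocols):
        spec = TraceSpec(protocol_id="B", true_state_fluxes=TRUE_FLUXES,
                         cytc_bump_frac=0.15, seed=5)
        trace, _ = simulate_trace(spec, protocols)
        fx = resp.compute_flux(trace)
        states = resp.detect_steady_states(fx, trace.events, protocols["B"])
        states = resp.baseline_correct(states, run_id=trace.run_id)
        run = resp.run_states(protocols["B"], states)
        assert not run.cytc_pass
        assert run.excluded

    def test_small_bump_passes(self, protocols, noiseless_b_run):
        trace, _ = noiseless_b_run  # default 2% bump
        fx = resp.compute_flux(trace)
        states = resp.detect_steady_states(fx, trace.events, protocols["B"])
        states = resp.baseline_correct(states, run_id=trace.run_id)
        run = resp.run_states(protocols["B"], states)
        assert run.cytc_pass
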