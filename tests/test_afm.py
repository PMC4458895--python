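"""Force-extension analysis: WLC mechanics, event detection, contour
length increments, classification and modal statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodfold.afm import (ForceExtensionTrace, WLCSegmentFit, accept_trace,
                         analyze_trace, classify_event, delta_lc,
                         detect_events, fit_segment, modal_stats,
                         speed_series, UnfoldingEvent)
from rodfold.simulate import (DomainClass, AFMSimConfig,
                              simulate_afm_trace, table_calibrated_config)
from rodfold.wlc import wlc_extension, wlc_force


class TestWLC:
    def test_force_vanishes_at_zero_extension(self):
        assert wlc_force(0.0, 80.0, 0.4) == 0.0

    def test_half_extension_closed_form(self):
        # (kBT/p) * [1/(4*(1/2)^2) - 1/4 + 1/2] = (4.114/0.4) * 1.25
        assert wlc_force(40.0, 80.0, 0.4) == pytest.approx(12.85625)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(10.0, 400.0), st.floats(0.1, 2.0))
    def test_strictly_increasing_in_extension(self, lc, p):
        x = np.linspace(0.0, lc * 0.999, 200)
        f = wlc_force(x, lc, p)
        assert np.all(np.diff(f) > 0)

    def test_domain_error_at_contour_length(self):
        with pytest.raises(ValueError):
            wlc_force(80.0, 80.0, 0.4)

    def test_inversion_roundtrip(self):
        f = np.array([5.0, 50.0, 400.0])
        x = wlc_extension(f, 100.0, 0.4)
        np.testing.assert_allclose(wlc_force(x, 100.0, 0.4), f,
                                   rtol=1e-9)


def _synthetic_rising_edge(lc, n=120, noise_sd=0.0, seed=0, p=0.4):
    rng = np.random.default_rng(seed)
    x = np.linspace(1.0, lc * 0.93, n)
    f = wlc_force(x, lc, p) + rng.normal(0, noise_sd, n)
    t = np.linspace(0, 1, n)
    return ForceExtensionTrace(t, x, f, speed=800.0)


class TestEventDetection:
    def test_saturated_trace_yields_fourteen_peaks(self, saturated_trace):
        trace, _ = saturated_trace
        peaks = detect_events(trace)
        assert len(peaks) == 14
        assert peaks[-1].is_detachment
        assert all(a.extension <= b.extension
                   for a, b in zip(peaks, peaks[1:]))

    def test_pure_noise_has_no_peaks(self):
        rng = np.random.default_rng(1)
        trace = ForceExtensionTrace(np.linspace(0, 1, 500),
                                    np.linspace(0, 100, 500),
                                    rng.normal(0, 5, 500), 800.0)
        assert detect_events(trace, min_drop=30.0) == []

    def test_truth_peak_indices_recovered_within_three_samples(self):
        total, hits = 0, 0
        for i in range(60):
            cfg = table_calibrated_config(speed=800.0, seed=7000 + i)
            trace, truth = simulate_afm_trace(cfg)
            peaks = detect_events(trace)
            det = np.array([p.index for p in peaks])
            for idx in truth.sample_index:
                total += 1
                if det.size and np.min(np.abs(det - idx)) <= 3:
                    hits += 1
        assert hits / total >= 0.95


class TestSegmentFitting:
    def test_noiseless_contour_length_recovery(self):
        trace = _synthetic_rising_edge(80.0)
        fit = fit_segment(trace, 0, trace.force.size)
        assert fit.converged
        assert fit.lc == pytest.approx(80.0, abs=0.1)

    def test_noisy_recovery_within_one_nm(self):
        hits = 0
        for s in range(40):
            trace = _synthetic_rising_edge(80.0, noise_sd=10.0, seed=s)
            fit = fit_segment(trace, 0, trace.force.size)
            if abs(fit.lc - 80.0) < 1.0:
                hits += 1
        assert hits >= 36   # 95% regime at 40 reps

    def test_short_segment_is_an_input_error(self):
        trace = _synthetic_rising_edge(80.0)
        with pytest.raises(ValueError, match="15 points"):
            fit_segment(trace, 0, 5)

    def test_fit_invariant_to_persistence_convention(self):
        # fitted Lc must always exceed the largest extension in range
        trace = _synthetic_rising_edge(60.0, noise_sd=5.0, seed=3)
        fit = fit_segment(trace, 0, trace.force.size)
        assert fit.lc > trace.extension.max()


class TestDeltaLc:
    def test_consecutive_difference(self):
        fits = [WLCSegmentFit(60.0, 0.4, 0, 10, 0.0, True),
                WLCSegmentFit(74.5, 0.4, 10, 20, 0.0, True)]
        d = delta_lc(fits)
        assert d[0] == pytest.approx(14.5)          # = 145 A
        with pytest.raises(ValueError):
            delta_lc(fits[:1])

    def test_generator_truth_recovered_with_small_bias(self):
        errs = []
        for i in range(40):
            cfg = table_calibrated_config(speed=800.0, seed=8000 + i)
            trace, truth = simulate_afm_trace(cfg)
            ana = analyze_trace(trace)
            true_dlc = (truth.lc_after_nm - truth.lc_before_nm).dropna()
            got = [e.dlc for e in ana.events
                   if e.domain_class in ("E", "G5")]
            if len(got) == len(true_dlc):
                errs.extend(np.array(got) - true_dlc.to_numpy())
        assert len(errs) > 300
        assert abs(np.mean(errs)) < 0.3

    def test_classified_dlc_bounded_by_total_gain(self, saturated_trace):
        trace, truth = saturated_trace
        ana = analyze_trace(trace)
        classified = sum(e.dlc for e in ana.events
                         if e.domain_class in ("E", "G5"))
        total_gain = truth.iloc[-1].lc_before_nm - trace.meta["initial_lc"]
        assert classified <= total_gain + 1e-6


class TestClassification:
    @pytest.mark.parametrize("dlc_nm, expected", [
        (14.5, "E"),        # 145 A
        (21.6, "G5"),       # 216 A
        (30.0, "other"),
        (12.0, "E"),
        (18.5, "G5"),
    ])
    def test_windows(self, dlc_nm, expected):
        assert classify_event(dlc_nm) == expected

    def test_class_separation_below_one_percent(self):
        # E-like (14.5 nm) and G5-like (21.6 nm) increments measured with
        # the table scatter almost never cross the window boundary
        rng = np.random.default_rng(4)
        e_like = rng.normal(14.5, 1.2, 5000)
        g_like = rng.normal(21.6, 0.6, 5000)
        mis = (np.sum([classify_event(v) == "G5" for v in e_like])
               + np.sum([classify_event(v) == "E" for v in g_like]))
        assert mis / 10000 < 0.01


class TestModalStats:
    def test_mode_recovery_from_table_sized_sample(self):
        rng = np.random.default_rng(5)
        stat = modal_stats(rng.normal(250.0, 35.0, 409))
        assert stat.mode == pytest.approx(250.0, abs=5.0)
        assert stat.n == 409

    def test_identical_values_degenerate(self):
        stat = modal_stats(np.full(30, 7.0))
        assert stat.degenerate and stat.mode == 7.0 and stat.sd == 0.0

    def test_two_class_mixture_recovered_after_classification(self):
        rng = np.random.default_rng(6)
        e = rng.normal(14.5, 1.2, 300)
        g = rng.normal(21.6, 0.6, 300)
        mixed = np.concatenate([e, g])
        cls = np.array([classify_event(v) for v in mixed])
        mode_e = modal_stats(mixed[cls == "E"], bin_width=0.5).mode
        mode_g = modal_stats(mixed[cls == "G5"], bin_width=0.5).mode
        assert mode_e == pytest.approx(14.5, abs=0.5)
        assert mode_g == pytest.approx(21.6, abs=0.5)

    def test_small_samples_refused(self):
        with pytest.raises(ValueError, match="20"):
            modal_stats(np.arange(10.0))


class TestSpeedSeries:
    def test_bell_generator_transition_state_distance_recovered(self):
        # single-class Bell construct with xu = 0.25 nm pulled at the five
        # canonical speeds; kBT/slope recovers xu within 30%
        speeds = (200.0, 800.0, 1500.0, 3000.0, 5000.0)
        modes = []
        for v in speeds:
            forces = []
            for i in range(25):
                cls = DomainClass("X", 4, k0=3e-5, xu=0.25, dlc=20.0)
                cfg = AFMSimConfig(classes=(cls,), speed=v, seed=9000 + i,
                                   initial_lc=100.0, force_noise_sd=0.0,
                                   sample_rate=5000.0)
                _, truth = simulate_afm_trace(cfg)
                forces.extend(truth[truth.domain_class == "X"].force_pN)
            modes.append(np.mean(forces))
        fit = speed_series(speeds, modes)
        assert fit.xu_nm == pytest.approx(0.25, rel=0.30)

    def test_speed_independent_forces_give_zero_slope(self):
        fit = speed_series((200, 800, 3000), (300.0, 300.0, 300.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_speeds_rejected(self):
        with pytest.raises(ValueError):
            speed_series((200, 800), (250.0, 270.0))


class TestTraceAcceptance:
    def test_saturated_trace_accepted_with_full_composition(
            self, saturated_trace):
        trace, _ = saturated_trace
        ana = analyze_trace(trace)
        assert ana.accepted
        by_class = [e.domain_class for e in ana.events]
        assert by_class.count("E") == 6 and by_class.count("G5") == 7

    def test_too_few_events_rejected(self):
        events = [UnfoldingEvent(250.0, 10, 80.0, 14.5, "E"),
                  UnfoldingEvent(400.0, 90, 95.0, None, "detachment")]
        ok, reason = accept_trace(events)
        assert not ok and reason == "too few events"

    def test_excess_composition_rejected(self):
        events = ([UnfoldingEvent(400.0, i, 80.0, 21.6, "G5")
                   for i in range(8)]
                  + [UnfoldingEvent(500.0, 99, 95.0, None, "detachment")])
        ok, reason = accept_trace(events)
        assert not ok and reason == "exceeds composition"


def test_trace_validation():
    with pytest.raises(ValueError, match="non-decreasing"):
        ForceExtensionTrace(np.linspace(0, 1, 200),
                            np.linspace(100, 0, 200),
                            np.zeros(200), 800.0)
    with pytest.raises(ValueError, match="100"):
        ForceExtensionTrace(np.zeros(10), np.zeros(10), np.zeros(10),
                            800.0)
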