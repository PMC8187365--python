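import numpy as np
import pytest

from cardiomarker import synthetic as syn
from cardiomarker import transient_biomarkers as tb
from cardiomarker.errors import AnalysisError
from cardiomarker.trace_io import Trace


class TestSegmentation:
    def test_ten_segments_from_ten_second_ca_trace(self, ca_train):
        trace, stim, _ = ca_train
        segs = tb.segment_transients(trace, stim, "up")
        assert len(segs) == 10

    def test_down_polarity_peaks_are_minima(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        segs = tb.segment_transients(trace, stim, "down")
        for s in segs:
            assert s.peak_level <= s.baseline_level

    def test_noiseless_baseline_exact(self, ca_train):
        trace, stim, _ = ca_train
        for s in tb.segment_transients(trace, stim, "up"):
            assert s.baseline_level == pytest.approx(100.0, abs=0.7)


class TestCaAmplitude:
    def test_half_amplitude_transient(self, ca_train):
        trace, stim, _ = ca_train
        segs = tb.segment_transients(trace, stim, "up")
        mean_dff, values = tb.ca_peak_amplitude(segs)
        assert mean_dff == pytest.approx(0.50, abs=0.02)
        assert len(values) == 10

    def test_identical_transients_zero_spread(self, ca_train):
        trace, stim, _ = ca_train
        _, values = tb.ca_peak_amplitude(tb.segment_transients(trace, stim, "up"))
        assert np.std(values) < 0.01

    def test_noisy_closed_loop(self):
        trace, stim, _ = syn.gen_ca_train(syn.ca_params(noise_sd=2.0, seed=8))
        segs = tb.segment_transients(trace, stim, "up")
        mean_dff, _ = tb.ca_peak_amplitude(segs)
        assert mean_dff == pytest.approx(0.50, abs=0.02)

    def test_gain_invariance(self, ca_train):
        """dF/F0 is unchanged by a multiplicative gain on the whole trace."""
        trace, stim, _ = ca_train
        scaled = Trace(samples=trace.samples * 7.3,
                       sampling_rate_hz=trace.sampling_rate_hz,
                       unit="AU", kind="fluorescence")
        a, _ = tb.ca_peak_amplitude(tb.segment_transients(trace, stim, "up"))
        b, _ = tb.ca_peak_amplitude(tb.segment_transients(scaled, stim, "up"))
        assert b == pytest.approx(a, rel=1e-9)

    def test_nonpositive_f0_refused(self, ca_train):
        trace, stim, _ = ca_train
        shifted = Trace(samples=trace.samples - 200.0,
                        sampling_rate_hz=trace.sampling_rate_hz,
                        unit="AU", kind="fluorescence")
        segs = tb.segment_transients(shifted, stim, "up")
        with pytest.raises(AnalysisError):
            tb.ca_peak_amplitude(segs)


class TestShortening:
    def test_five_percent_shortening(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        segs = tb.segment_transients(trace, stim, "down")
        vals = [tb.shortening_percent(s) for s in segs]
        assert np.mean(vals) == pytest.approx(5.0, abs=0.1)  # 0.09/1.80

    def test_unit_rescaling_invariance(self, sarcomere_train):
        """shortening_percent is unchanged by um -> nm rescaling."""
        trace, stim, _ = sarcomere_train
        nm = Trace(samples=trace.samples * 1000.0,
                   sampling_rate_hz=trace.sampling_rate_hz,
                   unit="um", kind="sarcomere_length")
        a = [tb.shortening_percent(s) for s in tb.segment_transients(trace, stim, "down")]
        b = [tb.shortening_percent(s) for s in tb.segment_transients(nm, stim, "down")]
        assert np.allclose(a, b)


class TestSarcomereLengthFFT:
    @pytest.mark.parametrize("period", [1.5, 1.7, 1.8, 2.0, 2.2])
    def test_noiseless_recovery_within_half_percent(self, period):
        profile = syn.gen_striation_profile(period, 0.1, 256, 0.0, 1)
        res = tb.sarcomere_length_from_fft(profile, 0.1)
        assert abs(res.length_um - period) / period <= 0.005

    @pytest.mark.parametrize("period", [1.5, 1.7, 1.8, 2.0, 2.2])
    def test_noisy_recovery_within_two_percent(self, period):
        profile = syn.gen_striation_profile(period, 0.1, 256, 0.2, 2)
        res = tb.sarcomere_length_from_fft(profile, 0.1)
        assert abs(res.length_um - period) / period <= 0.02

    def test_white_noise_reports_no_striation(self):
        rng = np.random.default_rng(3)
        profile = Trace(samples=rng.normal(0, 1, 256), sampling_rate_hz=10.0,
                        unit="AU", kind="intensity_profile")
        res = tb.sarcomere_length_from_fft(profile, 0.1)
        assert res.length_um is None
        assert any("no striation" in f for f in res.findings)

    def test_short_profile_refused(self):
        profile = syn.gen_striation_profile(1.8, 0.1, 256, 0.0, 1)
        short = Trace(samples=profile.samples[:32], sampling_rate_hz=10.0,
                      unit="AU", kind="intensity_profile")
        with pytest.raises(AnalysisError):
            tb.sarcomere_length_from_fft(short, 0.1)


class TestPhaseFit:
    def test_noiseless_fit_tight_rmse(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        seg = tb.segment_transients(trace, stim, "down")[3]
        fit, features = tb.fit_transient_phases(seg)
        assert not fit.unfittable
        amp = seg.amplitude
        for rmse in fit.rmse:
            assert rmse <= 0.005 * amp or rmse < 1e-6
        assert features.shortening_percent == pytest.approx(5.0, abs=0.2)

    def test_boundaries_strictly_increasing(self, ca_train):
        trace, stim, _ = ca_train
        seg = tb.segment_transients(trace, stim, "up")[2]
        fit, _ = tb.fit_transient_phases(seg)
        b = fit.boundaries_ms
        assert b[0] < b[1] < b[2] < b[3]

    def test_features_match_raw_landmarks(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        seg = tb.segment_transients(trace, stim, "down")[3]
        _, features = tb.fit_transient_phases(seg)
        raw_ttp = (seg.peak_index - seg.onset_index) / seg.sampling_rate_hz * 1000.0
        one_sample_ms = 1000.0 / seg.sampling_rate_hz
        assert abs(features.time_to_peak_ms - raw_ttp) <= 2 * one_sample_ms

    def test_flat_failure_segment_unfittable(self):
        trace, stim, _ = syn.gen_sarcomere_train(
            syn.sarcomere_params(failure_probability=1.0, n_beats=3, seed=4))
        seg = tb.segment_transients(trace, stim, "down")[1]
        fit, features = tb.fit_transient_phases(seg)
        assert fit.unfittable and features is None


class TestSecondaryEvents:
    def test_injected_fraction_recovered(self):
        p = syn.sarcomere_params(secondary_event_probability=1.0,
                                 secondary_amplitude_fraction=0.3, n_beats=10, seed=3)
        trace, stim, truth = syn.gen_sarcomere_train(p)
        segs = tb.segment_transients(trace, stim, "down")
        assert len(truth.events) == 10
        for seg in segs:
            events = tb.detect_secondary_event(seg)
            assert len(events) == 1
            assert events[0].fraction == pytest.approx(0.3, abs=0.05)

    def test_clean_transients_empty(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        for seg in tb.segment_transients(trace, stim, "down"):
            assert tb.detect_secondary_event(seg) == []

    def test_event_below_threshold_documented_miss(self):
        p = syn.sarcomere_params(secondary_event_probability=1.0,
                                 secondary_amplitude_fraction=0.05, n_beats=5, seed=5)
        trace, stim, truth = syn.gen_sarcomere_train(p)
        assert truth.events  # injected...
        for seg in tb.segment_transients(trace, stim, "down"):
            assert tb.detect_secondary_event(seg) == []  # ...but below 0.10 default

    def test_ca_events_detected_at_20hz(self):
        p = syn.ca_params(secondary_event_probability=0.4,
                          secondary_amplitude_fraction=0.3, n_beats=50,
                          noise_sd=1.0, seed=6)
        trace, stim, truth = syn.gen_ca_train(p)
        segs = tb.segment_transients(trace, stim, "up")
        truth_beats = {e.beat_index for e in truth.events}
        detected = {k for k, s in enumerate(segs) if tb.detect_secondary_event(s)}
        assert len(detected & truth_beats) / len(truth_beats) >= 0.95
        assert len(detected - truth_beats) <= 1


class TestFailureDetector:
    def test_flat_segment_is_failure(self):
        trace, stim, _ = syn.gen_sarcomere_train(
            syn.sarcomere_params(failure_probability=1.0, n_beats=3, seed=4))
        seg = tb.segment_transients(trace, stim, "down")[1]
        assert tb.detect_contraction_failure(seg, reference_amplitude=0.09)

    def test_full_amplitude_is_not_failure(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        seg = tb.segment_transients(trace, stim, "down")[2]
        assert not tb.detect_contraction_failure(seg, reference_amplitude=0.09)

    def test_seeded_closed_loop_counts_match(self):
        p = syn.sarcomere_params(failure_probability=0.2, n_beats=100, seed=5)
        trace, stim, truth = syn.gen_sarcomere_train(p)
        segs = tb.segment_transients(trace, stim, "down")
        flags = [tb.detect_contraction_failure(s, 0.09) for s in segs]
        assert sorted(np.flatnonzero(flags)) == sorted(truth.failure_indices)

    def test_nonpositive_reference_refused(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        seg = tb.segment_transients(trace, stim, "down")[0]
        with pytest.raises(AnalysisError):
            tb.detect_contraction_failure(seg, reference_amplitude=0.0)


class TestIncidence:
    @pytest.mark.parametrize("n_events,denom,expected", [
        (7, 100, 7.0), (0, 100, 0.0), (3, 45, 100.0 * 3 / 45)])
    def test_printed_rule_cases(self, n_events, denom, expected):
        flags = [True] * n_events + [False] * (denom - n_events)
        unit = "cells" if denom == 45 else "transients"
        res = tb.event_incidence(flags, window=denom, unit=unit)
        assert res.incidence_percent == pytest.approx(expected, abs=1e-12)
        assert res.n_events == n_events and res.denominator == denom

    def test_window_takes_most_recent(self):
        flags = [True] * 50 + [False] * 100
        res = tb.event_incidence(flags, window=100)
        assert res.incidence_percent == 0.0

    def test_empty_window_refused(self):
        with pytest.raises(AnalysisError):
            tb.event_incidence([], window=100)


class TestContractionSummary:
    def test_identical_transients_zero_change(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        segs = tb.segment_transients(trace, stim, "down")
        ref = np.mean([s.amplitude for s in segs[-15:]])
        out = tb.contraction_condition_summary(segs, reference_mean=float(ref))
        assert out["percent_change"] == pytest.approx(0.0, abs=0.5)

    def test_drug_scaling_recovered(self):
        base = syn.sarcomere_params(seed=6)
        spec = syn.DrugEffectSpec(ec50_um=0.012, max_effect_fraction=1.5,
                                  affected_parameter="primary_amplitude")
        scaled = syn.apply_drug_effect(spec, base, 1e6)  # saturating: x1.5
        t0, s0, _ = syn.gen_sarcomere_train(base)
        t1, s1, _ = syn.gen_sarcomere_train(scaled)
        ref = np.mean([s.amplitude for s in tb.segment_transients(t0, s0, "down")[-15:]])
        out = tb.contraction_condition_summary(
            tb.segment_transients(t1, s1, "down"), reference_mean=float(ref))
        assert out["percent_change"] == pytest.approx(50.0, abs=3.0)

    def test_failures_excluded_from_average(self):
        p = syn.sarcomere_params(failure_probability=0.3, n_beats=40, seed=7)
        trace, stim, truth = syn.gen_sarcomere_train(p)
        segs = tb.segment_transients(trace, stim, "down")
        flags = [tb.detect_contraction_failure(s, 0.09) for s in segs]
        out = tb.contraction_condition_summary(segs, failure_flags=flags)
        assert out["mean_amplitude"] == pytest.approx(0.09, abs=0.005)

    def test_insufficient_transients_refused(self, sarcomere_train):
        trace, stim, _ = sarcomere_train
        segs = tb.segment_transients(trace, stim, "down")[:5]
        with pytest.raises(AnalysisError):
            tb.contraction_condition_summary(segs)
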