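import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomarker import ap_biomarkers as apb
from cardiomarker import synthetic as syn
from cardiomarker.errors import AnalysisError
from cardiomarker.trace_io import StimulusTrain, Trace


def linear_repolarization_beat(fs=10_000.0, baseline=-80.0, peak=40.0,
                               repol_ms=300.0):
    """Analytic beat: instantaneous upstroke then a linear fall to baseline.

    With a strictly linear 300 ms repolarization the APD at level p is
    p * 300 ms (up to one sample of upstroke width).
    """
    n_rep = int(repol_ms / 1000.0 * fs)
    seg = np.concatenate([
        [baseline],
        np.linspace(peak, baseline, n_rep + 1),
        np.full(int(0.2 * fs), baseline),
    ])
    return apb.BeatSegment(samples=seg, sampling_rate_hz=fs, baseline_mv=baseline,
                           peak_mv=peak, peak_index=1, stim_onset_s=0.0,
                           next_stim_onset_s=1.0)


class TestSegmentBeats:
    def test_one_segment_per_stimulus(self, clean_ap_train):
        trace, stim, _ = clean_ap_train
        segs = apb.segment_beats(trace, stim)
        assert len(segs) == 20
        # last segment runs to the end of the trace
        last = segs[-1]
        n_expected = trace.n_samples - trace.index_at(last.stim_onset_s)
        assert last.samples.size == n_expected

    def test_noiseless_baseline_equals_resting_potential(self, clean_ap_train):
        trace, stim, _ = clean_ap_train
        segs = apb.segment_beats(trace, stim)
        for seg in segs:
            assert seg.baseline_mv == pytest.approx(-80.0, abs=1e-9)

    def test_no_stimuli_refused(self):
        tr = Trace(samples=np.zeros(100), sampling_rate_hz=100, unit="mV",
                   kind="voltage")
        stim = StimulusTrain(onset_times_s=[5.0], period_s=1.0, pulse_width_ms=3.0)
        with pytest.raises(AnalysisError):
            apb.segment_beats(tr, stim)


class TestComputeAPD:
    def test_linear_repolarization_landmarks(self):
        """-80 -> +40 with a linear 300 ms fall: APD20/50/90 = 60/150/270 ms."""
        seg = linear_repolarization_beat()
        apds = apb.compute_apd(seg)
        one_sample_ms = 0.1
        assert apds[0.2] == pytest.approx(60.0, abs=2 * one_sample_ms)
        assert apds[0.5] == pytest.approx(150.0, abs=2 * one_sample_ms)
        assert apds[0.9] == pytest.approx(270.0, abs=2 * one_sample_ms)

    def test_generator_closed_loop_within_a_millisecond(self):
        p = syn.APGenParams(apd90_ms=310.0, n_beats=5, seed=2)
        trace, stim, truth = syn.gen_ap_train(p)
        segs = apb.segment_beats(trace, stim)
        for seg, target in zip(segs, truth.apd90_ms):
            assert apb.compute_apd(seg)[0.9] == pytest.approx(target, abs=1.0)

    def test_incomplete_repolarization_reported_absent(self):
        fs = 1000.0
        seg_samples = np.concatenate([[-80.0], np.linspace(40.0, -10.0, 500)])
        seg = apb.BeatSegment(samples=seg_samples, sampling_rate_hz=fs,
                              baseline_mv=-80.0, peak_mv=40.0, peak_index=1,
                              stim_onset_s=0.0, next_stim_onset_s=0.5)
        apds = apb.compute_apd(seg)
        assert apds[0.9] is None
        assert apds[0.2] is not None

    def test_nonpositive_amplitude_refused(self):
        seg = apb.BeatSegment(samples=np.full(10, -80.0), sampling_rate_hz=1000,
                              baseline_mv=-80.0, peak_mv=-80.0, peak_index=0,
                              stim_onset_s=0.0, next_stim_onset_s=1.0)
        with pytest.raises(AnalysisError):
            apb.compute_apd(seg)

    def test_ordering_invariant_on_random_synthetic_beats(self):
        """APD20 <= APD50 <= APD90 across 1000 randomized beats."""
        checked = 0
        for seed in range(5):
            p = syn.APGenParams(apd90_ms=300.0, variability_sd_ms=25.0,
                                ar1_coeff=0.3, n_beats=200, noise_sd_mv=0.3,
                                sampling_rate_hz=2000.0, seed=seed)
            trace, stim, _ = syn.gen_ap_train(p)
            series = apb.compute_apd_series(apb.segment_beats(trace, stim))
            for a20, a50, a90 in zip(series.apd20_ms, series.apd50_ms,
                                     series.apd90_ms):
                if None in (a20, a50, a90):
                    continue
                assert a20 <= a50 <= a90
                checked += 1
        assert checked >= 900


def stv_bruteforce(series, n_window=20):
    used = list(series)[-n_window:]
    return sum(abs(b - a) for a, b in zip(used[:-1], used[1:])) / (len(used) * math.sqrt(2))


class TestSTV:
    def test_constant_series_zero(self):
        assert apb.compute_stv([300.0] * 20).stv_ms == 0.0

    def test_alternating_series_printed_formula(self):
        series = [300.0, 310.0] * 10
        res = apb.compute_stv(series)
        assert res.stv_ms == pytest.approx(190.0 / (20.0 * math.sqrt(2)), abs=1e-12)
        assert res.n_beats == 20
        assert res.poincare_pairs.shape == (19, 2)

    def test_two_beat_series(self):
        res = apb.compute_stv([250.0, 260.0])
        assert res.stv_ms == pytest.approx(10.0 / (2.0 * math.sqrt(2)), abs=1e-12)

    def test_fewer_than_two_beats_refused(self):
        with pytest.raises(AnalysisError):
            apb.compute_stv([300.0])

    def test_absent_beats_excluded(self):
        series = [300.0, None, 310.0, 300.0]
        res = apb.compute_stv(series)
        assert res.n_beats == 3

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=50, max_value=600), min_size=2, max_size=40),
           st.floats(min_value=-100, max_value=100),
           st.floats(min_value=0.1, max_value=10))
    def test_translation_invariance_and_homogeneity(self, series, shift, scale):
        base = apb.compute_stv(series).stv_ms
        shifted = apb.compute_stv([x + shift for x in series]).stv_ms
        scaled = apb.compute_stv([x * scale for x in series]).stv_ms
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)
        assert base == pytest.approx(stv_bruteforce(series), rel=1e-12)


class TestEADDetector:
    def test_clean_beats_produce_no_events(self, clean_ap_train):
        trace, stim, _ = clean_ap_train
        assert apb.detect_eads_train(apb.segment_beats(trace, stim)) == []

    def test_injected_ead_recovered_with_amplitude(self):
        p = syn.APGenParams(apd90_ms=300.0, ead_probability=1.0,
                            ead_amplitude_mv=10.0, n_beats=5, seed=3)
        trace, stim, truth = syn.gen_ap_train(p)
        events = apb.detect_eads_train(apb.segment_beats(trace, stim))
        assert sorted(e.beat_index for e in events) == truth.ead_beats
        for e in events:
            assert abs(e.rise_mv - 10.0) <= 1.0

    def test_no_false_events_on_noisy_beats(self):
        p = syn.APGenParams(apd90_ms=300.0, n_beats=100, noise_sd_mv=1.0, seed=4)
        trace, stim, _ = syn.gen_ap_train(p)
        assert apb.detect_eads_train(apb.segment_beats(trace, stim)) == []

    def test_detection_rate_at_twice_threshold(self):
        """>= 95% of injected EADs found when amplitude is 2x the 5 mV
        threshold and noise sd is 1 mV."""
        p = syn.APGenParams(apd90_ms=300.0, ead_probability=0.3,
                            ead_amplitude_mv=10.0, n_beats=200,
                            noise_sd_mv=1.0, seed=5)
        trace, stim, truth = syn.gen_ap_train(p)
        events = apb.detect_eads_train(apb.segment_beats(trace, stim))
        detected = {e.beat_index for e in events}
        truth_set = set(truth.ead_beats)
        assert len(detected & truth_set) / len(truth_set) >= 0.95
        assert len(detected - truth_set) == 0


class TestConditionSummary:
    def _series(self, apd90):
        p = syn.APGenParams(apd90_ms=apd90, n_beats=25, seed=6)
        trace, stim, _ = syn.gen_ap_train(p)
        return apb.compute_apd_series(apb.segment_beats(trace, stim))

    def test_identical_series_zero_percent_change(self):
        s = self._series(300.0)
        out = apb.condition_summary(s, s)
        for v in out["percent_change"].values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_prolongation_reported_in_percent(self):
        out = apb.condition_summary(self._series(360.0), self._series(300.0))
        assert out["percent_change"]["apd90_ms"] == pytest.approx(20.0, abs=0.5)

    def test_too_few_beats_refused(self):
        p = syn.APGenParams(apd90_ms=300.0, n_beats=5, seed=7)
        trace, stim, _ = syn.gen_ap_train(p)
        s = apb.compute_apd_series(apb.segment_beats(trace, stim))
        with pytest.raises(AnalysisError):
            apb.condition_summary(s)
        assert apb.condition_summary(s, allow_fewer=True)["condition"]["apd90_ms"] > 0
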