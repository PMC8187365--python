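"""Generator contracts: determinism, ground-truth fidelity, parameter scaling."""

import dataclasses

import numpy as np
import pytest

from cardiomarker import late_ina
from cardiomarker import synthetic as syn
from cardiomarker.errors import ValidationError


class TestAPGenerator:
    def test_seed_determinism_bit_level(self):
        p = syn.APGenParams(apd90_ms=300, variability_sd_ms=5, ar1_coeff=0.4,
                            ead_probability=0.2, noise_sd_mv=1.0, n_beats=10, seed=7)
        t1, _, g1 = syn.gen_ap_train(p)
        t2, _, g2 = syn.gen_ap_train(p)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.apd90_ms, g2.apd90_ms)

    def test_forced_eads_listed_for_every_beat(self):
        p = syn.APGenParams(apd90_ms=300, ead_probability=1.0, n_beats=5, seed=3)
        _, _, truth = syn.gen_ap_train(p)
        assert truth.ead_beats == [0, 1, 2, 3, 4]
        assert len(truth.eads) == 5
        for e in truth.eads:
            assert 0.4 <= e.phase_fraction <= 0.9

    def test_overlapping_beats_refused(self):
        with pytest.raises(ValidationError, match="overlap"):
            syn.gen_ap_train(syn.APGenParams(apd90_ms=990, pacing_hz=1.0))

    def test_ar1_ground_truth_recovers_requested_moments(self):
        """n = 5000 draws: sample mean/sd of the APD90 process match the
        requested values within 3 standard errors of an AR(1) process."""
        rng = np.random.default_rng(11)
        x = syn.ar1_series(300.0, 5.0, 0.5, 5000, rng)
        se_mean = 5.0 / np.sqrt(5000) * np.sqrt((1 + 0.5) / (1 - 0.5))
        assert abs(np.mean(x) - 300.0) < 3 * se_mean
        assert abs(np.std(x, ddof=1) - 5.0) < 3 * 5.0 / np.sqrt(2 * 5000) * 2

    def test_ead_injection_sits_in_ground_truth_window(self):
        """Construction audit: the EAD hump must lie between the beat's peak
        and its (extended) 90% repolarization time."""
        p = syn.APGenParams(apd90_ms=300, ead_probability=1.0, n_beats=8, seed=9)
        trace, stim, truth = syn.gen_ap_train(p)
        for e in truth.eads:
            onset = stim.onset_times_s[e.beat_index]
            assert onset < e.onset_time_s < onset + truth.apd90_ms[e.beat_index] / 1000.0


class TestTransientGenerators:
    def test_no_secondary_events_when_probability_zero(self):
        _, _, truth = syn.gen_ca_train(syn.ca_params(seed=1))
        assert truth.events == []

    def test_ten_second_acquisition_yields_ten_transients(self):
        trace, stim, _ = syn.gen_ca_train(syn.ca_params(seed=1))
        assert stim.n_stimuli == 10
        assert trace.sampling_rate_hz == 20.0

    def test_events_lie_between_peak_and_next_stimulus(self):
        p = syn.sarcomere_params(secondary_event_probability=1.0, n_beats=20, seed=2)
        _, stim, truth = syn.gen_sarcomere_train(p)
        for e in truth.events:
            onset = stim.onset_times_s[e.beat_index]
            assert onset < e.onset_time_s < onset + stim.period_s

    def test_shortening_amplitude_refused_at_or_above_baseline(self):
        with pytest.raises(ValidationError):
            syn.gen_sarcomere_train(syn.sarcomere_params(primary_amplitude=1.8))

    def test_failures_recorded_and_flat(self):
        p = syn.sarcomere_params(failure_probability=1.0, n_beats=5, seed=3)
        trace, _, truth = syn.gen_sarcomere_train(p)
        assert truth.failure_indices == [0, 1, 2, 3, 4]
        assert np.allclose(trace.samples, 1.80)

    def test_nonpositive_decay_refused(self):
        with pytest.raises(ValidationError):
            syn.ca_params(decay_tau_ms=0.0)


class TestForceGenerator:
    def test_premature_cycles_precede_their_stimulus(self):
        _, stim, truth = syn.gen_force_train(
            syn.force_params(n_beats=40, seed=5), premature_probability=0.3)
        prem = [e for e in truth.events if e.label == "premature"]
        assert prem
        for e in prem:
            lead = stim.onset_times_s[e.beat_index] - e.onset_time_s
            assert 0.300 <= lead <= 0.450

    def test_automaticity_poisson_count(self):
        _, _, truth = syn.gen_force_train(
            syn.force_params(n_beats=20, seed=9), automaticity_rate_hz=0.5)
        spont = [e for e in truth.events if e.label == "spontaneous"]
        assert 5 <= len(spont) <= 15  # ~Poisson(10), seed-fixed

    def test_overlapping_rate_refused(self):
        with pytest.raises(ValidationError, match="overlap"):
            syn.gen_force_train(syn.force_params(), automaticity_rate_hz=2.0)


class TestStriationProfile:
    def test_nyquist_violation_refused(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            syn.gen_striation_profile(0.15, 0.1, 256, 0.0, 1)

    def test_profile_period_matches_request(self):
        tr = syn.gen_striation_profile(1.8, 0.1, 256, 0.0, 1)
        # count zero crossings of the centred profile: ~2 per period
        y = tr.samples - np.mean(tr.samples)
        crossings = np.sum(np.diff(np.signbit(y)))
        expected = 2 * 25.6 / 1.8
        assert abs(crossings - expected) <= 2


class TestDrugEffect:
    spec = syn.DrugEffectSpec(ec50_um=0.012, hill_coeff=1.0, max_effect_fraction=2.0,
                              affected_parameter="primary_amplitude",
                              event_prob_gain=0.4)

    def test_identity_at_zero_concentration(self):
        base = syn.sarcomere_params(seed=1)
        assert syn.apply_drug_effect(self.spec, base, 0.0) == base

    def test_half_effect_at_ec50(self):
        base = syn.sarcomere_params(seed=1)
        mid = syn.apply_drug_effect(self.spec, base, 0.012)
        # scaling 1 + (2-1)*0.5 = 1.5: exactly half the saturating doubling
        assert mid.primary_amplitude == pytest.approx(base.primary_amplitude * 1.5)
        assert mid.secondary_event_probability == pytest.approx(0.2)

    def test_ceiling_at_saturating_concentration(self):
        base = syn.sarcomere_params(seed=1)
        sat = syn.apply_drug_effect(self.spec, base, 1e9)
        assert sat.primary_amplitude == pytest.approx(base.primary_amplitude * 2.0, rel=1e-6)

    def test_unknown_parameter_refused(self):
        bad = dataclasses.replace(self.spec, affected_parameter="charisma")
        with pytest.raises(ValidationError, match="charisma"):
            syn.apply_drug_effect(bad, syn.sarcomere_params(seed=1), 0.01)


class TestRampCurrentGenerator:
    def test_zero_enhancer_scale_gives_pure_noise(self):
        protocol, _ = late_ina.build_ramp_protocol(10_000)
        p = syn.RampCurrentParams(enhancer_scale=0.0, noise_sd_pa=0.0)
        tr = syn.gen_ramp_current(protocol, p)
        assert np.allclose(tr.samples, 0.0)

    def test_default_peak_density_within_calibration_window(self):
        protocol, _ = late_ina.build_ramp_protocol(10_000)
        p = syn.RampCurrentParams(noise_sd_pa=0.0)
        iv = late_ina.extract_ramp_iv(syn.gen_ramp_current(protocol, p), protocol,
                                      p.capacitance_pf)
        assert 6.5 <= abs(iv.peak_density_pa_per_pf) <= 9.3
        assert abs(iv.peak_voltage_mv - 0.0) <= 2.0

    def test_gate_shift_moves_peak_left(self):
        protocol, _ = late_ina.build_ramp_protocol(10_000)
        base = late_ina.extract_ramp_iv(
            syn.gen_ramp_current(protocol, syn.RampCurrentParams(noise_sd_pa=0.0)),
            protocol, 100.0)
        shifted = late_ina.extract_ramp_iv(
            syn.gen_ramp_current(protocol,
                                 syn.RampCurrentParams(noise_sd_pa=0.0, shift_mv=-15.0)),
            protocol, 100.0)
        assert shifted.peak_voltage_mv - base.peak_voltage_mv == pytest.approx(-15.0, abs=2.0)
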