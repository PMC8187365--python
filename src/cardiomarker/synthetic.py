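"""Synthetic paced recordings with auditable ground truth.

Every analysis stage in this package is tested against traces produced here:
1 Hz-paced action-potential trains (10 kHz), Ca2+-fluorescence transients
(20 Hz imaging), sarcomere-shortening transients (240 Hz video), trabecula
force cycles (10 kHz) and voltage-ramp clamp currents.  Each generator takes
a mandatory seed, uses a single RNG stream, and returns the trace together
with a ground-truth record describing exactly what was injected (per-beat
APD90, event onsets and amplitudes, failure indices), so detector thresholds
can be audited by construction rather than by the detectors themselves.

The waveforms are phenomenological stand-ins, not biophysical models: the
action potential is a fast linear upstroke followed by a logistic
repolarization whose threshold crossings are analytically placed, and the
mechanical/fluorescence transient is the classic double-exponential
``(1 - exp(-t/tau_rise)) * exp(-t/tau_decay)``, rescaled so its peak equals
the requested amplitude and linearly detrended to return exactly to baseline
by the next stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .trace_io import StimulusTrain, Trace
from . import late_ina

_LN9 = math.log(9.0)


def ar1_series(mean: float, sd: float, coeff: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with the requested mean, sd and lag-1 coefficient.

    x_i = coeff * x_{i-1} + e_i with innovation variance sd^2*(1-coeff^2), so
    the marginal standard deviation is exactly ``sd``.
    """
    if not (0 <= coeff < 1):
        raise ValidationError("ar1 coefficient must be in [0, 1)")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    x = np.empty(n)
    if sd == 0:
        x.fill(0.0)
    else:
        innov_sd = sd * math.sqrt(1.0 - coeff**2)
        x[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            x[i] = coeff * x[i - 1] + rng.normal(0.0, innov_sd)
    return mean + x


def _make_train(stim_start_s: float, n_beats: int, pacing_hz: float,
                pulse_width_ms: float = 3.0) -> StimulusTrain:
    onsets = stim_start_s + np.arange(n_beats) / pacing_hz
    return StimulusTrain(onset_times_s=onsets, period_s=1.0 / pacing_hz,
                         pulse_width_ms=pulse_width_ms)


# --------------------------------------------------------------------------
# Action potentials
# --------------------------------------------------------------------------

@dataclass
class APGenParams:
    """Parameters of the paced action-potential train generator.

    ``apd90_ms`` is the target mean of the AR(1) per-beat APD90 process;
    ``tau_fraction`` sets the logistic repolarization time constant as a
    fraction of that beat's APD90.  EADs (``ead_probability`` per beat) are
    injected as a raised-cosine depolarizing hump of ``ead_amplitude_mv``
    during which repolarization pauses, so the net depolarizing rise equals
    the requested amplitude and the beat's effective APD90 is extended by
    ``ead_width_ms``.
    """

    apd90_ms: float = 300.0
    resting_mv: float = -80.0
    peak_mv: float = 40.0
    variability_sd_ms: float = 0.0
    ar1_coeff: float = 0.0
    ead_probability: float = 0.0
    ead_amplitude_mv: float = 10.0
    ead_width_ms: float = 40.0
    n_beats: int = 20
    pacing_hz: float = 1.0
    sampling_rate_hz: float = 10_000.0
    stim_start_s: float = 0.5
    upstroke_ms: float = 1.0
    tau_fraction: float = 1.0 / 12.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apd90_ms <= 0 or self.n_beats < 1 or self.pacing_hz <= 0:
            raise ValidationError("apd90_ms, n_beats and pacing_hz must be positive")
        if not (0 <= self.ar1_coeff < 1):
            raise ValidationError("ar1_coeff must be in [0, 1)")
        if not (0 <= self.ead_probability <= 1):
            raise ValidationError("ead_probability must be in [0, 1]")
        if self.ead_amplitude_mv < 0 or self.variability_sd_ms < 0 or self.noise_sd_mv < 0:
            raise ValidationError("amplitudes and noise sd must be >= 0")
        if self.peak_mv <= self.resting_mv:
            raise ValidationError("peak_mv must exceed resting_mv")


@dataclass
class EADTruth:
    beat_index: int
    onset_time_s: float
    amplitude_mv: float
    phase_fraction: float
    width_ms: float


@dataclass
class APGroundTruth:
    """What was actually put into the trace, beat by beat."""

    apd90_ms: np.ndarray    # effective values (EAD beats extended by the hump width)
    apd50_ms: np.ndarray
    apd20_ms: np.ndarray
    ead_beats: list[int]
    eads: list[EADTruth]


def _ap_landmarks(apd90: float, upstroke_ms: float, tau_fraction: float):
    """Logistic repolarization placed so the 90% crossing lands at apd90."""
    tau = tau_fraction * apd90
    # APD_p = t_mid + tau*ln(p/(1-p)) - (1-p)*upstroke; solve t_mid from p=0.9
    t_mid = apd90 + 0.1 * upstroke_ms - tau * _LN9
    apd50 = t_mid - 0.5 * upstroke_ms
    apd20 = t_mid - tau * math.log(4.0) - 0.8 * upstroke_ms
    return tau, t_mid, apd50, apd20


def gen_ap_train(params: APGenParams) -> tuple[Trace, StimulusTrain, APGroundTruth]:
    """Generate a paced AP train; returns trace, stimuli and ground truth."""
    p = params
    rng = np.random.default_rng(p.seed)
    period_ms = 1000.0 / p.pacing_hz
    margin_ms = 50.0  # diastolic baseline must exist before the next stimulus
    budget = p.apd90_ms + p.upstroke_ms + (p.ead_width_ms if p.ead_probability > 0 else 0.0)
    if budget >= period_ms - margin_ms:
        raise ValidationError(
            f"apd90_ms={p.apd90_ms:g} (+EAD width) does not fit the "
            f"{period_ms:g} ms pacing period; beats would overlap"
        )

    apd90 = ar1_series(p.apd90_ms, p.variability_sd_ms, p.ar1_coeff, p.n_beats, rng)
    hi = period_ms - margin_ms - p.upstroke_ms - (p.ead_width_ms if p.ead_probability > 0 else 0.0)
    apd90 = np.clip(apd90, 20.0, hi)

    ead_mask = rng.random(p.n_beats) < p.ead_probability
    ead_phase = rng.uniform(0.4, 0.9, p.n_beats)  # phase-2/3 window

    stim = _make_train(p.stim_start_s, p.n_beats, p.pacing_hz)
    duration = p.stim_start_s + p.n_beats / p.pacing_hz
    n = int(round(duration * p.sampling_rate_hz))
    t = np.arange(n) / p.sampling_rate_hz
    v = np.full(n, p.resting_mv)
    amp = p.peak_mv - p.resting_mv

    apd90_eff = apd90.copy()
    apd50_eff = np.empty(p.n_beats)
    apd20_eff = np.empty(p.n_beats)
    eads: list[EADTruth] = []

    for k in range(p.n_beats):
        onset = stim.onset_times_s[k]
        i0 = int(round(onset * p.sampling_rate_hz))
        i1 = min(int(round((onset + 1.0 / p.pacing_hz) * p.sampling_rate_hz)), n)
        tr = (t[i0:i1] - onset) * 1000.0  # ms from stimulus onset

        tau, t_mid, apd50_k, apd20_k = _ap_landmarks(apd90[k], p.upstroke_ms, p.tau_fraction)
        apd50_eff[k] = apd50_k
        apd20_eff[k] = apd20_k

        up = tr < p.upstroke_ms
        seg = np.where(
            up,
            p.resting_mv + amp * tr / p.upstroke_ms,
            p.resting_mv + amp / (1.0 + np.exp(np.clip((tr - t_mid) / tau, -500, 500))),
        )
        if ead_mask[k]:
            f = ead_phase[k]
            w = p.ead_width_ms
            t0 = t_mid + tau * math.log(f / (1.0 - f))  # time at fraction f repolarized
            v0 = p.resting_mv + amp * (1.0 - f)
            in_hump = (tr >= t0) & (tr < t0 + w)
            after = tr >= t0 + w
            seg = np.where(in_hump,
                           v0 + p.ead_amplitude_mv * np.sin(np.pi * (tr - t0) / w) ** 2,
                           seg)
            seg = np.where(after,
                           p.resting_mv + amp / (1.0 + np.exp(np.clip((tr - w - t_mid) / tau, -500, 500))),
                           seg)
            apd90_eff[k] = apd90[k] + w
            if f < 0.5:
                apd50_eff[k] = apd50_k + w
            eads.append(EADTruth(k, onset + t0 / 1000.0, p.ead_amplitude_mv, f, w))
        v[i0:i1] = seg

    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)

    trace = Trace(samples=v, sampling_rate_hz=p.sampling_rate_hz, unit="mV", kind="voltage")
    truth = APGroundTruth(apd90_eff, apd50_eff, apd20_eff,
                          [int(i) for i in np.flatnonzero(ead_mask)], eads)
    return trace, stim, truth


# --------------------------------------------------------------------------
# Double-exponential transients (Ca2+, sarcomere shortening, force)
# --------------------------------------------------------------------------

@dataclass
class TransientGenParams:
    """Parameters shared by the Ca2+/sarcomere/force transient generators.

    ``primary_amplitude`` is the absolute excursion (AU, um of shortening, or
    grams); secondary events are scaled by ``secondary_amplitude_fraction``.
    Use :func:`ca_params`, :func:`sarcomere_params` and :func:`force_params`
    for per-assay study defaults.
    """

    baseline_level: float = 100.0
    primary_amplitude: float = 50.0
    rise_tau_ms: float = 100.0
    decay_tau_ms: float = 250.0
    secondary_event_probability: float = 0.0
    secondary_amplitude_fraction: float = 0.3
    secondary_rise_tau_ms: float = 30.0
    secondary_decay_tau_ms: float = 80.0
    failure_probability: float = 0.0
    n_beats: int = 10
    pacing_hz: float = 1.0
    sampling_rate_hz: float = 20.0
    stim_start_s: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValidationError("rise_tau_ms and decay_tau_ms must be > 0")
        if self.primary_amplitude <= 0:
            raise ValidationError("primary_amplitude must be > 0")
        for name in ("secondary_event_probability", "secondary_amplitude_fraction",
                     "failure_probability"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_beats < 1 or self.pacing_hz <= 0 or self.sampling_rate_hz <= 0:
            raise ValidationError("n_beats, pacing_hz, sampling_rate_hz must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def ca_params(**overrides) -> TransientGenParams:
    """Study defaults for Ca2+ fluorescence: 10 s of 1 Hz pacing imaged at 20 Hz."""
    base = dict(baseline_level=100.0, primary_amplitude=50.0,
                rise_tau_ms=100.0, decay_tau_ms=200.0,
                secondary_rise_tau_ms=30.0, secondary_decay_tau_ms=100.0,
                n_beats=10, sampling_rate_hz=20.0)
    base.update(overrides)
    return TransientGenParams(**base)


def sarcomere_params(**overrides) -> TransientGenParams:
    """Study defaults for sarcomere shortening: 1.80 um resting length, 240 Hz video."""
    base = dict(baseline_level=1.80, primary_amplitude=0.09,
                rise_tau_ms=50.0, decay_tau_ms=120.0,
                secondary_rise_tau_ms=20.0, secondary_decay_tau_ms=80.0,
                n_beats=30, sampling_rate_hz=240.0)
    base.update(overrides)
    return TransientGenParams(**base)


def force_params(**overrides) -> TransientGenParams:
    """Study defaults for trabecula force: ~1 g resting tension, 10 kHz sampling."""
    base = dict(baseline_level=1.0, primary_amplitude=0.8,
                rise_tau_ms=60.0, decay_tau_ms=150.0,
                secondary_rise_tau_ms=30.0, secondary_decay_tau_ms=80.0,
                n_beats=30, sampling_rate_hz=10_000.0)
    base.update(overrides)
    return TransientGenParams(**base)


@dataclass
class EventTruth:
    beat_index: int
    onset_time_s: float
    amplitude: float        # absolute units of the trace
    fraction: float         # relative to the primary amplitude
    label: str              # "secondary" | "premature" | "spontaneous"


@dataclass
class TransientGroundTruth:
    amplitudes: np.ndarray          # intended primary amplitude per beat (0 for failures)
    failure_indices: list[int]
    events: list[EventTruth]


def _pulse_peak(rise_tau: float, decay_tau: float) -> tuple[float, float]:
    """Peak time and value of (1-exp(-t/rise))*exp(-t/decay)."""
    t_star = rise_tau * math.log((rise_tau + decay_tau) / rise_tau)
    f_max = (decay_tau / (rise_tau + decay_tau)) * math.exp(-t_star / decay_tau)
    return t_star, f_max


def _pulse(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential pulse; zero for t < 0."""
    _, f_max = _pulse_peak(rise_tau, decay_tau)
    f = (1.0 - np.exp(-np.maximum(t_ms, 0.0) / rise_tau)) * np.exp(-np.maximum(t_ms, 0.0) / decay_tau)
    return np.where(t_ms < 0, 0.0, f / f_max)


def _detrended_pulse(t_ms: np.ndarray, window_ms: float,
                     rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak pulse linearly detrended to reach exactly 0 at window_ms."""
    f = _pulse(t_ms, rise_tau, decay_tau)
    f_end = _pulse(np.asarray([window_ms]), rise_tau, decay_tau)[0]
    out = f - f_end * (t_ms / window_ms)
    return np.where((t_ms < 0) | (t_ms >= window_ms), 0.0, out)


def _relaxation_time_ms(rise_tau: float, decay_tau: float, remaining: float) -> float:
    """First time after the peak at which the unit pulse decays to `remaining`."""
    grid = np.arange(0.0, 20.0 * decay_tau, 1.0)
    f = _pulse(grid, rise_tau, decay_tau)
    k = int(np.argmax(f))
    after = np.flatnonzero(f[k:] <= remaining)
    if after.size == 0:
        return float(grid[-1])
    return float(grid[k + after[0]])


def _gen_transient_train(p: TransientGenParams, polarity: int,
                         unit: str, kind: str) -> tuple[Trace, StimulusTrain, TransientGroundTruth]:
    """Shared builder: polarity +1 for upward (Ca, force), -1 for shortening."""
    rng = np.random.default_rng(p.seed)
    period_ms = 1000.0 / p.pacing_hz
    stim = _make_train(p.stim_start_s, p.n_beats, p.pacing_hz)
    duration = p.stim_start_s + p.n_beats / p.pacing_hz
    n = int(round(duration * p.sampling_rate_hz))
    t = np.arange(n) / p.sampling_rate_hz
    y = np.full(n, float(p.baseline_level))

    fail_mask = rng.random(p.n_beats) < p.failure_probability
    sec_mask = rng.random(p.n_beats) < p.secondary_event_probability
    sec_u = rng.random(p.n_beats)   # placement fractions, drawn unconditionally

    # secondary events start after ~90% relaxation of the primary (the
    # detector only requires 70%) so the measured event amplitude is not
    # eroded by the still-decaying primary, and must end before the next
    # stimulus
    t_rel = _relaxation_time_ms(p.rise_tau_ms, p.decay_tau_ms, 0.10)
    sec_support = 3.0 * p.secondary_decay_tau_ms
    u_lo = t_rel + 10.0
    u_hi = max(u_lo + 1.0, period_ms - sec_support)

    amplitudes = np.where(fail_mask, 0.0, p.primary_amplitude)
    events: list[EventTruth] = []

    for k in range(p.n_beats):
        if fail_mask[k]:
            continue
        onset = stim.onset_times_s[k]
        i0 = int(round(onset * p.sampling_rate_hz))
        i1 = min(int(round((onset + 1.0 / p.pacing_hz) * p.sampling_rate_hz)), n)
        tr = (t[i0:i1] - onset) * 1000.0
        seg = p.primary_amplitude * _detrended_pulse(tr, period_ms, p.rise_tau_ms, p.decay_tau_ms)
        if sec_mask[k]:
            u = u_lo + sec_u[k] * (u_hi - u_lo)
            amp2 = p.secondary_amplitude_fraction * p.primary_amplitude
            seg = seg + amp2 * _detrended_pulse(tr - u, period_ms - u,
                                                p.secondary_rise_tau_ms,
                                                p.secondary_decay_tau_ms)
            events.append(EventTruth(k, onset + u / 1000.0, amp2,
                                     p.secondary_amplitude_fraction, "secondary"))
        y[i0:i1] += polarity * seg

    if polarity < 0 and p.primary_amplitude >= p.baseline_level:
        raise ValidationError("shortening amplitude must be below the resting level")
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, n)

    trace = Trace(samples=y, sampling_rate_hz=p.sampling_rate_hz, unit=unit, kind=kind)
    truth = TransientGroundTruth(amplitudes, [int(i) for i in np.flatnonzero(fail_mask)], events)
    return trace, stim, truth


def gen_ca_train(params: TransientGenParams) -> tuple[Trace, StimulusTrain, TransientGroundTruth]:
    """Paced Ca2+ fluorescence transients (upward, arbitrary units)."""
    return _gen_transient_train(params, +1, "AU", "fluorescence")


def gen_sarcomere_train(params: TransientGenParams) -> tuple[Trace, StimulusTrain, TransientGroundTruth]:
    """Paced sarcomere-length traces: downward (shortening) transients in um."""
    if params.primary_amplitude >= params.baseline_level:
        raise ValidationError("shortening amplitude must be below the resting sarcomere length")
    return _gen_transient_train(params, -1, "um", "sarcomere_length")


def gen_force_train(params: TransientGenParams, premature_probability: float = 0.0,
                    automaticity_rate_hz: float = 0.0
                    ) -> tuple[Trace, StimulusTrain, TransientGroundTruth]:
    """Trabecula force cycles with optional premature and automatic activity.

    Premature cycles replace the following stimulus-evoked cycle (refractory
    tissue) and start 300-450 ms before that stimulus.  Automaticity adds
    unstimulated full-amplitude cycles mid-diastole (300-450 ms after a
    stimulus) at the requested Poisson rate; rates that cannot fit a cycle
    between beats are refused.
    """
    p = params
    if not (0 <= premature_probability <= 1):
        raise ValidationError("premature_probability must be in [0, 1]")
    if automaticity_rate_hz < 0:
        raise ValidationError("automaticity_rate_hz must be >= 0")
    period_ms = 1000.0 / p.pacing_hz
    t_star, _ = _pulse_peak(p.rise_tau_ms, p.decay_tau_ms)
    support = t_star + 5.0 * p.decay_tau_ms
    if support >= period_ms:
        raise ValidationError("cycle duration exceeds the pacing period; cycles would overlap")
    if automaticity_rate_hz * (1.0 / p.pacing_hz) > 0.9:
        raise ValidationError("automaticity rate too high: cycles would overlap")

    rng = np.random.default_rng(p.seed)
    stim = _make_train(p.stim_start_s, p.n_beats, p.pacing_hz)
    duration = p.stim_start_s + p.n_beats / p.pacing_hz
    n = int(round(duration * p.sampling_rate_hz))
    t = np.arange(n) / p.sampling_rate_hz
    y = np.full(n, float(p.baseline_level))

    fail_mask = rng.random(p.n_beats) < p.failure_probability
    sec_mask = rng.random(p.n_beats) < p.secondary_event_probability
    sec_u = rng.random(p.n_beats)
    prem_mask = rng.random(p.n_beats) < premature_probability
    prem_lead = rng.uniform(0.300, 0.450, p.n_beats)  # s before the stimulus
    prem_mask[0] = False  # the first beat has no preceding diastole

    n_auto = rng.poisson(automaticity_rate_hz * (p.n_beats / p.pacing_hz))
    auto_slots = rng.choice(p.n_beats, size=min(n_auto, p.n_beats), replace=False) if n_auto else []
    auto_off = rng.uniform(0.300, 0.450, p.n_beats)   # s after the stimulus

    # cycle onset list: (time_s, amplitude, label, beat_index)
    cycles: list[tuple[float, float, str, int]] = []
    for k in range(p.n_beats):
        onset = float(stim.onset_times_s[k])
        if prem_mask[k]:
            cycles.append((onset - prem_lead[k], p.primary_amplitude, "premature", k))
        elif not fail_mask[k]:
            cycles.append((onset, p.primary_amplitude, "locked", k))
    for k in sorted(int(i) for i in np.atleast_1d(auto_slots)):
        if prem_mask[k] or (k + 1 < p.n_beats and prem_mask[k + 1]):
            continue  # keep the diastolic slot clean
        cycles.append((float(stim.onset_times_s[k]) + auto_off[k],
                       p.primary_amplitude, "spontaneous", k))
    cycles.sort()

    t_rel = _relaxation_time_ms(p.rise_tau_ms, p.decay_tau_ms, 0.10)
    amplitudes = np.where(fail_mask | prem_mask, 0.0, p.primary_amplitude)
    events: list[EventTruth] = []

    for onset_s, amp, label, k in cycles:
        win_ms = min(support * 1.2, (duration - onset_s) * 1000.0)
        if win_ms <= 0:
            continue
        i0 = max(int(round(onset_s * p.sampling_rate_hz)), 0)
        i1 = min(int(round((onset_s + win_ms / 1000.0) * p.sampling_rate_hz)), n)
        tr = (t[i0:i1] - onset_s) * 1000.0
        y[i0:i1] += amp * _detrended_pulse(tr, win_ms, p.rise_tau_ms, p.decay_tau_ms)
        if label != "locked":
            events.append(EventTruth(k, onset_s, amp, 1.0, label))
        elif sec_mask[k] and not fail_mask[k]:
            u = t_rel + 10.0 + sec_u[k] * max(1.0, (period_ms - 3.0 * p.secondary_decay_tau_ms)
                                              - (t_rel + 10.0))
            amp2 = p.secondary_amplitude_fraction * amp
            j1 = min(int(round((onset_s + period_ms / 1000.0) * p.sampling_rate_hz)), n)
            tr2 = (t[i0:j1] - onset_s) * 1000.0
            y[i0:j1] += amp2 * _detrended_pulse(tr2 - u, period_ms - u,
                                                p.secondary_rise_tau_ms,
                                                p.secondary_decay_tau_ms)
            events.append(EventTruth(k, onset_s + u / 1000.0, amp2,
                                     p.secondary_amplitude_fraction, "secondary"))

    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, n)

    trace = Trace(samples=y, sampling_rate_hz=p.sampling_rate_hz, unit="g", kind="force")
    truth = TransientGroundTruth(amplitudes, [int(i) for i in np.flatnonzero(fail_mask)], events)
    return trace, stim, truth


# --------------------------------------------------------------------------
# Striation intensity profile
# --------------------------------------------------------------------------

def gen_striation_profile(period_um: float, pixel_um: float, n_pixels: int,
                          noise_sd: float, seed: int) -> Trace:
    """1-D optical-density profile with sinusoidal Z-band periodicity.

    The profile has unit amplitude around an offset of 2 AU; ``noise_sd`` is
    additive white noise in the same units.  Periods at or below two pixels
    violate Nyquist and are refused.
    """
    if period_um <= 2.0 * pixel_um:
        raise ValidationError(
            f"period {period_um:g} um violates Nyquist for pixel size {pixel_um:g} um"
        )
    if n_pixels < 8:
        raise ValidationError("n_pixels too small")
    rng = np.random.default_rng(seed)
    x = np.arange(n_pixels) * pixel_um
    y = 2.0 + np.sin(2.0 * np.pi * x / period_um)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_pixels)
    return Trace(samples=y, sampling_rate_hz=1.0 / pixel_um, unit="AU",
                 kind="intensity_profile")


# --------------------------------------------------------------------------
# Drug effect scaling
# --------------------------------------------------------------------------

@dataclass
class DrugEffectSpec:
    """Phenomenological Hill-type action of a compound on generator parameters.

    At concentration c (uM) the affected parameter is multiplied by
    ``1 + (max_effect_fraction - 1) * occ`` and every ``*_probability`` field
    gains ``event_prob_gain * occ``, with occupancy
    ``occ = c^h / (c^h + ec50^h)``.  At c = 0 the effect is the identity.
    """

    ec50_um: float
    hill_coeff: float = 1.0
    max_effect_fraction: float = 1.0
    affected_parameter: str = "primary_amplitude"
    event_prob_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50_um <= 0 or self.hill_coeff <= 0:
            raise ValidationError("ec50_um and hill_coeff must be > 0")
        if self.event_prob_gain < 0:
            raise ValidationError("event_prob_gain must be >= 0")


def hill_occupancy(c: float, ec50: float, h: float) -> float:
    if c <= 0:
        return 0.0
    return c**h / (c**h + ec50**h)


def apply_drug_effect(spec: DrugEffectSpec, base_params, concentration_um: float):
    """Return a copy of ``base_params`` with the drug effect applied."""
    if concentration_um < 0:
        raise ValidationError("concentration_um must be >= 0")
    if not hasattr(base_params, spec.affected_parameter):
        raise ValidationError(
            f"unknown affected_parameter {spec.affected_parameter!r} "
            f"for {type(base_params).__name__}"
        )
    occ = hill_occupancy(concentration_um, spec.ec50_um, spec.hill_coeff)
    scale = 1.0 + (spec.max_effect_fraction - 1.0) * occ
    changes = {spec.affected_parameter: getattr(base_params, spec.affected_parameter) * scale}
    if spec.event_prob_gain > 0:
        for f in base_params.__dataclass_fields__:
            if f.endswith("_probability"):
                base = changes.get(f, getattr(base_params, f))
                changes[f] = min(1.0, base + spec.event_prob_gain * occ)
    return replace(base_params, **changes)


# --------------------------------------------------------------------------
# Ramp clamp current
# --------------------------------------------------------------------------

@dataclass
class RampCurrentParams:
    """Phenomenological late-Na window current for the voltage-ramp protocol.

    I(V) = gbar * enhancer_scale * a(V - shift) * i(V - shift) * (V - reversal)
    with Boltzmann activation/inactivation gates (nS * mV = pA), plus white
    noise.  Defaults are calibrated so that with a 100 pF cell the inward
    peak sits at 0 mV and its density falls in the 6.5-9.3 pA/pF range.
    """

    gbar_ns: float = 70.0
    reversal_mv: float = 40.0
    act_vhalf_mv: float = -2.5
    act_slope_mv: float = 6.0
    inact_vhalf_mv: float = 0.0
    inact_slope_mv: float = 12.0
    enhancer_scale: float = 1.0
    shift_mv: float = 0.0
    noise_sd_pa: float = 10.0
    capacitance_pf: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gbar_ns < 0 or self.enhancer_scale < 0 or self.noise_sd_pa < 0:
            raise ValidationError("gbar_ns, enhancer_scale and noise_sd_pa must be >= 0")
        if self.capacitance_pf <= 0:
            raise ValidationError("capacitance_pf must be > 0")
        if self.act_slope_mv <= 0 or self.inact_slope_mv <= 0:
            raise ValidationError("Boltzmann slopes must be > 0")


def ramp_current_of_voltage(v_mv: np.ndarray, params: RampCurrentParams) -> np.ndarray:
    """Noiseless current (pA) as a function of command voltage (mV)."""
    p = params
    vv = np.asarray(v_mv, dtype=float) - p.shift_mv
    a = 1.0 / (1.0 + np.exp(-(vv - p.act_vhalf_mv) / p.act_slope_mv))
    i = 1.0 / (1.0 + np.exp((vv - p.inact_vhalf_mv) / p.inact_slope_mv))
    return p.gbar_ns * p.enhancer_scale * a * i * (np.asarray(v_mv, dtype=float) - p.reversal_mv)


def gen_ramp_current(protocol: "late_ina.RampProtocol",
                     params: RampCurrentParams) -> Trace:
    """Synthetic whole-cell current trace aligned to the ramp protocol."""
    _, command = late_ina.build_ramp_protocol(protocol.sampling_rate_hz)
    rng = np.random.default_rng(params.seed)
    current = ramp_current_of_voltage(command.samples, params)
    if params.noise_sd_pa > 0:
        current = current + rng.normal(0.0, params.noise_sd_pa, current.size)
    return Trace(samples=current, sampling_rate_hz=protocol.sampling_rate_hz,
                 unit="pA", kind="current")
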