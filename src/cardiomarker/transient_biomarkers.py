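"""Ca2+-fluorescence and sarcomere-shortening transient analysis.

Covers stimulus-locked segmentation, peak amplitudes (dF/F0 for Ca2+,
percent shortening for sarcomere length), FFT-based sarcomere-length
estimation from striation intensity profiles, five-phase polynomial fits of
the monotonic transient, secondary-event detection (EAD-like Ca2+ events,
aftercontractions), contraction-failure detection and incidence arithmetic.

"Slope change before the next stimulus" is operationalized as a secondary
excursion in the primary direction of at least ``min_fraction`` of the
primary amplitude occurring after the transient has relaxed past
``relaxation_fraction`` of its excursion — an amplitude threshold rather
than a raw derivative sign, which is robust to noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .trace_io import StimulusTrain, Trace


@dataclass(frozen=True)
class TransientSegment:
    """One stimulus-locked window of a fluorescence/length/force trace."""

    samples: np.ndarray
    sampling_rate_hz: float
    baseline_level: float
    peak_level: float
    peak_index: int
    polarity: str  # "up" (Ca2+, force) or "down" (shortening)
    stim_onset_s: float
    next_stim_onset_s: float
    onset_index: int = 0  # index of the stimulus onset within `samples`

    @property
    def amplitude(self) -> float:
        """Polarity-corrected excursion (always >= 0 up to noise)."""
        if self.polarity == "down":
            return self.baseline_level - self.peak_level
        return self.peak_level - self.baseline_level

    def excursion(self) -> np.ndarray:
        """Polarity-corrected samples relative to baseline."""
        if self.polarity == "down":
            return self.baseline_level - self.samples
        return self.samples - self.baseline_level


@dataclass
class TransientFeatures:
    delta_f_over_f0: Optional[float]
    shortening_percent: Optional[float]
    time_to_peak_ms: float
    decay_time_50_ms: Optional[float]


@dataclass
class PhaseFit:
    """Piecewise-polynomial description of one monotonic transient.

    ``boundaries_ms`` are the 4 interior time points (from the stimulus
    onset) splitting the transient into baseline / contraction / peak region
    / relaxation / return-to-baseline; degrees default to (1, 3, 4, 3, 3).
    """

    boundaries_ms: tuple[float, float, float, float]
    coefficients: list[np.ndarray]
    degrees: tuple[int, ...]
    rmse: list[float]
    unfittable: bool = False


@dataclass(frozen=True)
class SecondaryEvent:
    time_s: float
    amplitude: float     # absolute trace units
    fraction: float      # relative to the primary amplitude


@dataclass(frozen=True)
class IncidenceResult:
    n_events: int
    denominator: int
    incidence_percent: float
    unit: str  # "transients" or "cells"


@dataclass
class StriationResult:
    length_um: Optional[float]
    findings: list[str]


def segment_transients(trace: Trace, stim: StimulusTrain, polarity: str,
                       baseline_window_ms: float = 100.0) -> list[TransientSegment]:
    """One segment per stimulus interval, including the pre-onset baseline window.

    Baseline is the mean over ``baseline_window_ms`` before the onset; at the
    20 Hz Ca2+ imaging rate this is the 2 frames preceding the stimulus.
    """
    if polarity not in ("up", "down"):
        raise AnalysisError("polarity must be 'up' or 'down'")
    fs = trace.sampling_rate_hz
    onsets = [t for t in np.asarray(stim.onset_times_s)
              if trace.start_time_s <= t < trace.end_time_s]
    if not onsets:
        raise AnalysisError("no stimulus onsets inside the trace span")
    nb = max(1, int(round(baseline_window_ms / 1000.0 * fs)))
    segments = []
    for k, onset in enumerate(onsets):
        i0 = trace.index_at(onset)
        if k + 1 < len(onsets):
            i1 = trace.index_at(onsets[k + 1])
            next_onset = onsets[k + 1]
        else:
            i1 = trace.n_samples
            next_onset = trace.end_time_s
        b0 = max(0, i0 - nb)
        window = trace.samples[b0:i1]
        onset_index = i0 - b0
        body = window[onset_index:]
        if body.size < 2:
            continue
        baseline = float(np.mean(trace.samples[b0:i0])) if i0 > b0 else float(body[0])
        rel = (baseline - body) if polarity == "down" else (body - baseline)
        peak_in_body = int(np.argmax(rel))
        segments.append(TransientSegment(
            samples=window, sampling_rate_hz=fs, baseline_level=baseline,
            peak_level=float(body[peak_in_body]), peak_index=onset_index + peak_in_body,
            polarity=polarity, stim_onset_s=float(onset),
            next_stim_onset_s=float(next_onset), onset_index=onset_index,
        ))
    return segments


def ca_peak_amplitude(segments: Sequence[TransientSegment], n_avg: int = 10,
                      allow_fewer: bool = False) -> tuple[float, list[float]]:
    """Mean dF/F0 over the last ``n_avg`` transients, plus per-transient values."""
    if len(segments) < n_avg and not allow_fewer:
        raise AnalysisError(f"need >= {n_avg} transients (got {len(segments)}); "
                            "pass allow_fewer=True to override")
    values = []
    for seg in segments[-n_avg:]:
        if seg.baseline_level <= 0:
            raise AnalysisError("F0 must be positive for dF/F0")
        values.append((seg.peak_level - seg.baseline_level) / seg.baseline_level)
    return float(np.mean(values)), values


def shortening_percent(segment: TransientSegment) -> float:
    """Percent sarcomere shortening: 100 * (baseline - peak) / baseline."""
    if segment.baseline_level <= 0:
        raise AnalysisError("resting sarcomere length must be positive")
    return 100.0 * (segment.baseline_level - segment.peak_level) / segment.baseline_level


def sarcomere_length_from_fft(profile: Trace, pixel_um: float,
                              band_um: tuple[float, float] = (1.2, 2.4),
                              pad_factor: int = 8) -> StriationResult:
    """Mean sarcomere length from the striation intensity profile.

    The dominant spatial frequency within ``band_um`` is located on the
    Hann-windowed, zero-padded magnitude spectrum with quadratic peak
    interpolation; the returned length is its reciprocal.  If no in-band
    peak exceeds 3x the spectral median (of the unpadded spectrum), a
    "no striation" finding is returned instead of a length.
    """
    y = profile.samples.astype(float)
    n = y.size
    if n < 64:
        raise AnalysisError("need at least 64 pixels")
    lo_um, hi_um = band_um
    if lo_um <= 2.0 * pixel_um:
        raise AnalysisError("band lower edge violates Nyquist for this pixel size")
    y = y - np.mean(y)
    window = np.hanning(n)

    # detection on the unpadded spectrum: in-band peak vs spectral median
    spec0 = np.abs(np.fft.rfft(y * window))
    freqs0 = np.fft.rfftfreq(n, d=pixel_um)
    band0 = (freqs0 >= 1.0 / hi_um) & (freqs0 <= 1.0 / lo_um)
    median0 = float(np.median(spec0[1:]))
    if not np.any(band0) or float(np.max(spec0[band0])) < 3.0 * median0:
        return StriationResult(None, ["no striation: no in-band spectral peak "
                                      "above 3x the spectral median"])

    npad = n * pad_factor
    spec = np.abs(np.fft.rfft(y * window, n=npad))
    freqs = np.fft.rfftfreq(npad, d=pixel_um)
    band = (freqs >= 1.0 / hi_um) & (freqs <= 1.0 / lo_um)
    k = int(np.flatnonzero(band)[np.argmax(spec[band])])
    if 0 < k < spec.size - 1:  # quadratic interpolation on the magnitude
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    else:
        delta = 0.0
    f_peak = (k + delta) / (npad * pixel_um)
    return StriationResult(float(1.0 / f_peak), [])


def _excursion_crossing(rel: np.ndarray, level: float, start: int,
                        rising: bool) -> Optional[float]:
    """Fractional index where the excursion crosses `level` after `start`."""
    s = rel[start:]
    above = s >= level
    if rising:
        k = np.flatnonzero(above[1:] & ~above[:-1])
    else:
        k = np.flatnonzero(~above[1:] & above[:-1])
    if k.size == 0:
        return None
    i = int(k[0])
    d = s[i + 1] - s[i]
    frac = 0.0 if d == 0 else (level - s[i]) / d
    return start + i + frac


def fit_transient_phases(segment: TransientSegment,
                         degrees: tuple[int, ...] = (1, 3, 4, 3, 3)
                         ) -> tuple[PhaseFit, Optional[TransientFeatures]]:
    """Five-phase polynomial fit of one monotonic transient, plus features.

    Boundaries are placed at the 10% excursion departure, the 90% rising
    crossing, the 90% falling crossing after the peak, and the 10%
    recovery crossing.  A non-monotone landmark sequence (e.g. a failure
    transient) yields an "unfittable" marker.
    """
    amp = segment.amplitude
    fs = segment.sampling_rate_hz
    rel = segment.excursion()
    unfittable = PhaseFit((0, 0, 0, 0), [], degrees, [], unfittable=True)
    if amp <= 0:
        return unfittable, None
    on = segment.onset_index
    peak = segment.peak_index
    b1 = _excursion_crossing(rel, 0.10 * amp, on, rising=True)
    b2 = _excursion_crossing(rel, 0.90 * amp, on, rising=True)
    b3 = _excursion_crossing(rel, 0.90 * amp, peak, rising=False)
    b4 = _excursion_crossing(rel, 0.10 * amp, peak, rising=False)
    if None in (b1, b2, b3, b4) or not (on <= b1 < b2 < b3 < b4):
        return unfittable, None

    t_ms = (np.arange(rel.size) - on) / fs * 1000.0
    bounds_idx = [on, b1, b2, b3, b4, rel.size - 1]
    coeffs, rmses = [], []
    for ph in range(5):
        # only samples strictly inside the phase, so e.g. the flat baseline
        # fit is not polluted by the first rising sample
        j0 = int(math.ceil(bounds_idx[ph]))
        j1 = int(math.floor(bounds_idx[ph + 1])) + 1
        if ph == 0:
            j0 = 0  # phase 1 covers the pre-stimulus baseline window too
        if j1 - j0 < 2:
            j1 = min(j0 + 2, rel.size)
            j0 = max(0, j1 - 2)
        xs, ys = t_ms[j0:j1], segment.samples[j0:j1]
        deg = min(degrees[ph], max(0, xs.size - 1))
        c = np.polyfit(xs, ys, deg)
        coeffs.append(c)
        rmses.append(float(np.sqrt(np.mean((np.polyval(c, xs) - ys) ** 2))))

    fit = PhaseFit(tuple(float((b - on) / fs * 1000.0) for b in (b1, b2, b3, b4)),
                   coeffs, degrees, rmses)

    # features from the fitted peak-region polynomial
    xs_peak = np.linspace(fit.boundaries_ms[1], fit.boundaries_ms[2], 200)
    fitted_peak_curve = np.polyval(coeffs[2], xs_peak)
    if segment.polarity == "down":
        k = int(np.argmin(fitted_peak_curve))
    else:
        k = int(np.argmax(fitted_peak_curve))
    peak_val = float(fitted_peak_curve[k])
    time_to_peak = float(xs_peak[k])
    i50 = _excursion_crossing(rel, 0.50 * amp, peak, rising=False)
    decay50 = None if i50 is None else float((i50 - peak) / fs * 1000.0)
    f0 = segment.baseline_level
    features = TransientFeatures(
        delta_f_over_f0=((peak_val - f0) / f0 if segment.polarity == "up" and f0 > 0 else None),
        shortening_percent=(100.0 * (f0 - peak_val) / f0 if segment.polarity == "down" else None),
        time_to_peak_ms=time_to_peak,
        decay_time_50_ms=decay50,
    )
    return fit, features


def detect_secondary_event(segment: TransientSegment,
                           relaxation_fraction: float = 0.7,
                           min_fraction: float = 0.10,
                           smooth_ms: float = 15.0,
                           reference_amplitude: Optional[float] = None
                           ) -> list[SecondaryEvent]:
    """Secondary excursions after the primary transient has relaxed.

    After recovery passes ``relaxation_fraction`` of the primary excursion,
    any new excursion in the primary direction of at least ``min_fraction``
    of the primary amplitude (ending before the next stimulus) is reported:
    EAD-like event for Ca2+, aftercontraction for sarcomere/force traces.
    ``reference_amplitude`` (absolute units) overrides the segment's own
    amplitude as the normalizer, useful for low-amplitude beats.
    """
    amp = reference_amplitude if reference_amplitude is not None else segment.amplitude
    if amp <= 0:
        return []
    fs = segment.sampling_rate_hz
    rel = segment.excursion()
    nsm = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if nsm > 1:
        from scipy.ndimage import uniform_filter1d
        rel = uniform_filter1d(rel, nsm, mode="nearest")
    peak = segment.peak_index
    recov_level = (1.0 - relaxation_fraction) * amp
    after = np.flatnonzero(rel[peak:] <= recov_level)
    if after.size == 0:
        return []
    start = peak + int(after[0])
    win = rel[start:]
    if win.size < 3:
        return []

    events: list[SecondaryEvent] = []
    i = 1
    while i < win.size - 1:
        if win[i] <= win[i - 1] and win[i] < win[i + 1]:  # local minimum
            j = i + 1
            while j < win.size and win[j] > win[i]:
                j += 1
            seg_max = float(np.max(win[i:j]))
            rise = seg_max - float(win[i])
            if rise >= min_fraction * amp:
                k = i + int(np.argmax(win[i:j]))
                t_event = segment.stim_onset_s + (start + i - segment.onset_index) / fs
                events.append(SecondaryEvent(t_event, rise, rise / amp))
            i = max(j, i + 1)
        else:
            i += 1
    return events


def detect_contraction_failure(segment: TransientSegment, reference_amplitude: float,
                               failure_fraction: float = 0.10,
                               smooth_ms: float = 15.0) -> bool:
    """True iff the segment's excursion is below ``failure_fraction`` of the
    reference (vehicle-baseline median) amplitude.

    The excursion is measured on a lightly smoothed trace so that a flat
    (failed) segment is not promoted above threshold by a single extreme
    noise sample.
    """
    if reference_amplitude <= 0:
        raise AnalysisError("reference amplitude must be positive")
    rel = segment.excursion()
    nsm = max(1, int(round(smooth_ms / 1000.0 * segment.sampling_rate_hz)))
    if nsm > 1:
        from scipy.ndimage import uniform_filter1d
        rel = uniform_filter1d(rel, nsm, mode="nearest")
    amplitude = float(np.max(rel[segment.onset_index:]))
    return amplitude < failure_fraction * reference_amplitude


def event_incidence(flags: Sequence[bool], window: int = 100,
                    unit: str = "transients") -> IncidenceResult:
    """Percentage incidence over the last ``window`` flags.

    ``unit="transients"`` follows the events-per-100-transients rule;
    ``unit="cells"`` counts cells showing events over total cells.
    """
    if unit not in ("transients", "cells"):
        raise AnalysisError("unit must be 'transients' or 'cells'")
    used = list(flags)[-window:]
    if not used:
        raise AnalysisError("empty incidence window")
    n_events = int(sum(bool(f) for f in used))
    return IncidenceResult(n_events, len(used),
                           100.0 * n_events / len(used), unit)


def contraction_condition_summary(segments: Sequence[TransientSegment],
                                  n_avg: int = 15,
                                  reference_mean: Optional[float] = None,
                                  failure_flags: Optional[Sequence[bool]] = None,
                                  exclude_failures: bool = True) -> dict:
    """Mean shortening over the last ``n_avg`` non-failure transients.

    Returns the mean amplitude (absolute units), the mean percent
    shortening, and — when ``reference_mean`` (same absolute units) is
    given — the percent change relative to it.  Failures are excluded from
    the average but remain available for incidence denominators.
    """
    if failure_flags is not None and exclude_failures:
        usable = [s for s, f in zip(segments, failure_flags) if not f]
    else:
        usable = list(segments)
    if len(usable) < n_avg:
        raise AnalysisError(f"need >= {n_avg} non-failure transients (got {len(usable)})")
    last = usable[-n_avg:]
    mean_amp = float(np.mean([s.amplitude for s in last]))
    out = {"mean_amplitude": mean_amp, "n_averaged": n_avg}
    if last[0].polarity == "down":
        out["mean_shortening_percent"] = float(np.mean([shortening_percent(s) for s in last]))
    if reference_mean is not None:
        if reference_mean <= 0:
            raise AnalysisError("reference mean must be positive")
        out["percent_change"] = 100.0 * (mean_amp - reference_mean) / reference_mean
        out["percent_of_control"] = 100.0 * mean_amp / reference_mean
    return out
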