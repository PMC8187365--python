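"""Action-potential biomarkers: APD20/50/90, STV(APD90), Poincare pairs, EADs.

Beats are segmented stimulus-to-stimulus.  Repolarization fractions are
referenced to the amplitude peak - pre-stimulus baseline (the conventional
APD definition), thresholds are crossed with linear interpolation between
samples, and the first downward crossing after the peak wins ties.
Short-term variability follows the Poincare-plot formula
``sum(|APD_{n+1} - APD_n|) / (n_beats * sqrt(2))`` over the most recent
20 s of beats.  An EAD is a net depolarization of at least ``min_rise_mv``
sustained for at least ``min_duration_ms`` between the 20% and 90%
repolarization crossings (phase 2/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .trace_io import StimulusTrain, Trace

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class BeatSegment:
    """One stimulus-locked window of a voltage trace."""

    samples: np.ndarray
    sampling_rate_hz: float
    baseline_mv: float
    peak_mv: float
    peak_index: int
    stim_onset_s: float
    next_stim_onset_s: float


@dataclass
class APDSeries:
    """Per-beat repolarization durations; None marks incomplete repolarization."""

    apd20_ms: list
    apd50_ms: list
    apd90_ms: list

    @property
    def n_beats(self) -> int:
        return len(self.apd90_ms)

    @property
    def incomplete_beats(self) -> list[int]:
        return [i for i, v in enumerate(self.apd90_ms) if v is None]


@dataclass(frozen=True)
class STVResult:
    stv_ms: float
    n_beats: int
    poincare_pairs: np.ndarray  # shape (n-1, 2): (APD_n, APD_{n+1})


@dataclass(frozen=True)
class EADEvent:
    beat_index: int
    time_s: float
    rise_mv: float
    phase_fraction: float


def segment_beats(trace: Trace, stim: StimulusTrain,
                  baseline_window_ms: float = 50.0) -> list[BeatSegment]:
    """One segment per stimulus, spanning onset to the next onset (or end)."""
    fs = trace.sampling_rate_hz
    onsets = [t for t in np.asarray(stim.onset_times_s)
              if trace.start_time_s <= t < trace.end_time_s]
    if not onsets:
        raise AnalysisError("no stimulus onsets inside the trace span")
    segments = []
    nb = max(1, int(round(baseline_window_ms / 1000.0 * fs)))
    for k, onset in enumerate(onsets):
        i0 = trace.index_at(onset)
        next_onset = onsets[k + 1] if k + 1 < len(onsets) else trace.end_time_s
        i1 = trace.index_at(next_onset) if k + 1 < len(onsets) else trace.n_samples
        seg = trace.samples[i0:i1]
        if seg.size < 2:
            continue
        b0 = max(0, i0 - nb)
        baseline = float(np.mean(trace.samples[b0:i0])) if i0 > b0 else float(seg[0])
        peak_index = int(np.argmax(seg))
        segments.append(BeatSegment(
            samples=seg, sampling_rate_hz=fs, baseline_mv=baseline,
            peak_mv=float(seg[peak_index]), peak_index=peak_index,
            stim_onset_s=float(onset), next_stim_onset_s=float(next_onset),
        ))
    return segments


def _cross_down(seg: np.ndarray, start: int, thr: float) -> Optional[float]:
    """Index (fractional) of the first downward crossing of thr at/after start."""
    s = seg[start:]
    below = s < thr
    if s[0] < thr:
        return float(start)
    k = np.flatnonzero(below[1:] & ~below[:-1])
    if k.size == 0:
        return None
    i = int(k[0])
    frac = (s[i] - thr) / (s[i] - s[i + 1])
    return start + i + frac


def _cross_up(seg: np.ndarray, stop: int, thr: float) -> Optional[float]:
    """Index (fractional) of the first upward crossing of thr before stop."""
    s = seg[: stop + 1]
    if s[0] >= thr:
        return 0.0
    above = s >= thr
    k = np.flatnonzero(above[1:] & ~above[:-1])
    if k.size == 0:
        return None
    i = int(k[0])
    frac = (thr - s[i]) / (s[i + 1] - s[i])
    return i + frac


def compute_apd(segment: BeatSegment,
                levels: Sequence[float] = (0.2, 0.5, 0.9)) -> dict[float, Optional[float]]:
    """APD at each repolarization level, in ms; None if the level is never reached.

    Duration runs from the upstroke crossing of ``peak - level*amplitude``
    (or from the peak, if the upstroke never crosses it) to the first
    downward crossing after the peak, linearly interpolated.
    """
    amp = segment.peak_mv - segment.baseline_mv
    if amp <= 0:
        raise AnalysisError("non-positive AP amplitude (peak below baseline)")
    seg = segment.samples
    fs = segment.sampling_rate_hz
    out: dict[float, Optional[float]] = {}
    for level in levels:
        thr = segment.peak_mv - level * amp
        i_up = _cross_up(seg, segment.peak_index, thr)
        if i_up is None:
            i_up = float(segment.peak_index)
        i_down = _cross_down(seg, segment.peak_index, thr)
        out[level] = None if i_down is None else (i_down - i_up) / fs * 1000.0
    return out


def compute_apd_series(segments: Sequence[BeatSegment],
                       levels: Sequence[float] = (0.2, 0.5, 0.9)) -> APDSeries:
    """Run :func:`compute_apd` over all beats and collect per-level series."""
    cols = {lv: [] for lv in levels}
    for seg in segments:
        apds = compute_apd(seg, levels)
        for lv in levels:
            cols[lv].append(apds[lv])
    return APDSeries(apd20_ms=cols.get(0.2, []), apd50_ms=cols.get(0.5, []),
                     apd90_ms=cols.get(0.9, []))


def compute_stv(apd90_series: Sequence[float], window_s: float = 20.0,
                pacing_hz: float = 1.0) -> STVResult:
    """STV(APD90) over the most recent ``window_s * pacing_hz`` beats.

    Beats with absent (None/NaN) APD90 are excluded before windowing; the
    denominator is the number of beats actually used.
    """
    vals = np.asarray([v for v in apd90_series if v is not None and np.isfinite(v)],
                      dtype=float)
    if vals.size < 2:
        raise AnalysisError("STV needs at least 2 beats with finite APD90")
    n_window = max(2, int(round(window_s * pacing_hz)))
    used = vals[-n_window:]
    diffs = np.abs(np.diff(used))
    stv = float(np.sum(diffs) / (used.size * SQRT2))
    pairs = np.column_stack([used[:-1], used[1:]])
    return STVResult(stv_ms=stv, n_beats=int(used.size), poincare_pairs=pairs)


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    from scipy.ndimage import uniform_filter1d
    return uniform_filter1d(x, n, mode="nearest")


def detect_eads(segment: BeatSegment, min_rise_mv: float = 5.0,
                min_duration_ms: float = 10.0, smooth_ms: float = 5.0,
                beat_index: int = 0) -> list[EADEvent]:
    """Depolarizing deflections during phase 2/3 of one beat.

    Scans from the 20%-repolarization crossing to the 90% crossing (or
    segment end).  A local minimum followed by a net depolarization of at
    least ``min_rise_mv`` that keeps the (smoothed) voltage above the
    minimum for at least ``min_duration_ms`` is reported as one event.
    """
    amp = segment.peak_mv - segment.baseline_mv
    if amp <= 0:
        return []
    seg = segment.samples
    fs = segment.sampling_rate_hz
    i20 = _cross_down(seg, segment.peak_index, segment.peak_mv - 0.2 * amp)
    if i20 is None:
        return []
    i90 = _cross_down(seg, segment.peak_index, segment.peak_mv - 0.9 * amp)
    stop = int(i90) if i90 is not None else seg.size - 1
    start = int(math.ceil(i20))
    if stop - start < 3:
        return []

    nsm = max(1, int(round(smooth_ms / 1000.0 * fs)))
    sm = _smooth(seg, nsm)
    win = sm[start: stop + 1]
    events: list[EADEvent] = []
    i = 1
    while i < win.size - 1:
        if win[i] <= win[i - 1] and win[i] < win[i + 1]:  # local minimum
            j = i + 1
            while j < win.size and win[j] > win[i]:
                j += 1
            rise = float(np.max(win[i:j]) - win[i])
            dur_ms = (j - i) / fs * 1000.0
            if rise >= min_rise_mv and dur_ms >= min_duration_ms:
                t_event = segment.stim_onset_s + (start + i) / fs
                phase = float((segment.peak_mv - win[i]) / amp)
                events.append(EADEvent(beat_index, t_event, rise, phase))
            i = max(j, i + 1)
        else:
            i += 1
    return events


def detect_eads_train(segments: Sequence[BeatSegment], **kwargs) -> list[EADEvent]:
    """Run the EAD detector over every beat of a train."""
    events: list[EADEvent] = []
    for k, seg in enumerate(segments):
        events.extend(detect_eads(seg, beat_index=k, **kwargs))
    return events


def condition_summary(apds: APDSeries, reference: Optional[APDSeries] = None,
                      n_avg: int = 20, pacing_hz: float = 1.0,
                      allow_fewer: bool = False) -> dict:
    """Mean of the last ``n_avg`` beats per level, percent change vs reference,
    and the STV(APD90) pair for both series."""

    def _summary(series: APDSeries) -> dict:
        out = {}
        for name, col in (("apd20_ms", series.apd20_ms),
                          ("apd50_ms", series.apd50_ms),
                          ("apd90_ms", series.apd90_ms)):
            vals = [v for v in col if v is not None]
            if len(vals) < n_avg and not allow_fewer:
                raise AnalysisError(
                    f"{name}: {len(vals)} complete beats < n_avg={n_avg} "
                    f"(pass allow_fewer=True to override)"
                )
            out[name] = float(np.mean(vals[-n_avg:])) if vals else float("nan")
        out["stv_ms"] = compute_stv(series.apd90_ms, pacing_hz=pacing_hz).stv_ms
        out["n_incomplete"] = len(series.incomplete_beats)
        return out

    result = {"condition": _summary(apds)}
    if reference is not None:
        ref = _summary(reference)
        result["reference"] = ref
        result["percent_change"] = {
            name: 100.0 * (result["condition"][name] - ref[name]) / ref[name]
            for name in ("apd20_ms", "apd50_ms", "apd90_ms")
        }
    return result
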