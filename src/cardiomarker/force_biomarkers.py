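"""Trabecula contraction/relaxation cycle analysis.

Cycles are excursions above a running local baseline; each is classified as
stimulus-locked (onset within a tolerance of a stimulus), premature (onset
in the window preceding a stimulus) or spontaneous (any other non-locked
onset).  Detected sub-threshold secondary excursions after at least 70%
relaxation of a locked cycle are attached to that cycle as
aftercontractions.  The analysis-window rules reproduce the study design:
either the ``n`` cycles immediately preceding the first aftercontraction
(``pre_first_event``) or the final ``n`` cycles (``end_of_record``).

The premature window defaults to 500 ms: extrasystolic cycles in the
synthetic data couple 300-450 ms before their stimulus, and a window of at
least 450 ms is needed for those onsets to classify as premature rather
than spontaneous.  The cutoff is exposed, not claimed as a measured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError
from .trace_io import StimulusTrain, Trace
from .transient_biomarkers import (IncidenceResult, TransientSegment,
                                   detect_secondary_event, event_incidence)


@dataclass
class ForceCycle:
    onset_time_s: float
    peak_time_s: float
    amplitude_g: float
    stimulus_locked: bool
    associated_stim_index: Optional[int]


@dataclass
class CycleClassification:
    aftercontraction: bool = False
    premature: bool = False
    spontaneous: bool = False


def segment_cycles(trace: Trace, stim: StimulusTrain,
                   lock_tolerance_ms: float = 50.0,
                   premature_window_ms: float = 500.0,
                   onset_fraction: float = 0.05,
                   smooth_ms: float = 5.0,
                   aftercontraction_max_fraction: float = 0.5,
                   relaxation_fraction: float = 0.7,
                   min_event_fraction: float = 0.10
                   ) -> list[tuple[ForceCycle, CycleClassification]]:
    """Detect, measure and classify force cycles on one trabecula trace.

    Candidate peaks smaller than ``aftercontraction_max_fraction`` of the
    running median amplitude that follow >= ``relaxation_fraction``
    relaxation of a locked cycle are folded into that cycle as
    aftercontractions rather than counted as independent cycles.
    """
    fs = trace.sampling_rate_hz
    y = trace.samples.astype(float)
    nsm = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if nsm > 1:
        from scipy.ndimage import uniform_filter1d
        sm = uniform_filter1d(y, nsm, mode="nearest")
    else:
        sm = y
    spread = float(np.percentile(sm, 98) - np.percentile(sm, 2))
    if spread <= 0:
        return []
    min_dist = max(1, int(round(0.2 * stim.period_s * fs)))
    peaks, _ = find_peaks(sm, prominence=0.08 * spread, distance=min_dist)
    if peaks.size == 0:
        return []

    onsets = np.asarray(stim.onset_times_s)
    lock_tol = lock_tolerance_ms / 1000.0
    prem_win = premature_window_ms / 1000.0
    look_back = int(round(0.7 * stim.period_s * fs))

    raw: list[dict] = []
    prev_pk = 0
    for pk in peaks:
        # baseline window reaches back at most to the previous cycle's peak,
        # so cycles riding on an incompletely relaxed predecessor measure
        # their amplitude from the intervening valley, not global diastole
        b0 = max(0, pk - look_back, prev_pk)
        local_base = float(np.min(sm[b0:pk + 1]))
        prev_pk = int(pk)
        amp = float(sm[pk] - local_base)
        if amp <= 0:
            continue
        thr = local_base + onset_fraction * amp
        below = np.flatnonzero(sm[b0:pk] <= thr)
        onset_idx = b0 + int(below[-1]) if below.size else b0
        raw.append({
            "onset_s": trace.start_time_s + onset_idx / fs,
            "peak_s": trace.start_time_s + pk / fs,
            "peak_idx": int(pk), "onset_idx": int(onset_idx),
            "baseline": local_base, "amplitude": amp,
        })
    if not raw:
        return []

    median_amp = float(np.median([c["amplitude"] for c in raw]))

    # split independent cycles from aftercontraction candidates
    cycles: list[dict] = []
    candidates: list[dict] = []
    for c in raw:
        if c["amplitude"] < aftercontraction_max_fraction * median_amp:
            candidates.append(c)
        else:
            cycles.append(c)

    results: list[tuple[ForceCycle, CycleClassification]] = []
    for c in cycles:
        onset_s = c["onset_s"]
        dist = np.abs(onsets - onset_s)
        k = int(np.argmin(dist))
        locked = bool(dist[k] <= lock_tol)
        cls = CycleClassification()
        if not locked:
            ahead = onsets[onsets > onset_s]
            if ahead.size and (ahead[0] - onset_s) <= prem_win:
                cls.premature = True
            else:
                cls.spontaneous = True
        results.append((ForceCycle(onset_s, c["peak_s"], c["amplitude"],
                                   locked, k if locked else None), cls))

    # attach sub-threshold candidates (and detector-level secondary events)
    # to the preceding stimulus-locked cycle as aftercontractions
    for cand in candidates:
        prev = [r for r in results if r[0].stimulus_locked and r[0].peak_time_s < cand["peak_s"]]
        if not prev:
            continue
        parent_cycle, parent_cls = prev[-1]
        # require >= relaxation_fraction recovery before the candidate onset
        i0 = int(round((parent_cycle.peak_time_s - trace.start_time_s) * fs))
        i1 = cand["onset_idx"]
        if i1 <= i0:
            continue
        recovered = float(sm[i0:i1 + 1].min()) - cand["baseline"]
        if recovered <= (1.0 - relaxation_fraction) * parent_cycle.amplitude_g \
                and cand["amplitude"] >= min_event_fraction * parent_cycle.amplitude_g:
            parent_cls.aftercontraction = True

    results.sort(key=lambda rc: rc[0].onset_time_s)
    return results


def cycles_to_segments(trace: Trace, stim: StimulusTrain,
                       baseline_window_ms: float = 100.0) -> list[TransientSegment]:
    """Stimulus-locked force segments (for the shared secondary-event detector)."""
    from .transient_biomarkers import segment_transients
    return segment_transients(trace, stim, polarity="up",
                              baseline_window_ms=baseline_window_ms)


def analysis_window_select(cycles: Sequence[tuple[ForceCycle, CycleClassification]],
                           mode: str, n: int = 30
                           ) -> tuple[list[tuple[ForceCycle, CycleClassification]], list[str]]:
    """Pick the n-cycle analysis window.

    ``pre_first_event``: the n cycles immediately preceding the first
    aftercontraction-bearing cycle (refused if fewer precede it; falls back
    to ``end_of_record`` with a finding when there is no event).
    ``end_of_record``: the final n cycles.
    """
    cycles = list(cycles)
    findings: list[str] = []
    if mode not in ("pre_first_event", "end_of_record"):
        raise AnalysisError("mode must be 'pre_first_event' or 'end_of_record'")
    if mode == "pre_first_event":
        first = next((i for i, (_, cls) in enumerate(cycles) if cls.aftercontraction), None)
        if first is None:
            findings.append("no aftercontraction event; fell back to end_of_record")
            mode = "end_of_record"
        elif first < n:
            raise AnalysisError(
                f"first aftercontraction at cycle {first}: only {first} cycles "
                f"precede it (need {n})"
            )
        else:
            return cycles[first - n: first], findings
    if len(cycles) < n:
        raise AnalysisError(f"only {len(cycles)} cycles available (need {n})")
    return cycles[-n:], findings


def force_condition_summary(selected: Sequence[tuple[ForceCycle, CycleClassification]],
                            reference_mean_g: Optional[float] = None,
                            all_cycles: Optional[Sequence[tuple[ForceCycle, CycleClassification]]] = None,
                            incidence_window: int = 100) -> dict:
    """Mean amplitude of the selected window, percent of control, and the
    aftercontraction incidence over the last ``incidence_window`` cycles."""
    selected = list(selected)
    if not selected:
        raise AnalysisError("empty cycle selection")
    mean_amp = float(np.mean([c.amplitude_g for c, _ in selected]))
    out = {"mean_amplitude_g": mean_amp, "n_cycles": len(selected)}
    if reference_mean_g is not None:
        if reference_mean_g <= 0:
            raise AnalysisError("reference mean must be positive")
        out["percent_of_control"] = 100.0 * mean_amp / reference_mean_g
    pool = list(all_cycles) if all_cycles is not None else selected
    flags = [cls.aftercontraction for _, cls in pool]
    inc = event_incidence(flags, window=incidence_window, unit="transients")
    out["aftercontraction_incidence_percent"] = inc.incidence_percent
    out["aftercontraction_count"] = inc.n_events
    out["spontaneous_rate_per_min"] = _spontaneous_rate(pool)
    return out


def _spontaneous_rate(cycles: Sequence[tuple[ForceCycle, CycleClassification]]) -> float:
    """Spontaneous (automatic) cycle rate in cycles/min over the record span."""
    if not cycles:
        return 0.0
    t0 = min(c.onset_time_s for c, _ in cycles)
    t1 = max(c.onset_time_s for c, _ in cycles)
    span_min = max((t1 - t0) / 60.0, 1e-9)
    n_spont = sum(1 for _, cls in cycles if cls.spontaneous)
    return n_spont / span_min
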