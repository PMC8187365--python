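"""Reading, writing and validation of recorded traces.

A recording is stored as a two-column CSV (``time_s,value``) next to a flat
JSON sidecar (same basename, ``.json`` extension) that carries the sampling
rate, signal unit and kind, the pacing schedule, and the recording metadata
(assay, condition label, drug concentration, cell capacitance, cell/heart
identifiers).  All times on disk are in seconds; milliseconds appear only in
reported biomarkers.

Floats are serialized with :func:`repr` (shortest round-trip representation,
well above 9 significant digits), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: canonical signal units (ASCII "um" stands for micrometre; "µm" is accepted
#: as an alias when reading sidecars)
UNITS = ("mV", "pA", "AU", "um", "g")
_UNIT_ALIASES = {"µm": "um", "μm": "um"}

KINDS = (
    "voltage",
    "current",
    "fluorescence",
    "sarcomere_length",
    "force",
    "intensity_profile",
)

ASSAYS = ("ap", "calcium", "contractility", "force", "clamp")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled, unit-annotated signal.

    For ``kind="intensity_profile"`` the "time" axis is a spatial axis along
    the myocyte and ``sampling_rate_hz`` is pixels per micrometre.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    unit: str
    kind: str
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("Trace.samples must be a non-empty 1-D sequence")
        if not (self.sampling_rate_hz > 0) or not math.isfinite(self.sampling_rate_hz):
            raise ValidationError("sampling_rate_hz must be a positive finite number")
        unit = _UNIT_ALIASES.get(self.unit, self.unit)
        object.__setattr__(self, "unit", unit)
        if unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if not (self.start_time_s >= 0) or not math.isfinite(self.start_time_s):
            raise ValidationError("start_time_s must be a finite number >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times in seconds (or micrometres for intensity profiles)."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def index_at(self, time_s: float) -> int:
        """Index of the first sample at or after ``time_s`` (clipped)."""
        i = math.ceil((time_s - self.start_time_s) * self.sampling_rate_hz - 1e-9)
        return int(min(max(i, 0), self.n_samples - 1))


@dataclass(frozen=True)
class StimulusTrain:
    """Pacing schedule: stimulus onset times plus nominal period and width."""

    onset_times_s: np.ndarray
    period_s: float
    pulse_width_ms: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.onset_times_s, dtype=float)
        object.__setattr__(self, "onset_times_s", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("onset_times_s must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("onset_times_s must be finite")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValidationError("onset_times_s must be strictly increasing")
        if not (self.period_s > 0):
            raise ValidationError("period_s must be > 0")
        if not (self.pulse_width_ms > 0):
            raise ValidationError("pulse_width_ms must be > 0")

    @property
    def n_stimuli(self) -> int:
        return int(self.onset_times_s.size)


@dataclass(frozen=True)
class RecordingMeta:
    """Assay-level metadata attached to one recording."""

    assay: str
    condition_label: str = ""
    concentration_um: Optional[float] = None
    capacitance_pf: Optional[float] = None
    cell_id: str = ""
    heart_id: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.concentration_um is not None and not (self.concentration_um >= 0):
            raise ValidationError("concentration_um must be >= 0")
        if self.capacitance_pf is not None and not (self.capacitance_pf > 0):
            raise ValidationError("capacitance_pf must be > 0")
        if self.assay == "clamp" and self.capacitance_pf is None:
            raise ValidationError(
                "capacitance_pf is required for clamp recordings (pA/pF normalization)"
            )


@dataclass(frozen=True)
class Finding:
    """One validation finding: a code, a human message, an optional index."""

    code: str
    message: str
    index: Optional[int] = None


def validate_trace(trace: Trace, stim: StimulusTrain) -> list[Finding]:
    """Check trace/stimulus invariants; return findings instead of raising.

    Empty list means every invariant holds and every stimulus onset lies
    inside the trace time span.
    """
    findings: list[Finding] = []
    bad = np.flatnonzero(~np.isfinite(trace.samples))
    for i in bad[:20]:  # cap the list; one finding per bad sample
        findings.append(
            Finding("non_finite_sample", f"non-finite sample at index {int(i)}", int(i))
        )
    if bad.size > 20:
        findings.append(
            Finding("non_finite_sample", f"... and {bad.size - 20} more non-finite samples")
        )
    t0, t1 = trace.start_time_s, trace.end_time_s
    for k, onset in enumerate(np.asarray(stim.onset_times_s)):
        if not (t0 <= onset <= t1):
            findings.append(
                Finding(
                    "stimulus_outside_trace",
                    f"stimulus {k} at {onset:g} s outside trace span [{t0:g}, {t1:g}] s",
                    k,
                )
            )
    if stim.n_stimuli > 1:
        diffs = np.diff(stim.onset_times_s)
        tol = 1.0 / trace.sampling_rate_hz
        irregular = np.flatnonzero(np.abs(diffs - stim.period_s) > tol)
        for k in irregular[:5]:
            findings.append(
                Finding(
                    "irregular_train",
                    f"inter-stimulus interval {diffs[k]:g} s deviates from period "
                    f"{stim.period_s:g} s by more than one sample period",
                    int(k),
                )
            )
    return findings


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: Trace, stim: StimulusTrain, meta: RecordingMeta, path) -> Path:
    """Write the CSV data file and its JSON sidecar; return the data path."""
    path = Path(path)
    times = trace.times()
    lines = ["time_s,value"]
    lines.extend(f"{t!r},{v!r}" for t, v in zip(times.tolist(), trace.samples.tolist()))
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "unit": trace.unit,
        "kind": trace.kind,
        "start_time_s": trace.start_time_s,
        "onset_times_s": [float(x) for x in np.asarray(stim.onset_times_s)],
        "period_s": stim.period_s,
        "pulse_width_ms": stim.pulse_width_ms,
        "assay": meta.assay,
        "condition_label": meta.condition_label,
        "cell_id": meta.cell_id,
        "heart_id": meta.heart_id,
    }
    if meta.concentration_um is not None:
        sidecar["concentration_um"] = meta.concentration_um
    if meta.capacitance_pf is not None:
        sidecar["capacitance_pf"] = meta.capacitance_pf
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=2) + "\n")
    return path


def read_trace(path) -> tuple[Trace, StimulusTrain, RecordingMeta]:
    """Read a data file + sidecar and return validated objects.

    Raises :class:`FormatError` for a missing sidecar, a bad header or a
    non-monotone time column, and :class:`ValidationError` for NaN samples
    (naming the row) or metadata invariant violations.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"data file not found: {path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing metadata sidecar: {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"sidecar is not valid JSON: {e}") from e

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "value"]:
        raise FormatError(f"expected header 'time_s,value', got {list(df.columns)}")
    if df.shape[0] == 0:
        raise FormatError("data file has no rows")

    times = df["time_s"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise FormatError("time column must be finite and strictly increasing")

    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValidationError(f"non-finite sample at row index {int(bad[0])}")

    try:
        rate = float(sidecar["sampling_rate_hz"])
        trace = Trace(
            samples=values,
            sampling_rate_hz=rate,
            unit=str(sidecar["unit"]),
            kind=str(sidecar["kind"]),
            start_time_s=float(sidecar.get("start_time_s", 0.0)),
        )
        stim = StimulusTrain(
            onset_times_s=np.asarray(sidecar["onset_times_s"], dtype=float),
            period_s=float(sidecar["period_s"]),
            pulse_width_ms=float(sidecar["pulse_width_ms"]),
        )
        meta = RecordingMeta(
            assay=str(sidecar["assay"]),
            condition_label=str(sidecar.get("condition_label", "")),
            concentration_um=(
                float(sidecar["concentration_um"]) if "concentration_um" in sidecar else None
            ),
            capacitance_pf=(
                float(sidecar["capacitance_pf"]) if "capacitance_pf" in sidecar else None
            ),
            cell_id=str(sidecar.get("cell_id", "")),
            heart_id=str(sidecar.get("heart_id", "")),
        )
    except KeyError as e:
        raise FormatError(f"sidecar missing required key: {e}") from e

    # implicit time check: row times must match start + i/rate
    expected = trace.times()
    max_dev = float(np.max(np.abs(times - expected)))
    if max_dev > 0.25 / rate:
        raise FormatError(
            f"time column deviates from sampling grid by {max_dev:g} s "
            f"(> 0.25 sample period)"
        )
    return trace, stim, meta
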