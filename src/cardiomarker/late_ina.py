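"""Voltage-ramp protocol for late Na+ current and ramp I-V extraction.

The command waveform holds at -80 mV (50 ms), hyperpolarizes to -95 mV
(200 ms), steps to -20 mV (50 ms) to activate and inactivate the fast Na+
current, steps to +40 mV (200 ms) to inactivate the Ca2+ current, and then
ramps linearly from +40 to -95 mV over 100 ms; sweeps repeat every 10 s.
The ramp segment mimics action-potential repolarization, and the current it
elicits, normalized to cell capacitance, is reported as a current-voltage
relationship in pA/pF.  The inward peak is the signed minimum of the binned
density; reporting layers may take its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ValidationError
from .trace_io import Trace


@dataclass(frozen=True)
class RampProtocol:
    hold_mv: float = -80.0
    hold_ms: float = 50.0
    hyper_mv: float = -95.0
    hyper_ms: float = 200.0
    pre_mv: float = -20.0
    pre_ms: float = 50.0
    depol_mv: float = 40.0
    depol_ms: float = 200.0
    ramp_start_mv: float = 40.0
    ramp_end_mv: float = -95.0
    ramp_ms: float = 100.0
    inter_sweep_s: float = 10.0
    sampling_rate_hz: float = 10_000.0

    @property
    def total_ms(self) -> float:
        return self.hold_ms + self.hyper_ms + self.pre_ms + self.depol_ms + self.ramp_ms

    @property
    def ramp_start_s(self) -> float:
        return (self.hold_ms + self.hyper_ms + self.pre_ms + self.depol_ms) / 1000.0

    @property
    def ramp_end_s(self) -> float:
        return self.ramp_start_s + self.ramp_ms / 1000.0

    def voltage_at(self, t_s):
        """Command voltage (mV) at time(s) t_s from sweep start."""
        t = np.asarray(t_s, dtype=float)
        edges_ms = np.cumsum([self.hold_ms, self.hyper_ms, self.pre_ms, self.depol_ms])
        t_ms = t * 1000.0
        ramp = self.ramp_start_mv + (self.ramp_end_mv - self.ramp_start_mv) * (
            (t_ms - edges_ms[3]) / self.ramp_ms
        )
        v = np.select(
            [t_ms < edges_ms[0], t_ms < edges_ms[1], t_ms < edges_ms[2],
             t_ms < edges_ms[3], t_ms < edges_ms[3] + self.ramp_ms],
            [self.hold_mv, self.hyper_mv, self.pre_mv, self.depol_mv, ramp],
            default=self.ramp_end_mv,
        )
        return v if v.shape else float(v)

    def time_of_ramp_voltage(self, v_mv):
        """Invert the affine ramp law: time (s) at which the ramp passes v_mv."""
        v = np.asarray(v_mv, dtype=float)
        frac = (v - self.ramp_start_mv) / (self.ramp_end_mv - self.ramp_start_mv)
        t = self.ramp_start_s + frac * self.ramp_ms / 1000.0
        return t if t.shape else float(t)


@dataclass(frozen=True)
class IVCurve:
    """Capacitance-normalized ramp I-V on a descending 1 mV grid."""

    voltage_mv: np.ndarray
    density_pa_per_pf: np.ndarray
    peak_voltage_mv: float
    peak_density_pa_per_pf: float


def build_ramp_protocol(sampling_rate_hz: float) -> tuple[RampProtocol, Trace]:
    """Return the protocol and its sampled command waveform (600 ms)."""
    if sampling_rate_hz < 1000:
        raise ValidationError("sampling_rate_hz must be >= 1000 for the ramp protocol")
    protocol = RampProtocol(sampling_rate_hz=sampling_rate_hz)
    n = int(round(protocol.total_ms / 1000.0 * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    command = Trace(samples=protocol.voltage_at(t), sampling_rate_hz=sampling_rate_hz,
                    unit="mV", kind="voltage")
    return protocol, command


def extract_ramp_iv(current: Trace, protocol: RampProtocol, capacitance_pf: float,
                    n_bins: int = 136) -> IVCurve:
    """Bin the ramp-segment current by command voltage and normalize to pA/pF.

    Samples on the ramp are mapped to voltage by the affine time->voltage
    law, averaged within 1 mV bins centred on integer millivolts from
    ramp_start down to ramp_end (136 bins by default), and divided by the
    cell capacitance.  Empty bins (possible at low sampling rates) are
    filled by linear interpolation from their neighbours.
    """
    if capacitance_pf <= 0:
        raise AnalysisError("capacitance must be > 0")
    fs = current.sampling_rate_hz
    n_needed = int(round(protocol.total_ms / 1000.0 * fs))
    if current.n_samples < n_needed:
        raise AnalysisError(
            f"current trace ({current.n_samples} samples) shorter than the "
            f"protocol ({n_needed} samples)"
        )
    i0 = int(round(protocol.ramp_start_s * fs))
    i1 = int(round(protocol.ramp_end_s * fs))
    t = np.arange(i0, i1) / fs
    v = np.asarray(protocol.voltage_at(t))
    y = current.samples[i0:i1] / capacitance_pf

    grid = np.linspace(protocol.ramp_start_mv, protocol.ramp_end_mv, n_bins)
    step = abs(grid[1] - grid[0])
    # assign each ramp sample to its nearest grid voltage
    idx = np.rint((grid[0] - v) / step).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    density = np.full(n_bins, np.nan)
    filled = counts > 0
    density[filled] = sums[filled] / counts[filled]
    if not np.all(filled):
        density[~filled] = np.interp(grid[~filled][::-1], grid[filled][::-1],
                                     density[filled][::-1])[::-1]

    k = int(np.argmin(density))
    return IVCurve(voltage_mv=grid, density_pa_per_pf=density,
                   peak_voltage_mv=float(grid[k]),
                   peak_density_pa_per_pf=float(density[k]))


def compare_iv(a: IVCurve, b: IVCurve) -> dict:
    """Peak shift (mV) and signed peak-density ratio between two I-V curves."""
    if a.voltage_mv.shape != b.voltage_mv.shape or not np.allclose(a.voltage_mv, b.voltage_mv):
        raise AnalysisError("I-V curves must share the same voltage grid")
    return {
        "peak_shift_mv": b.peak_voltage_mv - a.peak_voltage_mv,
        "peak_density_ratio": b.peak_density_pa_per_pf / a.peak_density_pa_per_pf,
    }
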