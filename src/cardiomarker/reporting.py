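"""Condition statistics and the end-to-end pipeline driver.

Two-condition comparisons use Student's t-test (paired or unpaired);
three or more conditions use one-way ANOVA followed by Bonferroni-adjusted
pairwise t contrasts (adjusted p = min(1, m*p) for m contrasts).
Significance is flagged at alpha = 0.05.

:func:`run_pipeline` reproduces the study's comparison structure (vehicle ->
challenge -> challenge + inhibitor) on synthetic recordings: for each assay
it generates per-cell traces from the condition's generator parameters,
runs the relevant analyzer, assembles condition summaries, percent changes
vs the reference condition, event incidences and paired statistics, and
writes a machine-readable JSON report plus per-assay CSV tables.  With a
fixed seed the whole report bundle is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ap_biomarkers, force_biomarkers, late_ina, synthetic, transient_biomarkers
from .errors import AnalysisError

ALPHA = 0.05


@dataclass
class Contrast:
    labels: tuple[str, str]
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


@dataclass
class ConditionComparison:
    labels: list[str]
    test: str
    contrasts: list[Contrast]
    anova_f: Optional[float] = None
    anova_p: Optional[float] = None
    alpha: float = ALPHA


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    m = len(p_values)
    return [min(1.0, m * p) for p in p_values]


def _t_contrast(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, float]:
    if paired:
        if a.size != b.size:
            raise AnalysisError("paired contrast needs equal-length matched sequences")
        d = a - b
        if np.allclose(d, 0):
            return 0.0, 1.0  # identical pairs: no effect by definition
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    if not np.isfinite(t):
        return 0.0, 1.0
    return float(t), float(p)


def compare_conditions(values_by_condition: dict[str, Sequence[float]],
                       design: str = "paired",
                       contrasts: Optional[Sequence[tuple[str, str]]] = None
                       ) -> ConditionComparison:
    """t-test for two conditions; one-way ANOVA + Bonferroni pairwise for more."""
    if design not in ("paired", "unpaired"):
        raise AnalysisError("design must be 'paired' or 'unpaired'")
    labels = list(values_by_condition)
    if len(labels) < 2:
        raise AnalysisError("need at least 2 conditions")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise AnalysisError(f"condition {k!r} needs n >= 2")
    paired = design == "paired"
    if paired and len({v.size for v in arrays.values()}) != 1:
        raise AnalysisError("paired design needs equal-length matched sequences")

    if contrasts is None:
        if len(labels) == 2:
            contrasts = [(labels[0], labels[1])]
        else:
            contrasts = [(labels[i], labels[j])
                         for i in range(len(labels)) for j in range(i + 1, len(labels))]

    raw = [_t_contrast(arrays[a], arrays[b], paired) for a, b in contrasts]
    if len(labels) == 2:
        adj = [p for _, p in raw]
        test = "paired_t" if paired else "unpaired_t"
        anova_f = anova_p = None
    else:
        adj = bonferroni([p for _, p in raw])
        test = "anova_bonferroni"
        f, p_a = stats.f_oneway(*arrays.values())
        anova_f, anova_p = float(f), float(p_a)

    out = [Contrast(tuple(c), t, p, pa, pa < ALPHA)
           for c, (t, p), pa in zip(contrasts, raw, adj)]
    return ConditionComparison(labels, test, out, anova_f, anova_p)


# --------------------------------------------------------------------------
# Pipeline driver
# --------------------------------------------------------------------------

def _derive_seed(base: int, *indices: int) -> int:
    s = int(base)
    for k in indices:
        s = (s * 1_000_003 + 7919 * (int(k) + 1)) % (2**31 - 1)
    return s


def _analyze_ap_cell(params: synthetic.APGenParams) -> dict:
    trace, stim, _ = synthetic.gen_ap_train(params)
    segs = ap_biomarkers.segment_beats(trace, stim)
    series = ap_biomarkers.compute_apd_series(segs)
    stv = ap_biomarkers.compute_stv(series.apd90_ms, pacing_hz=params.pacing_hz)
    events = ap_biomarkers.detect_eads_train(segs)
    vals90 = [v for v in series.apd90_ms if v is not None]
    vals50 = [v for v in series.apd50_ms if v is not None]
    vals20 = [v for v in series.apd20_ms if v is not None]
    n_avg = min(20, len(vals90))
    return {
        "apd20_ms": float(np.mean(vals20[-n_avg:])),
        "apd50_ms": float(np.mean(vals50[-n_avg:])),
        "apd90_ms": float(np.mean(vals90[-n_avg:])),
        "stv_ms": stv.stv_ms,
        "ead_count": len(events),
        "has_ead": len(events) > 0,
    }


def _analyze_ca_cell(params: synthetic.TransientGenParams) -> dict:
    trace, stim, _ = synthetic.gen_ca_train(params)
    segs = transient_biomarkers.segment_transients(trace, stim, polarity="up")
    mean_dff, _ = transient_biomarkers.ca_peak_amplitude(segs, allow_fewer=True,
                                                         n_avg=min(10, len(segs)))
    n_events = sum(bool(transient_biomarkers.detect_secondary_event(s)) for s in segs)
    return {"delta_f_over_f0": mean_dff, "event_transients": n_events,
            "has_event": n_events > 0, "n_transients": len(segs)}


def _analyze_contractility_cell(params: synthetic.TransientGenParams) -> dict:
    trace, stim, _ = synthetic.gen_sarcomere_train(params)
    segs = transient_biomarkers.segment_transients(trace, stim, polarity="down")
    amps = [s.amplitude for s in segs]
    ref_amp = float(np.median(amps))
    failures = [transient_biomarkers.detect_contraction_failure(s, ref_amp) for s in segs]
    events = [bool(transient_biomarkers.detect_secondary_event(s)) and not f
              for s, f in zip(segs, failures)]
    n_avg = min(15, sum(1 for f in failures if not f))
    summary = transient_biomarkers.contraction_condition_summary(
        segs, n_avg=max(1, n_avg), failure_flags=failures)
    inc_after = transient_biomarkers.event_incidence(events, window=100)
    inc_fail = transient_biomarkers.event_incidence(failures, window=100)
    return {
        "mean_shortening_percent": summary.get("mean_shortening_percent"),
        "mean_amplitude_um": summary["mean_amplitude"],
        "aftercontraction_incidence_percent": inc_after.incidence_percent,
        "failure_incidence_percent": inc_fail.incidence_percent,
        "has_event": inc_after.n_events > 0,
    }


def _analyze_force_cell(params: synthetic.TransientGenParams,
                        premature_probability: float = 0.0,
                        automaticity_rate_hz: float = 0.0) -> dict:
    trace, stim, _ = synthetic.gen_force_train(params, premature_probability,
                                               automaticity_rate_hz)
    cycles = force_biomarkers.segment_cycles(trace, stim)
    selected, _ = force_biomarkers.analysis_window_select(
        cycles, mode="end_of_record", n=min(30, len(cycles)))
    summary = force_biomarkers.force_condition_summary(selected, all_cycles=cycles)
    return {
        "mean_amplitude_g": summary["mean_amplitude_g"],
        "aftercontraction_incidence_percent": summary["aftercontraction_incidence_percent"],
        "spontaneous_rate_per_min": summary["spontaneous_rate_per_min"],
        "n_cycles": len(cycles),
    }


def _analyze_clamp_cell(params: synthetic.RampCurrentParams,
                        sampling_rate_hz: float = 10_000.0) -> dict:
    protocol, _ = late_ina.build_ramp_protocol(sampling_rate_hz)
    current = synthetic.gen_ramp_current(protocol, params)
    iv = late_ina.extract_ramp_iv(current, protocol, params.capacitance_pf)
    return {"peak_voltage_mv": iv.peak_voltage_mv,
            "peak_density_pa_per_pf": iv.peak_density_pa_per_pf}


_PARAM_TYPES = {
    "ap": synthetic.APGenParams,
    "calcium": synthetic.TransientGenParams,
    "contractility": synthetic.TransientGenParams,
    "force": synthetic.TransientGenParams,
    "clamp": synthetic.RampCurrentParams,
}

_FACTORIES = {
    "calcium": synthetic.ca_params,
    "contractility": synthetic.sarcomere_params,
    "force": synthetic.force_params,
}

_PRIMARY_METRIC = {
    "ap": "apd90_ms",
    "calcium": "delta_f_over_f0",
    "contractility": "mean_shortening_percent",
    "force": "mean_amplitude_g",
    "clamp": "peak_density_pa_per_pf",
}


def _analyze_cell(assay: str, params, cond_cfg: dict) -> dict:
    if assay == "ap":
        return _analyze_ap_cell(params)
    if assay == "calcium":
        return _analyze_ca_cell(params)
    if assay == "contractility":
        return _analyze_contractility_cell(params)
    if assay == "force":
        return _analyze_force_cell(params,
                                   cond_cfg.get("premature_probability", 0.0),
                                   cond_cfg.get("automaticity_rate_hz", 0.0))
    if assay == "clamp":
        return _analyze_clamp_cell(params)
    raise AnalysisError(f"unknown assay {assay!r}")


def run_pipeline(config: dict, out_dir: Optional[Path] = None) -> dict:
    """Run every configured assay and assemble the report bundle.

    Config layout::

        {"seed": 1,
         "assays": {"ap": {"n_cells": 6, "reference": "vehicle",
                           "conditions": [{"label": "vehicle", "params": {...}},
                                          {"label": "atx_ii",  "params": {...}}]},
                    ...}}

    ``params`` are keyword overrides of the assay's generator defaults; the
    per-cell seed is derived deterministically from the base seed, so the
    report is byte-identical across reruns with the same config.
    """
    if not config or not config.get("assays"):
        raise AnalysisError("empty pipeline config: no assays given")
    base_seed = int(config.get("seed", 0))
    report: dict = {"seed": base_seed, "assays": {}}
    tables: dict[str, pd.DataFrame] = {}

    for a_idx, (assay, acfg) in enumerate(sorted(config["assays"].items())):
        if assay not in _PARAM_TYPES:
            raise AnalysisError(f"unknown assay {assay!r}")
        conditions = acfg.get("conditions", [])
        if not conditions:
            raise AnalysisError(f"assay {assay!r} has no conditions")
        n_cells = int(acfg.get("n_cells", 6))
        reference = acfg.get("reference")
        rows = []
        for c_idx, cond in enumerate(conditions):
            label = cond["label"]
            for cell in range(n_cells):
                seed = _derive_seed(base_seed, a_idx, c_idx, cell)
                overrides = dict(cond.get("params", {}))
                overrides["seed"] = seed
                if assay in _FACTORIES:
                    params = _FACTORIES[assay](**overrides)
                else:
                    params = _PARAM_TYPES[assay](**overrides)
                row = {"condition": label, "cell": cell, "seed": seed}
                row.update(_analyze_cell(assay, params, cond))
                rows.append(row)
        df = pd.DataFrame(rows)
        tables[assay] = df

        metric = _PRIMARY_METRIC[assay]
        summary: dict = {"metric": metric, "conditions": {}}
        values_by_cond: dict[str, np.ndarray] = {}
        for cond in conditions:
            label = cond["label"]
            sub = df[df["condition"] == label]
            vals = sub[metric].to_numpy(dtype=float)
            values_by_cond[label] = vals
            entry = {"mean": float(np.mean(vals)),
                     "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                     "n": int(len(vals))}
            for extra in ("ead_count", "has_ead", "has_event",
                          "aftercontraction_incidence_percent",
                          "failure_incidence_percent", "stv_ms",
                          "spontaneous_rate_per_min", "peak_voltage_mv"):
                if extra in sub.columns:
                    col = sub[extra]
                    if col.dtype == bool:
                        entry[f"{extra}_cells"] = int(col.sum())
                        entry[f"{extra}_incidence_percent"] = 100.0 * float(col.mean())
                    else:
                        entry[f"{extra}_mean"] = float(col.mean())
            summary["conditions"][label] = entry
        if reference is not None and reference in values_by_cond:
            ref_mean = float(np.mean(values_by_cond[reference]))
            for label, vals in values_by_cond.items():
                if ref_mean != 0:
                    summary["conditions"][label]["percent_change_vs_reference"] = (
                        100.0 * (float(np.mean(vals)) - ref_mean) / ref_mean)
        if len(values_by_cond) >= 2:
            comparison = compare_conditions(values_by_cond, design="paired")
            summary["statistics"] = {
                "test": comparison.test,
                "anova_f": comparison.anova_f,
                "anova_p": comparison.anova_p,
                "contrasts": [dataclasses.asdict(c) for c in comparison.contrasts],
            }
        report["assays"][assay] = summary

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2, default=_json_default) + "\n")
        for assay, df in tables.items():
            df.to_csv(out_dir / f"{assay}_cells.csv", index=False)
    report["_tables"] = tables
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
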