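#!/usr/bin/env python
"""Simulate the demo recording set and archive it in the trace file format.

Writes one seeded synthetic recording per assay/condition (AP train, ramp
clamp current, sarcomere shortening) to scratch/demo_recordings/ as
CSV + JSON sidecars, together with the generator ground truth.  Later
scripts regenerate the same traces in memory from analysis/common.py, so
this step is about exercising and demonstrating the on-disk format, not a
prerequisite.
"""

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from cardiomarker import late_ina, synthetic as syn, trace_io as tio
import common


def np_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def main() -> None:
    out = common.SCRATCH / "demo_recordings"
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for c_idx, cond in enumerate(common.AP_CONDITIONS):
        params = syn.APGenParams(**cond["params"], seed=common.seed_for(0, c_idx))
        trace, stim, truth = syn.gen_ap_train(params)
        meta = tio.RecordingMeta(assay="ap", condition_label=cond["label"],
                                 cell_id="cell01", heart_id="demo")
        path = tio.write_trace(trace, stim, meta, out / f"ap_{cond['label']}.csv")
        (out / f"ap_{cond['label']}_truth.json").write_text(
            json.dumps(dataclasses.asdict(truth), default=np_default) + "\n")
        written.append(path.name)

    protocol, _ = late_ina.build_ramp_protocol(10_000.0)
    stim = tio.StimulusTrain(onset_times_s=[0.0], period_s=protocol.inter_sweep_s,
                             pulse_width_ms=protocol.total_ms)
    for c_idx, cond in enumerate(common.CLAMP_CONDITIONS):
        params = syn.RampCurrentParams(**cond["params"], seed=common.seed_for(1, c_idx))
        trace = syn.gen_ramp_current(protocol, params)
        meta = tio.RecordingMeta(assay="clamp", condition_label=cond["label"],
                                 capacitance_pf=params.capacitance_pf,
                                 cell_id="cell01", heart_id="demo")
        path = tio.write_trace(trace, stim, meta, out / f"clamp_{cond['label']}.csv")
        written.append(path.name)

    for c_idx, cond in enumerate(common.CONTRACTILITY_CONDITIONS):
        params = syn.sarcomere_params(**cond["params"], seed=common.seed_for(2, c_idx))
        trace, stim, truth = syn.gen_sarcomere_train(params)
        meta = tio.RecordingMeta(assay="contractility", condition_label=cond["label"],
                                 cell_id="cell01", heart_id="demo")
        path = tio.write_trace(trace, stim, meta, out / f"sarc_{cond['label']}.csv")
        written.append(path.name)

    # round-trip audit: every archived file reads back identically
    for name in written:
        trace, stim, meta = tio.read_trace(out / name)
        assert not tio.validate_trace(trace, stim)
    print(f"wrote and re-validated {len(written)} recordings under {out}")


if __name__ == "__main__":
    main()
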