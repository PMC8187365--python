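#!/usr/bin/env python
"""End-to-end pipeline run over the demo AP + contractility study.

Drives reporting.run_pipeline on the shared three-arm configuration and
writes the machine-readable report bundle to results/report/ (JSON report
plus one per-cell CSV per assay).  Rerunning with the same seed reproduces
the bundle byte for byte.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from cardiomarker import reporting
import common


def main() -> None:
    config = {
        "seed": common.BASE_SEED,
        "assays": {
            "ap": {"n_cells": 6, "reference": "vehicle",
                   "conditions": common.AP_CONDITIONS},
            "contractility": {"n_cells": 6, "reference": "vehicle",
                              "conditions": common.CONTRACTILITY_CONDITIONS},
            "clamp": {"n_cells": 6, "reference": "vehicle",
                      "conditions": common.CLAMP_CONDITIONS},
        },
    }
    out = common.RESULTS / "report"
    report = reporting.run_pipeline(config, out_dir=out)
    for assay, block in report["assays"].items():
        print(f"[{assay}] metric = {block['metric']}")
        for label, entry in block["conditions"].items():
            pct = entry.get("percent_change_vs_reference")
            pct_s = f", {pct:+.1f}% vs vehicle" if pct is not None else ""
            print(f"  {label}: {entry['mean']:.3g} +/- {entry['sem']:.2g}{pct_s}")
    print(f"report bundle written to {out}")


if __name__ == "__main__":
    main()
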