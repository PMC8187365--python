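"""Shared demo study conditions for the numbered analysis scripts.

The three-arm design mirrors the comparison structure of the underlying
assays: a vehicle baseline, a late-INa-enhancer-like challenge (APD
prolongation, raised beat-to-beat variability, EADs, positive inotropy with
aftercontractions/failures), and the challenge combined with a late-INa
inhibitor that restores the vehicle phenotype.  All traces are synthetic
and seeded; amplitude/probability choices are illustrative, not fitted to
any experimental dataset.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

BASE_SEED = 20260929

AP_CONDITIONS = [
    {"label": "vehicle",
     "params": {"apd90_ms": 300.0, "variability_sd_ms": 3.0, "ar1_coeff": 0.3,
                "noise_sd_mv": 0.5}},
    {"label": "challenge",
     "params": {"apd90_ms": 420.0, "variability_sd_ms": 10.0, "ar1_coeff": 0.5,
                "ead_probability": 0.15, "noise_sd_mv": 0.5}},
    {"label": "challenge_plus_inhibitor",
     "params": {"apd90_ms": 310.0, "variability_sd_ms": 4.0, "ar1_coeff": 0.3,
                "noise_sd_mv": 0.5}},
]

CLAMP_CONDITIONS = [
    {"label": "vehicle", "params": {}},
    {"label": "challenge", "params": {"enhancer_scale": 2.5, "shift_mv": -10.0}},
    {"label": "challenge_plus_inhibitor", "params": {"enhancer_scale": 1.1}},
]

CONTRACTILITY_CONDITIONS = [
    {"label": "vehicle", "params": {"noise_sd": 0.002}},
    {"label": "challenge",
     "params": {"primary_amplitude": 0.14, "secondary_event_probability": 0.25,
                "failure_probability": 0.05, "noise_sd": 0.002}},
    {"label": "challenge_plus_inhibitor",
     "params": {"primary_amplitude": 0.095, "noise_sd": 0.002}},
]


def seed_for(*indices: int) -> int:
    s = BASE_SEED
    for k in indices:
        s = (s * 1_000_003 + 7919 * (int(k) + 1)) % (2**31 - 1)
    return s
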