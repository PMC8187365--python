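import numpy as np
import pytest

from cardiomarker import synthetic as syn
from cardiomarker import trace_io as tio


@pytest.fixture
def clean_ap_train():
    """Noiseless 20-beat AP train with constant APD90 = 300 ms."""
    params = syn.APGenParams(apd90_ms=300.0, variability_sd_ms=0.0,
                             ead_probability=0.0, n_beats=20, seed=1)
    return syn.gen_ap_train(params)


@pytest.fixture
def ca_train():
    return syn.gen_ca_train(syn.ca_params(seed=2))


@pytest.fixture
def sarcomere_train():
    return syn.gen_sarcomere_train(syn.sarcomere_params(seed=3))


@pytest.fixture
def force_train():
    return syn.gen_force_train(syn.force_params(seed=4))


@pytest.fixture
def example_recording(tmp_path):
    """A written-out Ca2+ recording (csv + sidecar) for I/O tests."""
    trace, stim, _ = syn.gen_ca_train(syn.ca_params(noise_sd=1.0, seed=5))
    meta = tio.RecordingMeta(assay="calcium", condition_label="vehicle",
                             cell_id="c01", heart_id="h01")
    path = tio.write_trace(trace, stim, meta, tmp_path / "rec.csv")
    return path, trace, stim, meta
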