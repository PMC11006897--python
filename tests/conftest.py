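import numpy as np
import pytest

from axonspace import preprocess, synth, tuning
from axonspace.geometry import default_array


@pytest.fixture(scope="session")
def geom39():
    return default_array()


@pytest.fixture(scope="session")
def tuned_session():
    """Shared benchmark: 25 Gaussian-tuned axons on the 39-position array."""
    traces, log, truth, cfg = synth.make_tuned_session(
        n_axons=25, width=30.0, snr=3.0, n_reps=10, seed=1
    )
    tensor = preprocess.segment_and_dff(traces, log)
    responses = preprocess.trial_response(tensor)
    pos_idx = tuning.position_indices(tensor.trials, cfg.geometry)
    return {
        "traces": traces,
        "log": log,
        "truth": truth,
        "config": cfg,
        "tensor": tensor,
        "responses": responses,
        "pos_idx": pos_idx,
    }


@pytest.fixture(scope="session")
def flat_session():
    """Flat-responsive population: no spatial information by construction."""
    traces, log, truth, cfg = synth.make_tuned_session(
        n_axons=15, kind="flat_responsive", n_reps=8, seed=2
    )
    tensor = preprocess.segment_and_dff(traces, log)
    responses = preprocess.trial_response(tensor)
    pos_idx = tuning.position_indices(tensor.trials, cfg.geometry)
    return {
        "config": cfg,
        "tensor": tensor,
        "responses": responses,
        "pos_idx": pos_idx,
    }
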