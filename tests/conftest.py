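"""Shared fixtures: small synthetic cohorts and model-ready inputs.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleepfusion.config import ModelConfig, PreprocessConfig, SimConfig
from sleepfusion.model import build_inputs
from sleepfusion.preprocess import preprocess_recording
from sleepfusion.synthgen import simulate_cohort, simulate_epoch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 30 epochs — enough for I/O, QC and tiny CV tests."""
    return simulate_cohort(SimConfig(n_subjects=6, epochs_per_night=30, seed=11))


@pytest.fixture(scope="session")
def stage_epochs():
    """Twelve clean epochs per stage at the model rate, fixed seed."""
    gen = np.random.default_rng(42)
    cfg = SimConfig()
    out = {}
    for stage in (0, 1, 2):
        out[stage] = np.stack([simulate_epoch(stage, cfg, gen) for _ in range(12)])
    return out


@pytest.fixture(scope="session")
def tiny_dataset(small_cohort):
    """Preprocessed model-ready inputs per subject for the small cohort."""
    pre = PreprocessConfig()
    dataset = {}
    for rec, hyp in zip(small_cohort.recordings, small_cohort.hypnograms):
        epochs, _ = preprocess_recording(rec, pre)
        n = min(epochs.n_epochs, len(hyp))
        epochs.data = epochs.data[:n]
        dataset[rec.subject_id] = (build_inputs(epochs), hyp.labels[:n])
    return dataset


@pytest.fixture(scope="session")
def fast_model_cfg():
    """Short-schedule model config for smoke-level training tests."""
    return ModelConfig(max_epochs=2, early_stop_patience=2, batch_size=32)
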