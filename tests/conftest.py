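"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from ippg import pipeline, synth


@pytest.fixture(scope="session")
def clean_video_72bpm():
    """Full-length clean recording at 72 bpm (no drift, no motion)."""
    scenario = synth.Scenario(hr_hz=1.2, seed=1)
    seq, truth = synth.generate(scenario)
    return seq, truth


@pytest.fixture(scope="session")
def small_video_66bpm():
    """A small-frame 20 s recording for fast pipeline-level tests."""
    scenario = synth.Scenario(hr_hz=1.1, frame_size=(60, 80), seed=2)
    seq, truth = synth.generate(scenario)
    return seq, truth


@pytest.fixture()
def default_config():
    return pipeline.PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
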