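import numpy as np
import pytest

from respmech.entropy import EntropyParams
from respmech.pipeline import RunConfig
from respmech.synthetic import GeneratorConfig, OcclusionSchedule, generate_recording


@pytest.fixture(scope="session")
def default_recording():
    """One full-size synthetic recording under the default study conditions."""
    cfg = GeneratorConfig(seed=123)
    recording, truth = generate_recording(cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def small_recording():
    """A short recording for fast end-to-end tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_breaths=6,
        occlusion=OcclusionSchedule(n_efforts=8, failure_onset_effort=5),
    )
    recording, truth = generate_recording(cfg)
    return cfg, recording, truth


@pytest.fixture()
def fast_run_config():
    """Pipeline config with a short entropy window (keeps O(N^2) cost low)."""
    return RunConfig(entropy=EntropyParams(max_samples=1000, decimate_to_hz=1000.0))
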