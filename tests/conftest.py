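import numpy as np
import pytest

from gaitenc import GeneratorConfig, Recording, default_class_specs
from gaitenc.recordings import DEFAULT_SCHEMA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, subject="s1", label="walk", rate=50.0,
                   schema=DEFAULT_SCHEMA, rid="rec0"):
    return Recording(subject_id=subject, label=label, sample_rate_hz=rate,
                     schema=schema, data=np.asarray(data, float),
                     recording_id=rid)


@pytest.fixture
def small_recording(rng):
    """A 9-channel, 300-sample recording with mild structure."""
    t = np.arange(300) / 50.0
    data = np.column_stack(
        [np.sin(2 * np.pi * (1.0 + 0.1 * j) * t) + 0.1 * rng.standard_normal(300)
         for j in range(9)]
    )
    return make_recording(data)


@pytest.fixture
def tiny_generator_config():
    return GeneratorConfig(
        class_specs=default_class_specs(n_classes=3)[:3],
        n_subjects=2,
        recordings_per_subject_per_class=1,
        n_samples=256,
        nan_rate=0.0,
        seed=7,
    )
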