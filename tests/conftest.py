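import numpy as np
import pytest

from imufatigue import evaluation, preprocessing, synthetic
from imufatigue.core import SamplingSpec


@pytest.fixture(scope="session")
def tiny_config() -> synthetic.CohortConfig:
    return synthetic.CohortConfig(
        n_subjects=4, sets_per_hand=5, reps_per_set=5, warmup_reps=2, seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    cohort, manifest = synthetic.generate_cohort(tiny_config)
    return cohort, manifest


@pytest.fixture(scope="session")
def tiny_datasets(tiny_cohort, tiny_config):
    cohort, _ = tiny_cohort
    return preprocessing.process_cohort(cohort, tiny_config.sampling)


@pytest.fixture(scope="session")
def tiny_tables(tiny_datasets):
    return evaluation.prepare_tables(tiny_datasets)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_sine_recording(n_cycles=15, period=2.0, rate=50.0, noise=0.0, rpe=13.0,
                        seed=0, subject_id="s01", set_index=1):
    """A clean oscillatory set recording with a known cycle count."""
    gen = np.random.default_rng(seed)
    n = int(round(n_cycles * period * rate))
    t = np.arange(n) / rate
    wave = np.sin(2 * np.pi * t / period - np.pi / 2)
    channels = {
        "gx": wave + gen.normal(0, noise, n),
        "gy": 0.5 * wave + gen.normal(0, noise, n),
        "gz": 0.25 * wave + gen.normal(0, noise, n),
        "ax": 0.4 * wave + gen.normal(0, noise, n),
        "ay": 0.3 * wave + gen.normal(0, noise, n),
        "az": 9.81 - 0.2 * wave + gen.normal(0, noise, n),
    }
    from imufatigue.core import SetRecording

    return SetRecording(
        subject_id=subject_id, hand="left", set_index=set_index,
        timestamps=t, channels=channels, reported_rpe=rpe, heart_rate=rpe * 10,
    )


@pytest.fixture
def sine_recording():
    return make_sine_recording()


@pytest.fixture
def sampling():
    return SamplingSpec(rate=50.0)
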