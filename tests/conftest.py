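import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tugseg.synthetic_tug import DEFAULT_PRESETS, GroupPreset, batch_generate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def noiseless_preset(group: str = "healthy_young", total_mean: float | None = None) -> GroupPreset:
    """Deterministic, noise-free variant of a group preset."""
    base = DEFAULT_PRESETS[group]
    import dataclasses

    return dataclasses.replace(
        base,
        total_sigma=0.0,
        noise_sigma=0.0,
        total_mean=total_mean if total_mean is not None else base.total_mean,
    )


@pytest.fixture(scope="session")
def clean_trials():
    """Six noiseless healthy-young trials (deterministic)."""
    return batch_generate(6, noiseless_preset(), master_seed=7)


@pytest.fixture(scope="session")
def noisy_mixed_trials():
    """Nine noisy trials cycling through all three groups."""
    return batch_generate(9, list(DEFAULT_PRESETS.values()), master_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
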