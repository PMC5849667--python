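import dataclasses

import pytest

from dbsval.simulate import SyntheticConfig, generate_cohort


@pytest.fixture
def default_cohort():
    """A study-like 20-patient cohort with the default noise structure."""
    return generate_cohort(SyntheticConfig(seed=12345))


@pytest.fixture
def noise_free_cohort():
    """A zero-noise, zero-intercept cohort: an exact fixed point of the
    pipeline (WB = slope * DBS everywhere)."""
    cfg = SyntheticConfig(
        intercept=0.0,
        ratio_cv=0.0,
        duplicate_cv=0.0,
        dbswb_cv=0.0,
        invalid_spot_rate=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def clean_config():
    """Default parameters but with no invalid spots (deterministic n)."""
    return dataclasses.replace(SyntheticConfig(seed=99), invalid_spot_rate=0.0)
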