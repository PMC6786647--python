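import numpy as np
import pytest

from sibilant.kinematics import schedule_from_table
from sibilant.synth import (
    SynthesisConfig,
    synth_hotwire,
    synth_microphone,
)


@pytest.fixture(scope="session")
def bundle20():
    """Synthetic recording bundle for the 20 mm/s articulation (seeded)."""
    cfg = SynthesisConfig(sched=schedule_from_table(20), seed=123)
    return cfg, synth_microphone(cfg), synth_hotwire(cfg)


@pytest.fixture(scope="session")
def bundle10_lagged():
    cfg = SynthesisConfig(sched=schedule_from_table(10), seed=5)
    return cfg, synth_microphone(cfg), synth_hotwire(cfg)


@pytest.fixture(scope="session")
def bundle10_no_lag():
    cfg = SynthesisConfig(sched=schedule_from_table(10), seed=5, uc_lag=0.0)
    return cfg, synth_microphone(cfg), synth_hotwire(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
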