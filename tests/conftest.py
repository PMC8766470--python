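import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zfdkit import Interval, make_editing_model, random_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def amplicon():
    """200-nt amplicon with an 8-bp spacer rich in editable cytosines."""
    rng = np.random.default_rng(11)
    left = "".join(rng.choice(list("ACGT"), 90))
    spacer = "TCATCCGC"  # C_2 (TC), C_5 (TC), C_6 (CC), C_8 (GC)
    right = "".join(rng.choice(list("ACGT"), 102))
    ref = left + spacer + right
    return ref, Interval(90, 98)


@pytest.fixture(scope="session")
def toy_genome():
    return random_genome(3000, seed=7)


@pytest.fixture(scope="session")
def on_model(toy_genome):
    return make_editing_model(
        toy_genome,
        Interval(1000, 1008),
        context_defaults={"TC": 0.3, "AC": 0.05, "GC": 0.02, "CC": 0.02},
        seq_error_rate=0.001,
        circular=True,
    )
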