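import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eusocia.config import ModelConfig, TraitState

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fh_haplo() -> ModelConfig:
    """Reference scenario: haplodiploid, female hibernation, monogamy."""
    return ModelConfig(F1=2.0, F3=2.0, S_f=0.9, S_m=0.6, b=1.5)


@pytest.fixture
def fig2_config() -> ModelConfig:
    """Parameters of the coevolutionary-transition reference run."""
    return ModelConfig(F1=5.0, F3=5.0, S_f=0.9, S_m=0.6, b=1.5)


@pytest.fixture
def even_traits() -> TraitState:
    return TraitState(0.5, 0.5, 0.0)


def random_config(rng: np.random.Generator, life_cycle: str) -> ModelConfig:
    """A random valid scenario for property sweeps."""
    return ModelConfig(
        life_cycle=life_cycle,
        ploidy=rng.choice(["haplodiploid", "diploid"]),
        F1=float(rng.uniform(0.5, 8.0)),
        F3=float(rng.uniform(0.5, 8.0)),
        S_f=float(rng.uniform(0.05, 1.0)),
        S_m=float(rng.uniform(0.0, 1.0)),
        b=float(rng.uniform(0.0, 3.0)),
    )


def random_traits(rng: np.random.Generator) -> TraitState:
    return TraitState(
        z1=float(rng.uniform(0.05, 0.95)),
        z2=float(rng.uniform(0.05, 0.95)),
        h=float(rng.uniform(0.0, 0.9)),
    )
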