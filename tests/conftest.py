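import numpy as np
import pytest

from plastcomp.plan import TOY_HOTSPOT_LABELS, toy_plan
from plastcomp.sim import SimConfig, evolve


@pytest.fixture(scope="session")
def toy_config():
    return SimConfig(
        plan=toy_plan(),
        hotspot_labels={lab: 10.0 for lab in TOY_HOTSPOT_LABELS},
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_config):
    """One deterministic toy-plan simulation shared across tests."""
    records, truth = evolve(toy_config)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(n, rng, gc=0.38):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
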