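import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from rrlact.basis import LegendreBasis
from rrlact.model import ModelSpec
from rrlact.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def basis5() -> LegendreBasis:
    return LegendreBasis(5)


@pytest.fixture(scope="session")
def basis3() -> LegendreBasis:
    return LegendreBasis(3)


@pytest.fixture(scope="session")
def tiny_dataset():
    """~50-record data set with full structure, small enough for dense oracles."""
    cfg = SimConfig(
        n_founders=6, offspring_per_generation=8, n_herds=2,
        years=(1996, 1998), seed=5,
    )
    records, ped, truth = simulate_dataset(cfg)
    return cfg, records, ped, truth


@pytest.fixture(scope="session")
def small_dataset():
    """~1,500-record data set used for REML behaviour tests."""
    cfg = SimConfig(
        n_founders=40, offspring_per_generation=250, n_herds=8,
        years=(1996, 1999), tests_per_animal=(6, 6), seed=7,
    )
    records, ped, truth = simulate_dataset(cfg)
    return cfg, records, ped, truth


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    return ModelSpec()


def random_pedigree(n: int, n_founders: int, seed: int):
    """Random acyclic pedigree triples: parents always have smaller ids."""
    rng = np.random.default_rng(seed)
    triples = []
    for i in range(1, n + 1):
        if i <= n_founders:
            triples.append((i, 0, 0))
        else:
            s = int(rng.integers(1, i))
            d = int(rng.integers(1, i))
            if s == d:
                d = 0
            triples.append((i, s, d))
    return triples
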