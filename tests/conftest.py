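import numpy as np
import pytest

from ncplink import (
    AssociationDataset,
    SyntheticConfig,
    generate_dataset,
    loocv,
)


@pytest.fixture
def identity_ds() -> AssociationDataset:
    """2x2 identity network: m1-d1 and m2-d2 known."""
    return AssociationDataset(("m1", "m2"), ("d1", "d2"), np.eye(2, dtype=int))


@pytest.fixture
def toy_ds() -> AssociationDataset:
    """3 microbes x 2 diseases with one duplicated microbe profile."""
    md = np.array([[1, 0], [1, 0], [0, 1]])
    return AssociationDataset(("m1", "m2", "m3"), ("d1", "d2"), md)


def random_dataset(rng: np.random.Generator, nm: int = 15, nd: int = 8,
                   density: float = 0.25) -> AssociationDataset:
    """A random binary network guaranteed to have >= 2 associations."""
    while True:
        md = (rng.random((nm, nd)) < density).astype(int)
        if md.sum() >= 2:
            break
    names_m = tuple(f"m{i}" for i in range(nm))
    names_d = tuple(f"d{j}" for j in range(nd))
    return AssociationDataset(names_m, names_d, md)


SMALL_SYNTH = dict(
    n_microbes=80,
    n_diseases=16,
    n_microbe_clusters=4,
    n_disease_clusters=4,
    intra_cluster_prob=0.25,
    inter_cluster_prob=0.03,
    degree_skew=0.7,
)


@pytest.fixture(scope="session")
def small_planted_ds() -> AssociationDataset:
    """A down-sized planted-cluster network for fast CV tests."""
    return generate_dataset(SyntheticConfig(seed=7, **SMALL_SYNTH))


@pytest.fixture(scope="session")
def default_planted_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_planted_ds(default_planted_cfg) -> AssociationDataset:
    """The default benchmark-shaped planted network (seed 7)."""
    return generate_dataset(default_planted_cfg)


@pytest.fixture(scope="session")
def default_planted_loocv(default_planted_ds):
    """LOOCV on the default planted network, shared across tests."""
    return loocv(default_planted_ds)
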