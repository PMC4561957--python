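import numpy as np
import pytest

from mirbm import (
    AssociationRecord,
    GeneratorConfig,
    MultiTypeNetwork,
    generate,
    init_params,
    network_from_records,
)

#: The six known triples of the small worked network: 2 miRNAs x 3 diseases,
#: four evidence types, six 1-entries.
TOY_TRIPLES = [
    ("mir-1", "disease-A", "target"),
    ("mir-1", "disease-A", "circulation"),
    ("mir-1", "disease-B", "genetics"),
    ("mir-1", "disease-C", "epigenetics"),
    ("mir-2", "disease-B", "target"),
    ("mir-2", "disease-C", "circulation"),
]


@pytest.fixture
def toy_net() -> MultiTypeNetwork:
    return network_from_records(
        [AssociationRecord(m, d, t) for m, d, t in TOY_TRIPLES]
    )


@pytest.fixture
def tiny_net() -> MultiTypeNetwork:
    """A 2-disease x 3-miRNA x 2-type network small enough for exact
    enumeration oracles (n*t = 4 visible units)."""
    net, _ = generate(
        GeneratorConfig(
            n_diseases=2,
            n_mirnas=3,
            n_types=2,
            latent_dim=2,
            per_type_target_counts=(2, 2),
            noise_flip_rate=0.0,
            seed=5,
        )
    )
    assert net.n_associations >= 2
    return net


def random_tiny_params(seed: int, n=None, t=None, m=None):
    """Random dimensions in {1, 2} and Gaussian parameters for oracle tests."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(1, 3))
    t = t or int(rng.integers(1, 3))
    m = m or int(rng.integers(1, 3))
    params = init_params(n, t, m, sd=0.5, seed=rng)
    v = rng.integers(0, 2, size=(n, t)).astype(np.int8)
    r = ((v.sum(axis=1) > 0) | (rng.random(n) < 0.5)).astype(np.int8)
    h = rng.integers(0, 2, size=m).astype(np.int8)
    return params, v, r, h
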