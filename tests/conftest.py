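import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hugephage.simulate import CommunitySpec, generate_community

#: The standard study-scale community every recovery test works from:
#: ten phage genomes spanning 200-700 kb and five bacterial hosts.
COMMUNITY_SEED = 42


@pytest.fixture(scope="session")
def community():
    spec = CommunitySpec(seed=COMMUNITY_SEED, n_phage=10, n_host=5)
    contigs, annotations, truth = generate_community(spec)
    return {"spec": spec, "contigs": contigs, "annotations": annotations,
            "truth": truth,
            "by_id": {c.id: c for c in contigs}}


@pytest.fixture(scope="session")
def small_community():
    spec = CommunitySpec(seed=3, n_phage=3, n_host=2,
                         phage_length_range=(200_000, 240_000),
                         host_length_range=(210_000, 230_000))
    contigs, annotations, truth = generate_community(spec)
    return {"spec": spec, "contigs": contigs, "annotations": annotations,
            "truth": truth,
            "by_id": {c.id: c for c in contigs}}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
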