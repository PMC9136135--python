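import numpy as np
import pytest

from ucps_motif import (
    PlantSpec,
    SyntheticParams,
    generate_cohorts,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohorts():
    """Small planted cohorts shared by enrichment/proximity/pipeline tests."""
    params = SyntheticParams(
        n_pos=80,
        n_neg=80,
        length=250,
        seed=11,
        plants=[
            PlantSpec("tri", "EEE", 0.8, 0.4),
            PlantSpec("kkx", "KKX", 0.9, 0.5),
            PlantSpec("lir", "WXXL", 0.9, 0.9),
        ],
    )
    pos, neg, truth = generate_cohorts(params)
    return params, pos, neg, truth


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))
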