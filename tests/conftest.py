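import numpy as np
import pytest

# A synthetic ~60-residue domain consensus used to plant and recover
# domain copies; fixed so alignment scores are reproducible. It stands in
# for a real AP2 seed consensus, which the tests deliberately avoid
# depending on.
SYNTHETIC_DOMAIN = (
    "HYRGVRQRPWGKWVAEIRDPKKAARVWLGTFDTAEAAARAYDEAALRFKGNKAKLNFPER"
)


@pytest.fixture(scope="session")
def domain_consensus() -> str:
    return SYNTHETIC_DOMAIN


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
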