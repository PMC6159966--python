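import numpy as np
import pytest

from dmmrkit.refsigs import make_reference_signatures
from dmmrkit.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference_signatures():
    return make_reference_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = SimConfig(n_samples=16, n_loci=40, mutations_per_sample=80,
                    n_genes=60, genome_length=200_000, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def tiny_reference():
    # chr1: positions 1..8 = T A C A G T G A (1-based)
    return {"chr1": "TACAGTGA"}
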