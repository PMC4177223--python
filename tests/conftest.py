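import numpy as np
import pytest

from hybridzone import LocusModel, make_locus_models


@pytest.fixture(scope="session")
def fixed_models():
    """Ten loci fixed for allele 100 in A and 102 in B (diagnostic panel)."""
    return [
        LocusModel(f"D{l + 1:02d}", [100, 102], [1.0, 0.0], [0.0, 1.0])
        for l in range(10)
    ]


@pytest.fixture(scope="session")
def diverged_models():
    """Ten 8-allele loci at moderate drift (FST in the ~0.15 range)."""
    return make_locus_models(10, 8, 0.18, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
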