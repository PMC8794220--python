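import numpy as np
import pytest

from florypot import synthetic
from florypot.fragments import collect_distances
from florypot.io_structures import CoarseGrainLevel


@pytest.fixture(scope="session")
def gaussian_ensemble():
    """300 ideal chains of 900 residues, Kuhn length 3.8 Å (fixed seeds)."""
    b = 3.8
    chains = [
        synthetic.generate_gaussian_chain(900, b=b, seed=10_000 + i)
        for i in range(300)
    ]
    return chains, b


@pytest.fixture(scope="session")
def gaussian_fragment_sets(gaussian_ensemble):
    chains, b = gaussian_ensemble
    sets = collect_distances(chains, (70, 90), CoarseGrainLevel.CA,
                             record_types=False)
    return sets, b
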