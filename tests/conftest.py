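import numpy as np
import pandas as pd
import pytest

from budworm.io import GenotypeMatrix
from budworm.simulate import SimConfig, simulate_dataset


def make_matrix(calls, scaffolds=None, positions=None, ids=None):
    """Small GenotypeMatrix from a dosage array (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    loci = pd.DataFrame(
        {
            "scaffold": scaffolds if scaffolds is not None else ["s1"] * L,
            "pos": positions if positions is not None else np.arange(1, L + 1),
            "ref": ["A"] * L,
            "alt": ["C"] * L,
        }
    )
    ids = ids if ids is not None else [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(ids, loci, calls)


@pytest.fixture(scope="session")
def study():
    """One paper-scale simulated study (400 loci) shared across tests."""
    return simulate_dataset(SimConfig(seed=11, n_loci=400))


@pytest.fixture(scope="session")
def study_truth_labels(study):
    truth = study.truth.set_index("id")
    return truth.loc[study.genotypes.individuals, "true_class"]
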