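import numpy as np
import pandas as pd
import pytest

from mirpipe.simulate import default_cohort_params, generate_cohort
from mirpipe.topography import TissueProfileSet


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default study-analogue cohort (seeded)."""
    df, truth = generate_cohort(default_cohort_params(seed=12345))
    return df, truth


@pytest.fixture()
def tiny_profile_set():
    """Two individuals, two tissues, three microRNAs, hand-computable."""
    mirs = ["m1", "m2", "m3"]
    profiles = {
        ("a", "EBC"): np.array([1.0, 0.0, 1.0]),
        ("a", "BAL"): np.array([1.0, 1.0, 0.0]),  # Hamming 2
        ("b", "EBC"): np.array([0.0, 0.0, 0.0]),
        ("b", "BAL"): np.array([1.0, 1.0, 1.0]),  # Hamming 3
    }
    return TissueProfileSet(
        individuals=["a", "b"], tissues=["EBC", "BAL"], mirs=mirs, profiles=profiles
    )


def random_profile_set(rng, n_ind=12, n_mir=13, tissues=("EBC", "BAL"), missing_rate=0.0):
    """Independent random binary profiles (a null-topography dataset)."""
    individuals = [f"i{k}" for k in range(n_ind)]
    profiles = {}
    for t in tissues:
        mat = (rng.random((n_ind, n_mir)) < 0.5).astype(float)
        if missing_rate:
            mat[rng.random(mat.shape) < missing_rate] = np.nan
        for i, ind in enumerate(individuals):
            profiles[(ind, t)] = mat[i]
    return TissueProfileSet(
        individuals=individuals,
        tissues=list(tissues),
        mirs=[f"m{j}" for j in range(n_mir)],
        profiles=profiles,
    )
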