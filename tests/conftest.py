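import warnings

import numpy as np
import pytest

import metsel as ms


def make_grm(ncp: int, p: int, seed: int, n_subpops: int = 1, fst: float = 0.0):
    """Structured synthetic GRM used across the suite."""
    markers = ms.simulate_marker_matrix(ncp, p, n_subpops=n_subpops, fst=fst, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ms.grm_from_markers(markers, maf_threshold=0.05)


@pytest.fixture(scope="session")
def small_grm():
    """8-genotype GRM with mild two-group structure."""
    return make_grm(8, 500, seed=3, n_subpops=2, fst=0.2)


@pytest.fixture(scope="session")
def panel_grm():
    """Medium diversity panel: 60 genotypes, 3 subpopulations, Fst 0.3."""
    return make_grm(60, 800, seed=21, n_subpops=3, fst=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
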