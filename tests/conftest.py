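import numpy as np
import pandas as pd
import pytest

from chromsig.io_tracks import BinnedTrack, GenomeLayout
from chromsig.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def simple_layout():
    """One 1000 bp chromosome plus a sex chromosome split PAR/SDR/autosome."""
    regions = pd.DataFrame(
        [("sctg_sex", 0, 600, "PAR"), ("sctg_sex", 600, 900, "SDR_MALE")],
        columns=["chromosome", "start", "end", "region_class"])
    return GenomeLayout(chromosomes={"chr1": 1000, "sctg_sex": 1000},
                        regions=regions)


@pytest.fixture
def flat_track():
    def make(values, bin_size=200, **kw):
        if isinstance(values, dict):
            vals = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        else:
            vals = {"chr1": np.asarray(values, dtype=float)}
        return BinnedTrack(bin_size=bin_size, values=vals, **kw)
    return make


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic dataset shared across tests (in-memory only)."""
    cfg = SyntheticConfig(seed=11, n_autosomes=2, autosome_length=100_000,
                          sex_chromosome_length=100_000, par_end=80_000,
                          sdr_female=(80_000, 90_000), sdr_male=(90_000, 100_000))
    return cfg, generate_dataset(cfg)


def simulate_hmm_sequence(emission, transition, T, seed):
    """Sample a state path and binary observations from known HMM parameters."""
    rng = np.random.default_rng(seed)
    K, M = emission.shape
    states = np.zeros(T, dtype=int)
    states[0] = rng.integers(K)
    for t in range(1, T):
        states[t] = rng.choice(K, p=transition[states[t - 1]])
    X = (rng.random((T, M)) < emission[states]).astype(np.uint8)
    return states, X
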