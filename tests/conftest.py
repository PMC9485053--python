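import numpy as np
import pytest

from carpet.simulate import SimConfig, simulate_study


def mini_config(seed: int = 11, **overrides) -> SimConfig:
    """A small, fast study for unit tests (not the acceptance conditions)."""
    defaults = dict(
        seed=seed,
        n_contigs=2,
        contig_len=80_000,
        n_ca_arrays=40,
        n_can_arrays=8,
        n_other_repeats=50,
        n_genes=60,
        gene_len_range=(800, 2000),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def mini_study():
    return simulate_study(mini_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
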