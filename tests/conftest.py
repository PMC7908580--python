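import warnings

import numpy as np
import pytest

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz  # noqa: F401  (silence its one-time refactor notice)

import maupmtup as m


@pytest.fixture(scope="session")
def small_lattice():
    """6x6 rook lattice with a coarser (factor-2) rainfall grid."""
    return m.gen_lattice(6, 6, 2, (100, 300), seed=42)


@pytest.fixture(scope="session")
def path4_lattice():
    """1x4 path lattice with equal populations of 250."""
    return m.gen_lattice(1, 4, 1, (250, 250), seed=0)


@pytest.fixture(scope="session")
def reduced_mcmc():
    """Shortened sampler settings for replicate-heavy checks."""
    return m.BYMConfig(chains=1, iterations=2000, burn_in=800, thinning=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
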