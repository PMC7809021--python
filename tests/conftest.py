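import numpy as np
import pytest

from tadlink.simulate import SimParams, simulate

# Reduced genome for tests that exercise the full pipeline: same TAD /
# gene / DAR structure as the defaults, scaled so a run takes < 1 s.
SCALED = dict(
    n_chrom=2,
    chrom_len=6_000_000,
    tad_len_range=(180_000, 700_000),
    n_chip_background=40,
)


def scaled_params(seed: int, **overrides) -> SimParams:
    kw = dict(SCALED)
    kw.update(overrides)
    return SimParams(seed=seed, **kw)


@pytest.fixture(scope="session")
def bundle():
    """One scaled synthetic dataset shared by read-only tests."""
    return simulate(scaled_params(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
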