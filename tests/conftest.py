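import numpy as np
import pytest

from bayesalphabet.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genotypes():
    """5 animals x 4 SNPs with 3 masked cells (hand-checkable)."""
    dos = np.array(
        [
            [0, 1, 2, 2],
            [1, 1, 2, 0],
            [2, 0, 2, 1],
            [0, 2, 2, 1],
            [1, 1, 2, 2],
        ],
        dtype=float,
    )
    mask = np.zeros_like(dos, dtype=bool)
    mask[0, 0] = mask[1, 0] = mask[2, 3] = True
    return GenotypeMatrix(dosages=dos, mask=mask)


def coded_panel(rng, n, k, maf_low=0.1, maf_high=0.9):
    """Random HWE centered-ten panel for sampler tests."""
    p = rng.uniform(maf_low, maf_high, size=k)
    return 10.0 * (rng.binomial(2, p, size=(n, k)) - 1.0)
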