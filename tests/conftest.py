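import numpy as np
import pytest

from ldhic.ld import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_panel(rng):
    """80 SNPs x 200 haplotypes with moderate allele frequencies."""
    m = 80
    freqs = rng.uniform(0.1, 0.9, size=m)
    alleles = (rng.random((200, m)) < freqs).astype(np.uint8)
    # ensure polymorphic columns
    alleles[0] = 0
    alleles[1] = 1
    positions = np.sort(rng.choice(500_000, size=m, replace=False)) + 1
    return HaplotypePanel(alleles, positions)


def brute_force_r2_dprime(hapA, hapB):
    """Definitional r²/D′ from explicit haplotype tallies (test oracle)."""
    hapA = np.asarray(hapA, dtype=bool)
    hapB = np.asarray(hapB, dtype=bool)
    n = hapA.size
    pAB = np.sum(hapA & hapB) / n
    pA = hapA.mean()
    pB = hapB.mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    dmax = (min(pA * (1 - pB), (1 - pA) * pB) if D > 0
            else min(pA * pB, (1 - pA) * (1 - pB)))
    dp = 0.0 if dmax == 0 else abs(D) / dmax
    return r2, dp
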