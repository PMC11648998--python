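import numpy as np
import pytest

from hicvst import ContactMatrix, SynthConfig, from_dense, simulate_pair


@pytest.fixture
def intra_pair():
    """The 2x2 worked example: dense [[4,2],[2,6]] and [[3,1],[1,7]]."""
    m1 = from_dense(np.array([[4.0, 2.0], [2.0, 6.0]]), "chrA", "chrA", 10_000)
    m2 = from_dense(np.array([[3.0, 1.0], [1.0, 7.0]]), "chrA", "chrA", 10_000)
    return m1, m2


@pytest.fixture
def inter_pair():
    """A 2x3 inter-chromosomal pair with every cell nonzero."""
    a = np.arange(1, 7, dtype=float).reshape(2, 3)
    m1 = from_dense(a, "chrA", "chrB", 10_000)
    m2 = from_dense(a[::-1].copy().reshape(2, 3) + 1, "chrA", "chrB", 10_000)
    return m1, m2


@pytest.fixture(scope="session")
def nb_pair():
    """Default negative-binomial replicate pair (overdispersed, seed-fixed)."""
    return simulate_pair(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def poisson_pair():
    """Poisson replicate pair (alpha = 0), same geometry as the NB default."""
    return simulate_pair(SynthConfig(seed=3, alpha=0.0))


def random_matrix_pair(rng: np.random.Generator, n: int = 30,
                       chrom: str = "chrR") -> tuple[ContactMatrix, ContactMatrix]:
    """Small dense-ish random intra pair for property tests."""
    lam = rng.gamma(2.0, 2.0, size=(n, n))
    lam = (lam + lam.T) / 2
    a = rng.poisson(lam).astype(float)
    b = rng.poisson(lam).astype(float)
    a = np.triu(a) + np.triu(a, 1).T
    b = np.triu(b) + np.triu(b, 1).T
    return (from_dense(a, chrom, chrom, 1000),
            from_dense(b, chrom, chrom, 1000))
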