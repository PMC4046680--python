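import numpy as np
import pytest

from scpca.setio import GenotypeMatrix, Phenotype


def sample_categorical(rng, n, d, scale=0.4, offset_scale=0.3):
    """Genotypes from a rank-1 natural-parameter ground truth.

    Returns (codes, true cell probabilities (3, n, d)).
    """
    u = rng.standard_normal(n)
    v1 = rng.standard_normal(d) * scale
    v2 = rng.standard_normal(d) * scale
    m1 = rng.standard_normal(d) * offset_scale
    m2 = rng.standard_normal(d) * offset_scale
    th1 = np.outer(u, v1) + m1
    th2 = np.outer(u, v2) + m2
    Z = 1 + np.exp(th1) + np.exp(th2)
    p0, p1, p2 = 1 / Z, np.exp(th1) / Z, np.exp(th2) / Z
    r = rng.random((n, d))
    codes = np.where(r < p0, 0, np.where(r < p0 + p1, 1, 2)).astype(np.int8)
    return codes, np.stack([p0, p1, p2])


def genotype_matrix(values):
    values = np.asarray(values, dtype=np.int8)
    n, d = values.shape
    return GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_genotypes(rng):
    return genotype_matrix(rng.integers(0, 3, size=(40, 8)))


@pytest.fixture
def balanced_phenotype():
    y = np.array([1, 0] * 20, dtype=np.int8)
    return Phenotype(y=y, sample_ids=[f"s{i}" for i in range(40)])
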