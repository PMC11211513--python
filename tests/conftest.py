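import numpy as np
import pytest

from twingp import (GenotypeMatrix, ILSTSVRHyperparams, PhenotypeVector,
                    simulate_genotypes, simulate_phenotypes, TraitSpec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """A small well-conditioned regression problem (n=20, m=4)."""
    X = rng.normal(size=(20, 4))
    beta = np.array([1.5, -2.0, 0.0, 0.5])
    y = X @ beta + 0.1 * rng.normal(size=20)
    return X, y


@pytest.fixture
def linear_hp():
    return ILSTSVRHyperparams(C1=2.0, C3=0.5, eps1=0.05, eps2=0.05)


@pytest.fixture
def genotab(tmp_path):
    """A tiny genotype CSV on disk plus the matrix it encodes."""
    X = GenotypeMatrix([[0, 1], [2, 0], [1, 1]],
                       ["a", "b", "c"], ["m1", "m2"])
    path = tmp_path / "geno.csv"
    from twingp.io import write_genotype_table
    write_genotype_table(X, path)
    return path, X
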