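import numpy as np
import pytest

from epiget import (BinaryPhenotype, GenotypeMatrix, GenotypeModel,
                    SimulationModel, simulate_case_control)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """A seeded 200-subject, 8-marker data set with a balanced phenotype."""
    g = GenotypeMatrix(values=rng.integers(0, 3, size=(200, 8)))
    y = BinaryPhenotype(values=np.tile([0, 1], 100))
    return g, y


@pytest.fixture(scope="session")
def interaction_dataset():
    """One seeded case-control draw from a five-SNP interaction model
    (MAF 0.25, copula rho 0.1, log(3) interaction between SNPs 1 and 2)."""
    gm = GenotypeModel(p=5, maf=0.25, rho=0.1)
    pm = SimulationModel(beta0=-1.0,
                         marginal={0: np.log(1.5), 1: np.log(1.5)},
                         interactions=(((0, 1), np.log(3.0)),))
    return simulate_case_control(gm, pm, 500, 500, seed=2024)
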