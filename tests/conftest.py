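import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from demosat.dataset import GenotypeDataset
from demosat.simulator import (MutationModel, bottleneck_model, constant_model,
                               simulate_dataset)


@pytest.fixture(scope="session")
def gsm_mut():
    return MutationModel.gsm(1e-4, 0.2)


@pytest.fixture(scope="session")
def bottleneck_dataset(gsm_mut):
    """181 x 39 dataset from the canonical strong-bottleneck demography."""
    return simulate_dataset(181, 39, bottleneck_model(10000, 200, 10000, 10, 20),
                            gsm_mut, seed=101)


@pytest.fixture(scope="session")
def constant_dataset(gsm_mut):
    return simulate_dataset(181, 39, constant_model(10000, 10000, 25),
                            gsm_mut, seed=102)


def make_dataset(genotypes, pops=None, locus_names=None):
    """Helper: build a GenotypeDataset from a nested genotype list."""
    alleles = np.asarray(genotypes, dtype=np.int64)
    n, n_loci = alleles.shape[:2]
    return GenotypeDataset(
        alleles=alleles,
        pop_labels=np.array(pops if pops is not None else ["p1"] * n, dtype=object),
        locus_names=locus_names or [f"loc{i + 1}" for i in range(n_loci)],
    )
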