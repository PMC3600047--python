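import numpy as np
import pytest

from claderates.data_io import read_tree
from claderates.synthetic_data import (
    SimConfig,
    default_codon_model,
    default_nuc_model,
    make_table1_fixture,
    simulate_pair_tree,
)


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def six_taxon_tree():
    return read_tree(
        "(((A:0.05,B:0.08):0.03,(C:0.04,D:0.10):0.02):0.02,(E:0.06,F:0.03):0.04);"
    )


@pytest.fixture
def small_tree():
    return read_tree("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture
def nuc_model():
    return default_nuc_model()


@pytest.fixture
def codon_model():
    return default_codon_model()


@pytest.fixture
def pair_cfg():
    return SimConfig(seed=7, n_pairs=3)


@pytest.fixture
def pair_study(pair_cfg):
    return simulate_pair_tree(pair_cfg)


def random_nuc_spec(rng, gamma=False, pinv=False):
    from claderates.substitution_models import ExchangeabilityPartition, NucModelSpec

    part = ExchangeabilityPartition("012345")
    return NucModelSpec(
        partition=part,
        theta=rng.uniform(0.5, 2.0, 6),
        pi=rng.dirichlet(np.ones(4) * 5),
        gamma_shape=float(rng.uniform(0.3, 2.0)) if gamma else None,
        p_inv=float(rng.uniform(0.05, 0.3)) if pinv else None,
    )
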