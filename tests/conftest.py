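import numpy as np
import pytest

from clinekit import (
    ClineModel,
    GenotypeMatrix,
    SimConfig,
    load_contact_zone_fixture,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def contact_records():
    return load_contact_zone_fixture()


@pytest.fixture(scope="session")
def two_pure_demes():
    """Two strongly differentiated demes far from the cline center."""
    cfg = SimConfig(
        n_loci=26,
        alleles_per_locus=8,
        deme_positions=[0.0, 1000.0],
        n_per_deme=[50, 50],
        true_cline=ClineModel(center=500.0, width=1.0),
        true_mt_cline=ClineModel(center=500.0, width=1.0),
        n_reference=0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def diagnostic_genotypes():
    """Two populations fixed for alternative alleles at every locus."""
    n_loci, n_per = 8, 10
    calls = np.zeros((2 * n_per, n_loci, 2), dtype=np.int64)
    calls[n_per:] = 1
    return GenotypeMatrix(
        ids=[f"i{j}" for j in range(2 * n_per)],
        pops=["p1"] * n_per + ["p2"] * n_per,
        loci=[f"L{l}" for l in range(n_loci)],
        calls=calls,
    )
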