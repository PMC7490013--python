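import numpy as np
import pytest

from tecsuite.synthetic import (
    HtoMixSpec,
    LocusSpec,
    ScCountSpec,
    TrajectorySpec,
    gen_germline_locus,
    gen_hto_counts,
    gen_sc_counts,
    gen_trajectory,
)


@pytest.fixture(scope="session")
def locus():
    """Default synthetic germline locus."""
    return gen_germline_locus(LocusSpec(seed=7))


@pytest.fixture(scope="session")
def atg_free_locus():
    """Locus whose V segments carry no start codon: nothing is productive."""
    return gen_germline_locus(LocusSpec(atg_fraction=0.0, seed=7))


@pytest.fixture(scope="session")
def clustered_counts():
    """Five well-separated subtypes, one age, low dropout; 500 cells."""
    spec = ScCountSpec(
        ages=(4,), n_replicates=1, n_cells_per_sample=500,
        n_clusters=5, marker_fold=10.0, dropout=0.02, seed=11,
    )
    return gen_sc_counts(spec)


@pytest.fixture(scope="session")
def hto_mixture():
    """Signal NB(500), background NB(5), 6 HTOs, 2000 barcodes, 10% doublets."""
    spec = HtoMixSpec(seed=3)
    return gen_hto_counts(spec)


@pytest.fixture(scope="session")
def shifting_trajectory():
    """Three meta-stable states; age shifts weight into the earliest state."""
    spec = TrajectorySpec(
        ages=(1, 4, 16), n_replicates=3, n_cells_per_sample=150,
        state_weights={
            1: (0.15, 0.25, 0.60),
            4: (0.35, 0.25, 0.40),
            16: (0.60, 0.25, 0.15),
        },
        seed=5,
    )
    return gen_trajectory(spec)
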