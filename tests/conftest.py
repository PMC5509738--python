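import numpy as np
import pytest

from jointcov import PhenotypeLabels, SyntheticDesign, generate, worked_toy


@pytest.fixture(scope="session")
def toy():
    return worked_toy()


@pytest.fixture(scope="session")
def small_planted():
    """40 probes, 102/29 patients: 1 marginal probe, 1 pair, no cliques."""
    design = SyntheticDesign(n_probes=40, n_marginal_signal=1, n_pair_signal=1,
                             n_cliques=0, seed=11)
    return generate(design)


@pytest.fixture(scope="session")
def null_small():
    """30 null probes over a small balanced cohort for cheap null checks."""
    design = SyntheticDesign(n_probes=30, n_patients_g1=25, n_patients_g2=15,
                             n_marginal_signal=0, n_pair_signal=0, n_cliques=0,
                             seed=5)
    return generate(design)


@pytest.fixture
def tiny_labels():
    ids = [f"P{i}" for i in range(10)]
    return PhenotypeLabels(ids, np.array([0] * 6 + [1] * 4))
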