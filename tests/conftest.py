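import numpy as np
import pytest

from psmsr import DRUG_PRESETS, PRESETS, SeedingDesign, run_seeding_panel


@pytest.fixture(scope="session")
def het_params():
    """Published co-culture (immediate-mix) parameter set."""
    return PRESETS["heterotypic"]


@pytest.fixture(scope="session")
def drug_params():
    return DRUG_PRESETS["heterotypic-cisplatin"]


@pytest.fixture(scope="session")
def drug_phenotype_params():
    return PRESETS["heterotypic-cisplatin"]


@pytest.fixture(scope="session")
def het_panel(het_params):
    """Drug-free heterotypic seeding panel: 5000 cells, ratios 1:1-8:1,
    sampled every 2 h over 144 h (shared across tests; read-only)."""
    return run_seeding_panel(het_params, SeedingDesign())


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noisy heterotypic dataset with ground truth attached."""
    from psmsr import make_fixture

    return make_fixture("tiny-heterotypic", sigma=0.05, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
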