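import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phylorecruit as pr

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def three_taxon_tree() -> pr.Phylogeny:
    return pr.parse_newick("((A,B)N1,C)R;")


@pytest.fixture(scope="session")
def five_taxon_tree() -> pr.Phylogeny:
    return pr.parse_newick("((((A,B)N1,C)N2,D)N3,E)R;")


@pytest.fixture(scope="session")
def amniote() -> pr.Phylogeny:
    return pr.amniote_tree()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
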