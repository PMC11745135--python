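import warnings

import numpy as np
import pytest

import scorpsize as sz

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def two_tip():
    return sz.read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    return sz.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def star_tree():
    return sz.read_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")


@pytest.fixture(scope="session")
def sim_complete_100():
    """Allometric scenario without missingness or big noise, 100 species."""
    scenario = sz.AllometryScenario(n_species=100, missing_fraction=0.0, seed=5)
    return sz.simulate_traits(scenario)


@pytest.fixture(scope="session")
def small_pmm_settings():
    """Short chain for synthetic-recovery studies."""
    return sz.MCMCSettings(iterations=4000, burn_in=500, thin=5)
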