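import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from nitronet import simulate


@pytest.fixture(scope="session")
def quad_tree() -> TreeNode:
    """((A,B),(C,D)) — the 4-tip worked example tree."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def small_study():
    """A compact study with planted structure, shared across tests.

    14 sites x 2 treatments x 4 plots, 150 frequent OTUs in four modules,
    600 rare OTUs — the design at reduced OTU count.
    """
    return simulate.generate_study(
        n_sites=14,
        plots_per_treatment=4,
        n_frequent=150,
        n_rare=600,
        module_sizes=(25, 25, 20, 20),
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_composition(rng) -> pd.DataFrame:
    return pd.DataFrame(
        rng.dirichlet(np.ones(4), size=8), columns=list("ABCD"),
        index=[f"s{i}" for i in range(8)],
    )
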